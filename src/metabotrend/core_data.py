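"""Core data containers for LC-MS time-course analysis.

A study is represented by an intensity matrix (observations x peaks) bound to
two metadata tables: one describing the observations (experimental group,
study time, analytical batch, acquisition order, biological replicate) and one
describing the peaks (m/z, retention time, ionization mode).  Pooled
quality-control injections are ordinary observations whose group is the
reserved label ``"QC"``.

Compound, adduct and pathway reference data live in a :class:`KnowledgeBase`
used by the annotation and pathway-overlap stages.

All tables are plain UTF-8 comma-separated files with a header row and the
entity identifier in the first column; the pathway table is long-format
(``pathway_id,pathway_name,compound_id``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Reserved observation group label identifying pooled QC injections.
QC_GROUP = "QC"

OBS_COLUMNS = ["group", "time", "batch", "acq_order", "replicate"]
PEAK_COLUMNS = ["mz", "rt", "mode"]


class DataValidationError(ValueError):
    """Raised when input tables violate a structural invariant."""


@dataclass
class Dataset:
    """Intensity matrix bound to observation and peak metadata.

    Attributes
    ----------
    values
        DataFrame of intensities, index = observation IDs, columns = peak IDs.
        Missing intensities are ``NaN`` (flagged, never silently zeroed).
    obs
        Observation metadata indexed by observation ID with columns
        ``group, time, batch, acq_order, replicate``.
    peaks
        Peak metadata indexed by peak ID with columns ``mz, rt, mode``.
    """

    values: pd.DataFrame
    obs: pd.DataFrame
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.obs.index.has_duplicates:
            dups = self.obs.index[self.obs.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate observation IDs: {dups}")
        if self.peaks.index.has_duplicates:
            dups = self.peaks.index[self.peaks.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate peak IDs: {dups}")
        if not self.values.index.equals(self.obs.index):
            missing = sorted(set(self.values.index) ^ set(self.obs.index))
            raise DataValidationError(
                f"intensity rows and observation metadata disagree on IDs: {missing}"
            )
        if not self.values.columns.equals(self.peaks.index):
            missing = sorted(set(self.values.columns) ^ set(self.peaks.index))
            raise DataValidationError(
                f"intensity columns and peak metadata disagree on IDs: {missing}"
            )
        acq = self.obs["acq_order"]
        if acq.duplicated().any():
            raise DataValidationError("acquisition order must be unique across the run")
        non_qc = self.obs["group"].astype(str) != QC_GROUP
        if self.obs.loc[non_qc, "time"].isna().any():
            bad = self.obs.index[non_qc & self.obs["time"].isna()].tolist()
            raise DataValidationError(f"non-QC observations missing time: {bad}")
        finite = np.isfinite(self.values.to_numpy(dtype=float))
        nan = self.values.isna().to_numpy()
        if not (finite | nan).all():
            raise DataValidationError("intensities contain non-finite, non-missing values")

    # -- convenience accessors --------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.obs)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def is_qc(self) -> pd.Series:
        return self.obs["group"].astype(str) == QC_GROUP

    @property
    def groups(self) -> list[str]:
        """Experimental groups in order of first acquisition (QC excluded)."""
        g = self.obs.loc[~self.is_qc].sort_values("acq_order")["group"]
        return list(dict.fromkeys(g))

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def with_values(self, values: pd.DataFrame) -> "Dataset":
        """New Dataset sharing metadata, with a replaced intensity matrix."""
        return Dataset(values=values, obs=self.obs.copy(), peaks=self.peaks.copy())

    def subset_obs(self, mask: pd.Series) -> "Dataset":
        return Dataset(
            values=self.values.loc[mask],
            obs=self.obs.loc[mask],
            peaks=self.peaks.copy(),
        )

    def subset_peaks(self, peak_ids: Iterable[str]) -> "Dataset":
        ids = list(peak_ids)
        return Dataset(
            values=self.values.loc[:, ids],
            obs=self.obs.copy(),
            peaks=self.peaks.loc[ids],
        )


@dataclass
class KnowledgeBase:
    """Compound, adduct and pathway reference tables.

    Attributes
    ----------
    compounds
        Indexed by compound ID; columns ``name, monoisotopic_mass`` (Da).
    adducts
        Indexed by adduct name; columns ``n`` (multimer count), ``charge``
        (signed integer), ``mass_shift`` (Da, electron correction included).
    pathways
        Long-format: columns ``pathway_id, pathway_name, compound_id``,
        one row per pathway membership.
    """

    compounds: pd.DataFrame
    adducts: pd.DataFrame
    pathways: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.compounds.index.has_duplicates:
            dups = self.compounds.index[self.compounds.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate compound IDs: {dups}")
        if (self.compounds["monoisotopic_mass"] <= 0).any():
            bad = self.compounds.index[self.compounds["monoisotopic_mass"] <= 0].tolist()
            raise DataValidationError(f"non-positive monoisotopic mass for: {bad}")
        if (self.adducts["n"] < 1).any():
            raise DataValidationError("adduct multimer count must be >= 1")
        if (self.adducts["charge"] == 0).any():
            bad = self.adducts.index[self.adducts["charge"] == 0].tolist()
            raise DataValidationError(f"adducts with zero charge: {bad}")
        if len(self.pathways):
            unknown = set(self.pathways["compound_id"]) - set(self.compounds.index)
            if unknown:
                raise DataValidationError(
                    f"pathway members reference unknown compounds: {sorted(unknown)}"
                )

    def pathway_members(self) -> dict[str, set[str]]:
        """Mapping pathway_id -> set of member compound IDs."""
        if not len(self.pathways):
            return {}
        return {
            pid: set(sub["compound_id"])
            for pid, sub in self.pathways.groupby("pathway_id", sort=True)
        }

    def pathway_names(self) -> dict[str, str]:
        if not len(self.pathways):
            return {}
        return dict(
            self.pathways.drop_duplicates("pathway_id")[
                ["pathway_id", "pathway_name"]
            ].itertuples(index=False)
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_dataset(
    intensity_path: str | Path,
    obs_meta_path: str | Path,
    peak_meta_path: str | Path,
) -> Dataset:
    """Load an intensity matrix with its observation and peak metadata.

    The intensity CSV has one observation per row and one peak per column;
    the first column holds observation IDs and the header row peak IDs.
    Blank or ``NA`` cells are kept as missing values, never zeroed.

    Raises
    ------
    DataValidationError
        On any ID mismatch between the matrix and the metadata tables, or
        duplicate observation/peak IDs (the offending IDs are listed).
    """
    values = pd.read_csv(intensity_path, index_col=0, na_values=["NA", ""])
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values = values.astype(float)

    obs = pd.read_csv(obs_meta_path, index_col=0)
    obs.index = obs.index.astype(str)
    _require_columns(obs, OBS_COLUMNS, obs_meta_path)
    obs["acq_order"] = obs["acq_order"].astype(int)
    obs["time"] = pd.to_numeric(obs["time"], errors="coerce")

    peaks = pd.read_csv(peak_meta_path, index_col=0)
    peaks.index = peaks.index.astype(str)
    _require_columns(peaks, PEAK_COLUMNS, peak_meta_path)

    # align rows to metadata order only when sets agree; mismatch -> validate error
    if set(values.index) == set(obs.index):
        values = values.loc[obs.index]
    if set(values.columns) == set(peaks.index):
        values = values.loc[:, peaks.index]
    values.index.name = "obs_id"
    values.columns.name = None
    values.columns = pd.Index(values.columns, name=None)
    return Dataset(values=values, obs=obs, peaks=peaks)


def load_knowledge_base(
    compound_path: str | Path,
    adduct_path: str | Path,
    pathway_path: str | Path | None = None,
) -> KnowledgeBase:
    """Load compound, adduct and (optionally empty) pathway tables."""
    compounds = pd.read_csv(compound_path, index_col=0)
    compounds.index = compounds.index.astype(str)
    _require_columns(compounds, ["name", "monoisotopic_mass"], compound_path)

    adducts = pd.read_csv(adduct_path, index_col=0)
    adducts.index = adducts.index.astype(str)
    _require_columns(adducts, ["n", "charge", "mass_shift"], adduct_path)
    adducts["n"] = adducts["n"].astype(int)
    adducts["charge"] = adducts["charge"].astype(int)

    if pathway_path is None:
        pathways = empty_pathways()
    else:
        pathways = pd.read_csv(pathway_path, dtype=str)
        if pathways.empty:
            pathways = empty_pathways()
        else:
            _require_columns(
                pathways.set_index(pathways.columns[0]),
                ["compound_id"],
                pathway_path,
            )
            if "pathway_name" not in pathways.columns:
                pathways["pathway_name"] = pathways["pathway_id"]
            pathways = pathways[["pathway_id", "pathway_name", "compound_id"]]
    return KnowledgeBase(compounds=compounds, adducts=adducts, pathways=pathways)


def empty_pathways() -> pd.DataFrame:
    return pd.DataFrame(columns=["pathway_id", "pathway_name", "compound_id"], dtype=str)


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# Writing (round-trip partners of the loaders)
# ---------------------------------------------------------------------------

def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a Dataset to ``intensities.csv / observations.csv / peaks.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / "intensities.csv",
        "observations": out / "observations.csv",
        "peaks": out / "peaks.csv",
    }
    ds.values.to_csv(paths["intensities"], index_label="obs_id")
    ds.obs.to_csv(paths["observations"], index_label="obs_id")
    ds.peaks.to_csv(paths["peaks"], index_label="peak_id")
    return paths


def write_knowledge_base(kb: KnowledgeBase, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.csv",
        "adducts": out / "adducts.csv",
        "pathways": out / "pathways.csv",
    }
    kb.compounds.to_csv(paths["compounds"], index_label="compound_id")
    kb.adducts.to_csv(paths["adducts"], index_label="adduct")
    kb.pathways.to_csv(paths["pathways"], index=False)
    return paths
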