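"""Putative accurate-mass peak annotation and cluster-pathway overlap.

A peak observed at m/z ``x`` in a given ionization mode is tentatively
annotated with every (compound, adduct) pair of matching polarity whose
expected ion m/z,

    m/z = (n * M + mass_shift) / |z|,

lies within a ppm tolerance of ``x`` (M = monoisotopic mass, n = multimer
count, z = charge, mass_shift includes the electron correction).  Matching by
accurate mass alone is the lowest identification tier — every annotation is
labelled "putative (MSI level 5)".  All matches within tolerance are kept: a
peak may carry several candidate compounds and a compound may explain several
peaks.

Pathway overlap then counts, per (cluster, pathway), how many annotated peaks
in the cluster match pathway members and how many distinct member compounds
those matches cover — a raw overlap score for ranking pathways against
clusters of interesting trends, not an enrichment test.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .core_data import KnowledgeBase

#: Fixed confidence label: accurate mass only, no orthogonal evidence.
CONFIDENCE_LABEL = "putative (MSI level 5)"

DEFAULT_TOL_PPM = 5.0

ANNOTATION_COLUMNS = [
    "peak_id",
    "compound_id",
    "adduct",
    "expected_mz",
    "observed_mz",
    "error_ppm",
    "confidence",
]


def expected_mz(monoisotopic_mass: float, n: int, charge: int, mass_shift: float) -> float:
    """Expected ion m/z for an adduct: (n*M + mass_shift) / |charge|."""
    if monoisotopic_mass <= 0:
        raise ValueError("monoisotopic mass must be > 0")
    if charge == 0:
        raise ValueError("adduct charge must be non-zero")
    return (n * monoisotopic_mass + mass_shift) / abs(charge)


def annotate_peaks(
    peaks: pd.DataFrame,
    kb: KnowledgeBase,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> pd.DataFrame:
    """Match peaks to compound/adduct targets by accurate m/z.

    *peaks* is the peak metadata table (index peak_id; columns ``mz, mode``).
    Adducts are matched only to peaks of their own polarity (the sign of the
    adduct charge).  Returns an annotation table with one row per
    (peak, compound, adduct) hit; the result is order-independent (sorted by
    peak_id, compound_id, adduct).
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    if kb.compounds.empty or kb.adducts.empty or peaks.empty:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)

    masses = kb.compounds["monoisotopic_mass"].to_numpy(dtype=float)
    compound_ids = kb.compounds.index.to_numpy()
    rows = []
    for adduct_name, ad in kb.adducts.iterrows():
        polarity = "+" if ad["charge"] > 0 else "-"
        targets = (ad["n"] * masses + ad["mass_shift"]) / abs(ad["charge"])
        mode = peaks["mode"].astype(str).str.strip().replace({"−": "-", "pos": "+", "neg": "-"})
        sub = peaks[mode == polarity]
        if sub.empty:
            continue
        obs = sub["mz"].to_numpy(dtype=float)
        err_ppm = 1e6 * (obs[:, None] - targets[None, :]) / targets[None, :]
        hit_i, hit_j = np.where(np.abs(err_ppm) <= tol_ppm)
        for i, j in zip(hit_i, hit_j):
            rows.append(
                {
                    "peak_id": sub.index[i],
                    "compound_id": compound_ids[j],
                    "adduct": adduct_name,
                    "expected_mz": targets[j],
                    "observed_mz": obs[i],
                    "error_ppm": err_ppm[i, j],
                    "confidence": CONFIDENCE_LABEL,
                }
            )
    out = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return out.sort_values(["peak_id", "compound_id", "adduct"]).reset_index(drop=True)


def pathway_overlap(
    model: ClusterModel,
    annotations: pd.DataFrame,
    kb: KnowledgeBase,
) -> pd.DataFrame:
    """Count pathway-member annotations per cluster.

    For each (cluster, pathway): ``n_peaks`` is the number of annotated peaks
    in the cluster matching at least one pathway member, ``n_compounds`` the
    number of distinct member compounds matched, and ``compounds`` their
    names.  Rows are sorted by n_peaks desc, n_compounds desc, pathway_id.
    Only pairs with at least one matching peak are listed.
    """
    members = kb.pathway_members()
    names = kb.pathway_names()
    compound_names = kb.compounds["name"].to_dict()

    peak_compounds: dict[str, set[str]] = {}
    if len(annotations):
        for peak_id, sub in annotations.groupby("peak_id"):
            peak_compounds[str(peak_id)] = set(sub["compound_id"])

    rows = []
    for c in range(model.k):
        cluster_peaks = {model.vectors.peak_of(l) for l in model.members(c)}
        for pid, mem in members.items():
            matched_peaks = {
                p for p in cluster_peaks if peak_compounds.get(p, set()) & mem
            }
            matched_compounds = set()
            for p in matched_peaks:
                matched_compounds |= peak_compounds[p] & mem
            if not matched_peaks:
                continue
            rows.append(
                {
                    "cluster_id": c,
                    "pathway_id": pid,
                    "pathway_name": names.get(pid, pid),
                    "n_peaks": len(matched_peaks),
                    "n_compounds": len(matched_compounds),
                    "compounds": "; ".join(
                        sorted(compound_names.get(cid, cid) for cid in matched_compounds)
                    ),
                    "compound_ids": ";".join(sorted(matched_compounds)),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "pathway_id",
            "pathway_name",
            "n_peaks",
            "n_compounds",
            "compounds",
            "compound_ids",
        ],
    )
    return out.sort_values(
        ["n_peaks", "n_compounds", "pathway_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def export_pathway_lists(overlaps: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one compound-ID list per (cluster, pathway) with matches.

    Each file holds one compound ID per line — the format accepted by the
    MetaCyc SmartTable paste-in, so perturbed pathway members can be
    highlighted in an online pathway browser.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for _, row in overlaps.iterrows():
        if row["n_compounds"] == 0:
            continue
        safe_pid = str(row["pathway_id"]).replace("/", "_").replace(" ", "_")
        path = out / f"cluster{row['cluster_id']}_{safe_pid}.txt"
        ids = sorted(str(row["compound_ids"]).split(";"))
        path.write_text("\n".join(ids) + "\n", encoding="utf-8")
        written.append(path)
    return written
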