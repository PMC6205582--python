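"""Between-batch offset and within-batch drift correction, peak scaling,
and correction-quality metrics.

LC-MS intensities shift between analytical batches and drift with acquisition
order inside a batch.  Correction subtracts (or divides by) a per-cell
correction factor ``C`` estimated from the pooled-QC injections — or, when
the QC trend does not track the samples, from a smooth trend of the
experimental samples themselves ("background" correction) — and restores the
peak to a working scale with a rescale value ``R``:

    additive        X' = X - C + R
    multiplicative  X' = X * R / C

Quality is quantified per peak by the replicate relative standard deviation,
the one-way between/within experimental-group variance ratio (F statistic),
and the mean pairwise univariate-Gaussian Bhattacharyya distance between
batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Dataset, QC_GROUP

logger = logging.getLogger(__name__)

FactorMethod = Literal["qc_mean", "qc_linear", "qc_moving_median", "background"]
Form = Literal["additive", "multiplicative"]
Rescale = Literal["qc_median", "batch_mean", "global_mean"]

#: Default moving-median window for background correction, as a fraction of
#: the batch's acquisition-order span.
BACKGROUND_WINDOW_FRACTION = 0.10


class CorrectionError(ValueError):
    """Raised for batches that cannot support the requested correction."""


@dataclass
class CorrectionFactors:
    """Per-cell correction factors C and rescale values R.

    ``C`` and ``R`` are observation x peak DataFrames aligned with the
    dataset they were estimated from (R is constant per peak, or per
    (peak, batch) for batch-level rescaling).
    """

    C: pd.DataFrame
    R: pd.DataFrame
    method: str
    form: str = "additive"

    def __post_init__(self) -> None:
        if not np.isfinite(self.R.to_numpy(dtype=float)).all():
            raise CorrectionError("non-finite rescale values R")
        if self.form == "multiplicative" and (self.C == 0).any().any():
            raise CorrectionError("multiplicative form requires all C != 0")


# ---------------------------------------------------------------------------
# Factor estimation
# ---------------------------------------------------------------------------

def correction_factors(
    ds: Dataset,
    method: FactorMethod = "qc_mean",
    window: float | None = None,
    rescale: Rescale | None = None,
    form: Form = "additive",
) -> CorrectionFactors:
    """Estimate correction factors from QC or background trends, per batch.

    Parameters
    ----------
    method
        ``qc_mean``: C is the batch's QC mean (constant per peak and batch).
        ``qc_linear``: C from the least-squares line of QC intensity against
        acquisition order, evaluated at every observation (needs >= 2 QCs
        per batch).
        ``qc_moving_median``: C from a centered moving median of the QCs over
        acquisition order (``window`` in acquisition-order units).
        ``background``: C from a moving median of the *non-QC* observations,
        tracking the experimental trend directly; default window is 10% of
        the batch's acquisition-order span.
    window
        Total moving-median window width in acquisition-order units.
    rescale
        ``qc_median`` (default for QC methods): per-peak median of the
        original QC intensities over the whole run — a batch-independent
        constant, so subtracting C and adding R actually removes the
        between-batch offsets contained in C.  ``global_mean`` (default for
        background): per-peak mean over the whole dataset.  ``batch_mean``:
        per-peak mean within the batch (note: a batch-level R re-introduces
        the batch level it contains; it preserves within-batch structure
        only).
    """
    if rescale is None:
        rescale = "global_mean" if method == "background" else "qc_median"

    X = ds.values
    is_qc = ds.is_qc
    C = pd.DataFrame(np.nan, index=X.index, columns=X.columns)
    R = pd.DataFrame(np.nan, index=X.index, columns=X.columns)
    global_mean = X.mean(axis=0, skipna=True)
    if rescale == "qc_median":
        if not is_qc.any():
            raise CorrectionError("rescale=qc_median requires QC observations")
        qc_median_global = X.loc[is_qc].median(axis=0, skipna=True)

    for batch, obs_b in ds.obs.groupby("batch", sort=False):
        rows = obs_b.index
        qc_rows = rows[is_qc.loc[rows]]
        smp_rows = rows[~is_qc.loc[rows]]
        Xb = X.loc[rows]
        acq = obs_b["acq_order"].to_numpy(dtype=float)

        if method == "qc_mean":
            _require_qcs(batch, qc_rows, 1, method)
            C.loc[rows] = np.broadcast_to(
                X.loc[qc_rows].mean(axis=0).to_numpy(), Xb.shape
            )
        elif method == "qc_linear":
            _require_qcs(batch, qc_rows, 2, method)
            C.loc[rows] = _linear_trend(
                X.loc[qc_rows].to_numpy(dtype=float),
                ds.obs.loc[qc_rows, "acq_order"].to_numpy(dtype=float),
                acq,
            )
        elif method == "qc_moving_median":
            _require_qcs(batch, qc_rows, 1, method)
            w = _resolve_window(window, acq)
            C.loc[rows] = _moving_median_trend(
                X.loc[qc_rows].to_numpy(dtype=float),
                ds.obs.loc[qc_rows, "acq_order"].to_numpy(dtype=float),
                acq,
                w,
            )
        elif method == "background":
            if len(smp_rows) < 2:
                raise CorrectionError(
                    f"batch {batch!r}: background correction needs >= 2 non-QC observations"
                )
            w = _resolve_window(window, acq)
            C.loc[rows] = _moving_median_trend(
                X.loc[smp_rows].to_numpy(dtype=float),
                ds.obs.loc[smp_rows, "acq_order"].to_numpy(dtype=float),
                acq,
                w,
            )
        else:
            raise ValueError(f"unknown correction method {method!r}")

        if rescale == "qc_median":
            r = qc_median_global
        elif rescale == "batch_mean":
            r = Xb.mean(axis=0, skipna=True)
        elif rescale == "global_mean":
            r = global_mean
        else:
            raise ValueError(f"unknown rescale {rescale!r}")
        R.loc[rows] = np.broadcast_to(r.to_numpy(), Xb.shape)

    return CorrectionFactors(C=C, R=R, method=method, form=form)


def _require_qcs(batch, qc_rows, n: int, what: str) -> None:
    if len(qc_rows) < n:
        raise CorrectionError(
            f"batch {batch!r}: {what} requires >= {n} QC observation(s), found {len(qc_rows)}"
        )


def _resolve_window(window: float | None, acq: np.ndarray) -> float:
    if window is not None:
        if window < 0:
            raise ValueError("window must be >= 0")
        return float(window)
    span = float(acq.max() - acq.min()) if len(acq) > 1 else 0.0
    return BACKGROUND_WINDOW_FRACTION * span


def _linear_trend(Y: np.ndarray, x: np.ndarray, x_eval: np.ndarray) -> np.ndarray:
    """Least-squares line of each column of Y against x, evaluated at x_eval."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)  # (2, n_peaks)
    return np.column_stack([x_eval, np.ones_like(x_eval)]) @ coef


def _moving_median_trend(
    Y: np.ndarray, x: np.ndarray, x_eval: np.ndarray, window: float
) -> np.ndarray:
    """Centered moving median of Y rows (sources at x) evaluated at x_eval.

    Falls back to the nearest source point when the window is empty at some
    evaluation position (window truncated at batch edges).
    """
    half = window / 2.0
    out = np.empty((len(x_eval), Y.shape[1]))
    for j, x0 in enumerate(x_eval):
        mask = np.abs(x - x0) <= half
        if not mask.any():
            mask = np.abs(x - x0) == np.abs(x - x0).min()
        out[j] = np.nanmedian(Y[mask], axis=0)
    return out


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def apply_correction(ds: Dataset, cf: CorrectionFactors) -> Dataset:
    """Apply correction factors: ``X - C + R`` or ``X * R / C``.

    Missing intensities must be imputed first (see :func:`impute_missing`);
    the metadata is carried over unchanged.
    """
    if not (cf.C.index.equals(ds.values.index) and cf.C.columns.equals(ds.values.columns)):
        raise CorrectionError("correction factor dimensions do not match the dataset")
    if ds.values.isna().any().any():
        n = ds.n_missing
        raise CorrectionError(
            f"{n} missing intensities present; impute (impute_missing) before correction"
        )
    if cf.form == "additive":
        corrected = ds.values - cf.C + cf.R
    elif cf.form == "multiplicative":
        if (cf.C == 0).any().any():
            raise CorrectionError("division by zero correction factor")
        corrected = ds.values * cf.R / cf.C
    else:
        raise ValueError(f"unknown form {cf.form!r}")
    return ds.with_values(corrected)


def impute_missing(ds: Dataset) -> Dataset:
    """Fill missing intensities with the (peak, group, time) median,
    falling back to the per-peak median; every filled cell is logged."""
    X = ds.values.copy()
    if not X.isna().any().any():
        return ds
    key = pd.Series(
        [f"{g}\x1f{t}" for g, t in zip(ds.obs["group"], ds.obs["time"])], index=X.index
    )
    cell_median = X.groupby(key, sort=False).transform("median")
    peak_median = X.median(axis=0, skipna=True)
    filled = X.fillna(cell_median).fillna(peak_median)
    rows, cols = np.where(X.isna().to_numpy())
    for r, c in zip(rows, cols):
        logger.info("imputed %s / %s", X.index[r], X.columns[c])
    logger.warning("imputed %d missing intensities", len(rows))
    return ds.with_values(filled)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def scale_peaks(
    ds: Dataset,
    method: Literal["auto", "pareto", "range", "vast"] = "auto",
    center: bool = True,
) -> Dataset:
    """Per-peak scaling so high-intensity peaks do not dominate the analysis.

    auto   : (x - mean) / sd            (unit variance)
    pareto : (x - mean) / sqrt(sd)      (softer; keeps some magnitude info)
    range  : (x - mean) / (max - min)
    vast   : auto * (mean / sd)         (down-weights unstable peaks)

    Zero-variance (flat) peaks cannot be scaled and are dropped with a
    logged warning — consistent with the significance filter removing flat
    profiles anyway.  Sample (ddof=1) standard deviation is used.
    """
    X = ds.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    rng_ = X.max(axis=0) - X.min(axis=0)

    flat = (sd == 0) | sd.isna() if method in ("auto", "pareto", "vast") else (rng_ == 0)
    if flat.any():
        dropped = list(X.columns[flat])
        logger.warning("dropping %d zero-variance peaks: %s", len(dropped), dropped[:10])
        keep = [c for c in X.columns if c not in set(dropped)]
        ds = ds.subset_peaks(keep)
        X, mean, sd, rng_ = ds.values, mean[keep], sd[keep], rng_[keep]

    centered = X - mean if center else X
    if method == "auto":
        scaled = centered / sd
    elif method == "pareto":
        scaled = centered / np.sqrt(sd)
    elif method == "range":
        scaled = centered / rng_
    elif method == "vast":
        scaled = centered / sd * (mean / sd)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return ds.with_values(scaled)


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

def bhattacharyya_gaussian(m1: float, v1: float, m2: float, v2: float) -> float:
    """Bhattacharyya distance between two univariate Gaussians.

    D_B = 1/4 ln( 1/4 (v1/v2 + v2/v1 + 2) ) + 1/4 (m1-m2)^2 / (v1+v2)
    """
    if v1 <= 0 or v2 <= 0:
        return float("nan")
    return 0.25 * np.log(0.25 * (v1 / v2 + v2 / v1 + 2.0)) + 0.25 * (m1 - m2) ** 2 / (
        v1 + v2
    )


@dataclass
class QualityReport:
    """Per-peak quality metrics for a dataset pair (before/after correction)."""

    per_peak: pd.DataFrame  # columns: rsd_*, f_stat_*, bhattacharyya_* x {before, after}
    summary: dict[str, float]
    flags: list[str]

    def to_csv(self, path) -> None:
        self.per_peak.to_csv(path, index_label="peak_id")


def _replicate_rsd(ds: Dataset) -> pd.Series:
    """Mean over (group, time) cells of sd/|mean| across replicates, per peak."""
    non_qc = ~ds.is_qc
    X = ds.values.loc[non_qc]
    key = pd.Series(
        [
            f"{g}\x1f{t}"
            for g, t in zip(ds.obs.loc[non_qc, "group"], ds.obs.loc[non_qc, "time"])
        ],
        index=X.index,
    )
    grouped = X.groupby(key, sort=False)
    sd = grouped.std(ddof=1)
    mean = grouped.mean()
    counts = grouped.count()
    rsd = (sd / mean.abs()).where(counts >= 2)
    return rsd.mean(axis=0, skipna=True)


def _group_f(ds: Dataset) -> pd.Series:
    """One-way ANOVA F (between/within experimental-group variance ratio)."""
    non_qc = ~ds.is_qc
    groups = ds.obs.loc[non_qc, "group"]
    pools = [ds.values.loc[non_qc].loc[groups == g] for g in groups.unique()]
    pools = [p for p in pools if len(p) >= 2]
    if len(pools) < 2:
        return pd.Series(np.nan, index=ds.values.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = stats.f_oneway(*[p.to_numpy(dtype=float) for p in pools], axis=0)
    return pd.Series(f, index=ds.values.columns)


def _batch_bhattacharyya(ds: Dataset) -> pd.Series:
    """Mean pairwise Bhattacharyya distance between batch distributions, per peak."""
    non_qc = ~ds.is_qc
    obs = ds.obs.loc[non_qc]
    X = ds.values.loc[non_qc]
    batches = list(dict.fromkeys(obs["batch"]))
    stats_per_batch = []
    for b in batches:
        sub = X.loc[obs["batch"] == b]
        if len(sub) < 2:
            continue
        stats_per_batch.append((sub.mean(axis=0), sub.var(axis=0, ddof=1)))
    if len(stats_per_batch) < 2:
        return pd.Series(np.nan, index=X.columns)
    dists = []
    for i in range(len(stats_per_batch)):
        for j in range(i + 1, len(stats_per_batch)):
            m1, v1 = stats_per_batch[i]
            m2, v2 = stats_per_batch[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                d = 0.25 * np.log(0.25 * (v1 / v2 + v2 / v1 + 2.0)) + 0.25 * (
                    m1 - m2
                ) ** 2 / (v1 + v2)
            dists.append(d)
    return pd.concat(dists, axis=1).mean(axis=1)


def correction_quality(before: Dataset, after: Dataset) -> QualityReport:
    """Quantify what a correction achieved, per peak and overall.

    Metrics (each computed on *before* and *after*): replicate RSD (raw
    intensity scale), between/within experimental-group F statistic, and the
    mean pairwise between-batch Bhattacharyya distance.  Groups or batches
    with fewer than two members are skipped and flagged.
    """
    if not before.obs.index.equals(after.obs.index):
        raise ValueError("before/after datasets must share observations")
    flags: list[str] = []
    cols = {}
    import warnings as _warnings

    with _warnings.catch_warnings():
        # metrics on underpopulated groups/batches yield all-NaN columns,
        # which numpy reports noisily; the flags below carry that information
        _warnings.simplefilter("ignore", RuntimeWarning)
        for tag, ds in (("before", before), ("after", after)):
            cols[f"rsd_{tag}"] = _replicate_rsd(ds)
            cols[f"f_stat_{tag}"] = _group_f(ds)
            cols[f"bhattacharyya_{tag}"] = _batch_bhattacharyya(ds)
            for name in ("rsd", "f_stat", "bhattacharyya"):
                if cols[f"{name}_{tag}"].isna().all():
                    flags.append(f"{name}_{tag}: not computable (insufficient members)")
        per_peak = pd.DataFrame(cols)
        summary = {
            f"median_{c}": float(per_peak[c].median(skipna=True)) for c in per_peak
        }
    return QualityReport(per_peak=per_peak, summary=summary, flags=flags)
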