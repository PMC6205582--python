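"""Significance filter: drop peaks whose profiles never leave the control
baseline, and tune the filter threshold against manual trend labels.

For each peak and each experimental group, all time points and replicates are
pooled and compared with the pooled control values by a two-sided Welch
t-test.  The smallest of these per-group p-values, ``p_min``, summarizes how
strongly the peak deviates from the control anywhere; a peak is kept for
clustering only if ``p_min <= alpha``.  No statistical conclusion is attached
to the p-values — the test is used purely as a flatness filter, so no
multiple-testing correction is applied.

The threshold ``alpha`` can be tuned against a manual classification of peaks
into clear-trend / no-clear-trend / undecided by maximizing agreement over a
fixed grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Dataset

logger = logging.getLogger(__name__)

#: Grid searched by :func:`optimize_alpha`: 0.001, 0.002, ..., 0.500.
ALPHA_GRID = np.round(np.arange(1, 501) / 1000.0, 3)

LABEL_CLEAR = "clear_trend"
LABEL_NO_CLEAR = "no_clear_trend"
LABEL_UNDECIDED = "undecided"


@dataclass
class FilterResult:
    """Per-peak filter outcome.

    ``table`` is indexed by peak ID with one ``p_<group>`` column per
    experimental group plus ``p_min`` and ``included``; ``included`` is
    exactly ``p_min <= alpha``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def p_min(self) -> pd.Series:
        return self.table["p_min"]

    @property
    def included_peaks(self) -> list[str]:
        return list(self.table.index[self.table["included"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="peak_id")


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with explicit degenerate handling.

    Zero variance in both pools: p = 1 when the means agree (flat vs flat),
    p = 0 otherwise (a deterministic shift).  Both cases are logged by the
    caller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def significance_filter(ds: Dataset, control: str, alpha: float = 0.05) -> FilterResult:
    """Flag peaks whose pooled group values never deviate from the control.

    Requires the control and at least one experimental group, each
    contributing >= 2 values per peak.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    non_qc = ~ds.is_qc
    obs = ds.obs.loc[non_qc]
    X = ds.values.loc[non_qc]
    if control not in set(obs["group"]):
        raise ValueError(f"control group {control!r} not present")
    exp_groups = [g for g in dict.fromkeys(obs["group"]) if g != control]
    if not exp_groups:
        raise ValueError("no experimental groups besides the control")

    ctrl = X.loc[obs["group"] == control].to_numpy(dtype=float)
    if ctrl.shape[0] < 2:
        raise ValueError("control group needs >= 2 observations")

    cols: dict[str, np.ndarray] = {}
    n_degenerate = 0
    for g in exp_groups:
        pool = X.loc[obs["group"] == g].to_numpy(dtype=float)
        if pool.shape[0] < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(pool, ctrl, equal_var=False, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both pools -> scipy yields nan; resolve per the
        # flat-vs-flat / deterministic-shift convention
        degenerate = np.isnan(p)
        if degenerate.any():
            eq = np.isclose(pool.mean(axis=0), ctrl.mean(axis=0))
            p[degenerate & eq] = 1.0
            p[degenerate & ~eq] = 0.0
            n_degenerate += int(degenerate.sum())
        cols[f"p_{g}"] = p
    if n_degenerate:
        logger.warning("%d zero-variance peak/group tests resolved to 0/1", n_degenerate)

    table = pd.DataFrame(cols, index=X.columns)
    table["p_min"] = table.min(axis=1)
    table["included"] = table["p_min"] <= alpha
    return FilterResult(table=table, alpha=float(alpha))


def optimize_alpha(
    p_min: pd.Series,
    labels: pd.Series,
) -> tuple[float, float]:
    """Choose alpha maximizing agreement with manual trend labels.

    *labels* take values ``clear_trend`` / ``no_clear_trend`` / ``undecided``
    (undecided peaks are ignored).  A clear-trend peak agrees when
    ``p_min <= alpha``; a no-clear-trend peak agrees when ``p_min > alpha``.
    The grid is 0.001..0.500 in steps of 0.001; ties go to the smallest
    alpha.  Returns ``(alpha, match_rate)``.
    """
    labels = labels.reindex(p_min.index)
    decided = labels.isin([LABEL_CLEAR, LABEL_NO_CLEAR])
    if not decided.any():
        raise ValueError("all labels undecided; nothing to optimize against")
    p = p_min[decided].to_numpy(dtype=float)
    is_clear = (labels[decided] == LABEL_CLEAR).to_numpy()

    # match count per grid alpha, vectorized over the grid
    included = p[None, :] <= ALPHA_GRID[:, None]  # (grid, peaks)
    matches = np.where(is_clear[None, :], included, ~included).sum(axis=1)
    best = int(np.argmax(matches))  # argmax returns first (smallest alpha) on ties
    return float(ALPHA_GRID[best]), float(matches[best] / len(p))
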