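"""Replicate collapsing, moving-window smoothing, control correction and
clustering input-vector assembly.

A peak's *time profile* for an experimental group is obtained by collapsing
the replicates at each time point (mean or median) and smoothing with a
centered moving window of fixed total width in time units.  The control
group's smoothed trend can be subtracted from the experimental groups so that
growth- and environment-driven changes shared with the control drop out.
Profiles are finally flattened into *input vectors* — one per peak
(concatenated over groups) or one per (peak, group) — which are the objects
the clustering stage groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core_data import Dataset, QC_GROUP

Stat = Literal["mean", "median"]


def _stat_fn(stat: Stat):
    if stat == "mean":
        return np.mean
    if stat == "median":
        # even neighborhood -> mean of the two central values (numpy default)
        return np.median
    raise ValueError(f"unknown stat {stat!r}")


def smooth_series(
    t: Sequence[float],
    y: Sequence[float],
    window: float,
    stat: Stat = "median",
) -> np.ndarray:
    """Centered moving-window smoother over an irregular time grid.

    Each output value is the *stat* over all input points within
    ``window / 2`` of that time point (closed interval, truncated at the
    series edges).  Output times equal input times; ``window = 0`` is the
    identity since every neighborhood contains at least the point itself.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if window < 0:
        raise ValueError("window must be >= 0")
    fn = _stat_fn(stat)
    half = window / 2.0
    out = np.empty_like(y)
    for i, t0 in enumerate(t):
        out[i] = fn(y[np.abs(t - t0) <= half])
    return out


def group_trend(
    ds: Dataset,
    group: str,
    window: float = 0.0,
    stat: Stat = "median",
) -> pd.DataFrame:
    """Smoothed per-peak time profile for one experimental group.

    Replicates at each time point are first collapsed with *stat*, then the
    collapsed series is smoothed with :func:`smooth_series`.  Returns a
    times x peaks DataFrame (index sorted ascending by time).
    """
    mask = ds.obs["group"] == group
    if not mask.any():
        raise ValueError(f"group {group!r} not present in dataset")
    sub = ds.values.loc[mask]
    times = ds.obs.loc[mask, "time"]
    collapsed = sub.groupby(times.to_numpy()).agg(stat)
    collapsed = collapsed.sort_index()
    t = collapsed.index.to_numpy(dtype=float)
    smoothed = np.column_stack(
        [smooth_series(t, collapsed[c].to_numpy(), window, stat) for c in collapsed]
    )
    return pd.DataFrame(smoothed, index=collapsed.index, columns=collapsed.columns)


def group_profiles(
    ds: Dataset,
    groups: Sequence[str] | None = None,
    window: float = 0.0,
    stat: Stat = "median",
) -> pd.DataFrame:
    """Long-format profiles (peak_id, group, time, value) for several groups."""
    if groups is None:
        groups = ds.groups
    frames = []
    for g in groups:
        trend = group_trend(ds, g, window=window, stat=stat)
        long = trend.reset_index(names="time").melt(
            id_vars="time", var_name="peak_id", value_name="value"
        )
        long["group"] = g
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[["peak_id", "group", "time", "value"]]


def control_correct(
    ds: Dataset,
    control: str,
    window: float = 0.0,
    stat: Stat = "median",
) -> Dataset:
    """Subtract the control group's smoothed trend from the experimental data.

    The trend is evaluated at the control time nearest each experimental
    observation's time; a gap beyond *window* is an error (no extrapolation
    is fabricated).  Control and QC observations are dropped from the result,
    leaving only control-corrected experimental intensities.
    """
    if not (ds.obs["group"] == control).any():
        raise ValueError(f"control group {control!r} not present in dataset")
    trend = group_trend(ds, control, window=window, stat=stat)
    control_times = trend.index.to_numpy(dtype=float)

    keep = (~ds.is_qc) & (ds.obs["group"] != control)
    exp = ds.subset_obs(keep)
    t_exp = exp.obs["time"].to_numpy(dtype=float)
    nearest_idx = np.abs(control_times[None, :] - t_exp[:, None]).argmin(axis=1)
    gaps = np.abs(control_times[nearest_idx] - t_exp)
    if (gaps > max(window, 0.0)).any():
        bad = exp.obs.index[gaps > max(window, 0.0)].tolist()
        raise ValueError(
            f"no control trend within the window for observations {bad[:10]}"
        )
    corrected = exp.values.to_numpy(dtype=float) - trend.to_numpy()[nearest_idx]
    return exp.with_values(
        pd.DataFrame(corrected, index=exp.values.index, columns=exp.values.columns)
    )


# ---------------------------------------------------------------------------
# Input vectors
# ---------------------------------------------------------------------------

@dataclass
class InputVectorSet:
    """The objects clustered: flattened per-peak (or per peak-and-group)
    time profiles sharing a common (group, time) column layout.

    Attributes
    ----------
    mode
        ``concatenated`` — one vector per peak, groups laid end to end in
        ``group_order``; groups may have different time grids.
        ``per_group`` — one vector per (peak, group); all groups must share
        one time grid so the vectors are comparable.
    matrix
        n_vectors x length float array.
    labels
        Vector labels: peak IDs (concatenated) or ``peak_id|group`` strings
        (per_group).
    layout
        One (group, time) pair per column; in per_group mode the group slot
        is ``"*"``.
    """

    mode: str
    matrix: np.ndarray
    labels: list[str]
    layout: list[tuple[str, float]]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time coordinate of each column (used for time-correlation seeding)."""
        return np.array([t for _, t in self.layout], dtype=float)

    def peak_of(self, label: str) -> str:
        return label.split("|", 1)[0]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.layout, names=["group", "time"])
        return pd.DataFrame(self.matrix, index=self.labels, columns=cols)


def build_input_vectors(
    profiles: pd.DataFrame,
    mode: Literal["concatenated", "per_group"] = "concatenated",
    group_order: Sequence[str] | None = None,
) -> InputVectorSet:
    """Assemble clustering input vectors from long-format profiles.

    *profiles* columns: ``peak_id, group, time, value`` (as produced by
    :func:`group_profiles`).  Every peak must share each group's time grid;
    ragged grids raise with the offending peaks listed.
    """
    required = {"peak_id", "group", "time", "value"}
    if not required.issubset(profiles.columns):
        raise ValueError(f"profiles must have columns {sorted(required)}")
    if group_order is None:
        group_order = list(dict.fromkeys(profiles["group"]))
    peaks = list(dict.fromkeys(profiles["peak_id"]))

    # per-group time grids, validated across peaks
    grids: dict[str, np.ndarray] = {}
    for g in group_order:
        sub = profiles[profiles["group"] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} absent from profiles")
        counts = sub.groupby("peak_id")["time"].apply(lambda s: tuple(sorted(s)))
        ref = counts.iloc[0]
        ragged = counts[counts != ref].index.tolist()
        if ragged:
            raise ValueError(f"ragged time grids in group {g!r} for peaks {ragged[:10]}")
        grids[g] = np.array(sorted(set(sub["time"])), dtype=float)

    pivots = {
        g: profiles[profiles["group"] == g]
        .pivot(index="peak_id", columns="time", values="value")
        .loc[peaks, grids[g]]
        for g in group_order
    }

    if mode == "concatenated":
        matrix = np.hstack([pivots[g].to_numpy(dtype=float) for g in group_order])
        labels = list(peaks)
        layout = [(g, float(t)) for g in group_order for t in grids[g]]
    elif mode == "per_group":
        ref = tuple(grids[group_order[0]])
        bad = [g for g in group_order if tuple(grids[g]) != ref]
        if bad:
            raise ValueError(
                f"per_group mode needs one shared time grid; groups {bad} differ"
            )
        matrix = np.vstack([pivots[g].to_numpy(dtype=float) for g in group_order])
        labels = [f"{p}|{g}" for g in group_order for p in peaks]
        layout = [("*", float(t)) for t in grids[group_order[0]]]
    else:
        raise ValueError(f"unknown vector mode {mode!r}")

    if not np.isfinite(matrix).all():
        raise ValueError("input vectors contain non-finite values")
    return InputVectorSet(mode=mode, matrix=matrix, labels=labels, layout=layout)
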