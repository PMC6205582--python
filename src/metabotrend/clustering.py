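"""Deterministic farthest-point k-means (d-k-means++), a seeded randomized
k-means baseline, and cluster-quality metrics.

Standard k-means++ seeds new centers by sampling proportionally to squared
distance from the existing centers.  The deterministic variant implemented
here replaces both sources of randomness:

1. the initial seed is chosen on the edge of the vector space — the vector
   farthest from the grand mean, or the one most correlated (in absolute
   value) with time;
2. each subsequent center is placed on the vector *farthest* from its
   nearest existing center (a parsimony rule instead of a probability), until
   either ``k`` centers exist or the space is covered (``D_max < D_stop``);
3. Lloyd refinement then alternates nearest-center assignment and
   componentwise mean (k-means) or median (k-medians) updates.

All ties — seed choice, farthest point, nearest center — break to the lowest
index, so repeated runs on the same input are bit-identical.  Distances are
Euclidean on the (already scaled) input vectors.

Model selection across ``k`` is supported by the mean silhouette width and a
spherical-Gaussian BIC; cluster tightness is summarized by the mean distance
to the assigned center ``D`` and its closest-fraction variant
(``D_closest10`` for the closest 10% of vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .time_profiles import InputVectorSet

#: Lower bound on the pooled MLE variance in the BIC; at or below it the
#: model is degenerate (e.g. k = n) and the score is flagged.
BIC_VARIANCE_FLOOR = 1e-12


@dataclass
class ClusterModel:
    """A fitted clustering of an input-vector set.

    ``distances`` holds each vector's Euclidean distance D_i to its assigned
    center; ``D`` is their mean and ``d_closest10`` the mean over the closest
    10% of vectors.  ``empty_clusters`` lists centers that lost all members
    during Lloyd refinement (kept frozen for determinism).
    """

    vectors: InputVectorSet
    centers: np.ndarray  # (k, length)
    assignment: np.ndarray  # (n,) center indices
    distances: np.ndarray  # (n,) D_i
    d_stop: float | None = None
    n_iter: int = 0
    empty_clusters: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def n(self) -> int:
        return self.vectors.n

    @property
    def D(self) -> float:
        """Mean distance to the assigned cluster center, over vectors."""
        return float(self.distances.mean())

    @property
    def d_closest10(self) -> float:
        return dispersion(self, 0.10)

    @property
    def wcss(self) -> float:
        """Within-cluster sum of squared distances."""
        return float((self.distances**2).sum())

    def members(self, c: int) -> list[str]:
        return [self.vectors.labels[i] for i in np.flatnonzero(self.assignment == c)]


def _as_matrix(vs: InputVectorSet | np.ndarray) -> np.ndarray:
    if isinstance(vs, InputVectorSet):
        return vs.matrix
    return np.asarray(vs, dtype=float)


def _pairwise_sq_to_centers(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances (n, k), computed stably."""
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def assign_nearest(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center assignment; ties break to the lowest center index."""
    d2 = _pairwise_sq_to_centers(X, centers)
    assignment = d2.argmin(axis=1)  # argmin takes the first minimum: lowest index
    dist = np.sqrt(d2[np.arange(len(X)), assignment])
    return assignment, dist


# ---------------------------------------------------------------------------
# Deterministic seeding
# ---------------------------------------------------------------------------

def select_seed(
    vs: InputVectorSet | np.ndarray,
    method: Literal["max_dist_from_mean", "max_abs_time_correlation"] = "max_dist_from_mean",
    times: Sequence[float] | None = None,
) -> int:
    """Pick the seed vector on the edge of the search space.

    ``max_dist_from_mean`` maximizes Euclidean distance to the grand mean;
    ``max_abs_time_correlation`` maximizes |Pearson r| between the vector's
    values and their time coordinates (constant vectors get r = 0).  Ties
    break to the lowest index.
    """
    X = _as_matrix(vs)
    if len(X) == 0:
        raise ValueError("no vectors")
    if method == "max_dist_from_mean":
        crit = np.linalg.norm(X - X.mean(axis=0), axis=1)
    elif method == "max_abs_time_correlation":
        if times is None:
            if not isinstance(vs, InputVectorSet):
                raise ValueError("times required for correlation seeding on raw arrays")
            times = vs.times
        t = np.asarray(times, dtype=float)
        tc = t - t.mean()
        xc = X - X.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(tc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ tc) / denom
        crit = np.abs(np.where(np.isfinite(r), r, 0.0))
    else:
        raise ValueError(f"unknown seed method {method!r}")
    return int(crit.argmax())


def farthest_point_centers(
    vs: InputVectorSet | np.ndarray,
    seed: int,
    k: int | None = None,
    d_stop: float | None = None,
) -> np.ndarray:
    """Iterative farthest-point center generation (the parsimony rule).

    Starting from the seed vector, repeatedly place a new center on the
    vector with the largest squared distance to its nearest existing center.
    Generation stops when ``k`` centers exist, or — if ``d_stop`` is given —
    as soon as every vector lies within ``d_stop`` of a center
    (``D_max < d_stop``); with both given, whichever triggers first.

    Returns the indices of the chosen center vectors, in selection order.
    """
    X = _as_matrix(vs)
    n = len(X)
    if k is None and d_stop is None:
        raise ValueError("give k, d_stop or both")
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if not 0 <= seed < n:
        raise ValueError("seed index out of range")

    chosen = [int(seed)]
    d2 = np.einsum("nd,nd->n", X - X[seed], X - X[seed])
    while True:
        if d_stop is not None and np.sqrt(d2.max()) < d_stop:
            break
        if k is not None and len(chosen) >= k:
            break
        if len(chosen) >= n:
            break
        m = int(d2.argmax())  # first maximum: lowest index on ties
        chosen.append(m)
        new_d2 = np.einsum("nd,nd->n", X - X[m], X - X[m])
        d2 = np.minimum(d2, new_d2)
    return np.array(chosen, dtype=int)


# ---------------------------------------------------------------------------
# Lloyd refinement
# ---------------------------------------------------------------------------

def lloyd_refine(
    vs: InputVectorSet | np.ndarray,
    centers: np.ndarray,
    update: Literal["mean", "median"] = "mean",
    max_iter: int = 300,
    tol: float = 1e-9,
    _wcss_trace: list[float] | None = None,
) -> ClusterModel:
    """Lloyd's algorithm from given initial centers.

    Alternates nearest-center assignment with componentwise mean (k-means)
    or median (k-medians) center updates until assignments stabilize, the
    largest center shift falls below *tol*, or *max_iter* is reached.
    A cluster that loses all members keeps its center frozen (and is
    reported in ``empty_clusters``) so the procedure stays deterministic.
    """
    X = _as_matrix(vs)
    centers = np.array(centers, dtype=float, copy=True)
    if centers.ndim != 2 or len(centers) == 0:
        raise ValueError("centers must be a non-empty 2-D array")
    assignment, dist = assign_nearest(X, centers)
    if _wcss_trace is not None:
        _wcss_trace.append(float((dist**2).sum()))
    empty: set[int] = set()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_centers = centers.copy()
        for c in range(len(centers)):
            members = assignment == c
            if not members.any():
                empty.add(c)
                continue
            if update == "mean":
                new_centers[c] = X[members].mean(axis=0)
            elif update == "median":
                new_centers[c] = np.median(X[members], axis=0)
            else:
                raise ValueError(f"unknown update {update!r}")
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        new_assignment, dist = assign_nearest(X, centers)
        if _wcss_trace is not None:
            _wcss_trace.append(float((dist**2).sum()))
        changed = (new_assignment != assignment).any()
        assignment = new_assignment
        if not changed and shift < tol:
            break
    if not isinstance(vs, InputVectorSet):
        vs = InputVectorSet(
            mode="raw",
            matrix=X,
            labels=[str(i) for i in range(len(X))],
            layout=[("*", float(j)) for j in range(X.shape[1])],
        )
    return ClusterModel(
        vectors=vs,
        centers=centers,
        assignment=assignment,
        distances=dist,
        n_iter=n_iter,
        empty_clusters=sorted(empty),
    )


def dkmeanspp(
    vs: InputVectorSet | np.ndarray,
    k: int | None = None,
    d_stop: float | None = None,
    seed_method: Literal["max_dist_from_mean", "max_abs_time_correlation"] = "max_dist_from_mean",
    update: Literal["mean", "median"] = "mean",
    max_iter: int = 300,
    tol: float = 1e-9,
    outlier_z: float | None = None,
) -> ClusterModel:
    """Full deterministic pipeline: seed, farthest-point centers, Lloyd.

    ``outlier_z``, when set, drops vectors whose distance to the grand mean
    has a z-score above the threshold *before* seeding, since the farthest-
    point rule would otherwise latch onto outliers (off by default; mainly
    useful with the mean update — the median update is robust on its own).
    """
    X = _as_matrix(vs)
    labels = vs.labels if isinstance(vs, InputVectorSet) else [str(i) for i in range(len(X))]
    if outlier_z is not None:
        d = np.linalg.norm(X - X.mean(axis=0), axis=1)
        sd = d.std(ddof=1) if len(d) > 1 else 0.0
        keep = d <= d.mean() + outlier_z * sd if sd > 0 else np.ones(len(d), bool)
        if isinstance(vs, InputVectorSet):
            vs = InputVectorSet(
                mode=vs.mode,
                matrix=X[keep],
                labels=[l for l, k_ in zip(labels, keep) if k_],
                layout=vs.layout,
            )
        else:
            vs = X[keep]
    seed = select_seed(vs, method=seed_method)
    init_idx = farthest_point_centers(vs, seed, k=k, d_stop=d_stop)
    init = _as_matrix(vs)[init_idx]
    model = lloyd_refine(vs, init, update=update, max_iter=max_iter, tol=tol)
    model.d_stop = d_stop
    return model


# ---------------------------------------------------------------------------
# Randomized baseline
# ---------------------------------------------------------------------------

def kmeans_baseline(
    vs: InputVectorSet | np.ndarray,
    k: int,
    runs: int = 100,
    rng_seed: int = 0,
    update: Literal["mean", "median"] = "mean",
    max_iter: int = 300,
) -> ClusterModel:
    """Best-of-*runs* standard k-means with uniform-random starts.

    Initial centers are drawn uniformly without replacement from the vectors;
    the run with the lowest within-cluster sum of squares wins (first such
    run on ties).  Fully reproducible from ``rng_seed``.
    """
    X = _as_matrix(vs)
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if not 1 <= k <= len(X):
        raise ValueError(f"k must be in [1, {len(X)}]")
    rng = np.random.default_rng(rng_seed)
    best: ClusterModel | None = None
    for _ in range(runs):
        idx = rng.choice(len(X), size=k, replace=False)
        model = lloyd_refine(vs, X[idx], update=update, max_iter=max_iter)
        if best is None or model.wcss < best.wcss:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def dispersion(model: ClusterModel, fraction: float = 1.0) -> float:
    """Mean distance-to-center over the closest ``ceil(fraction * n)`` vectors.

    ``fraction = 1`` gives D (the mean over all vectors); ``fraction = 0.1``
    gives the D_closest10 tightness summary.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = int(np.ceil(fraction * model.n))
    return float(np.sort(model.distances)[:m].mean())


def silhouette_width(model: ClusterModel) -> tuple[np.ndarray, float]:
    """Per-vector silhouette s = (b - a) / max(a, b) and its mean.

    ``a`` is the mean distance to co-members, ``b`` the smallest mean
    distance to another cluster; vectors in singleton clusters score 0 by
    convention.  Requires k >= 2 non-empty clusters.
    """
    X = model.vectors.matrix
    labels = model.assignment
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("silhouette requires >= 2 non-empty clusters")
    n = len(X)
    d2 = (
        np.einsum("nd,nd->n", X, X)[:, None]
        + np.einsum("nd,nd->n", X, X)[None, :]
        - 2 * (X @ X.T)
    )
    D = np.sqrt(np.maximum(d2, 0.0))
    s = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in present}
    mean_to = {c: D[:, labels == c].mean(axis=1) for c in present}
    sum_to = {c: D[:, labels == c].sum(axis=1) for c in present}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = sum_to[c][i] / (sizes[c] - 1)  # exclude self
        b = min(mean_to[o][i] for o in present if o != c)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s, float(s.mean())


def bic_score(model: ClusterModel) -> tuple[float, bool]:
    """Spherical-Gaussian BIC for model selection over k.

    All clusters share one MLE variance sigma^2 = sum(D_i^2) / (n * d);
    the classification log-likelihood is

        loglik = sum_c n_c ln(n_c / n)
               + sum_i [ -d/2 ln(2 pi sigma^2) - D_i^2 / (2 sigma^2) ]

    and BIC = loglik - (q / 2) ln n with q = k * d + 1 free parameters
    (the centers plus the shared variance).  Higher is better.  Returns
    ``(bic, degenerate)``; *degenerate* is True when the variance hits its
    floor (e.g. k = n, zero residuals), where the score is meaningless.
    """
    n, d = model.vectors.matrix.shape
    var = float((model.distances**2).sum()) / (n * d)
    degenerate = var <= BIC_VARIANCE_FLOOR
    var = max(var, BIC_VARIANCE_FLOOR)
    counts = np.bincount(model.assignment, minlength=model.k)
    nz = counts[counts > 0]
    loglik = float((nz * np.log(nz / n)).sum())
    loglik += -0.5 * n * d * np.log(2 * np.pi * var) - float(
        (model.distances**2).sum()
    ) / (2 * var)
    q = model.k * d + 1
    return loglik - 0.5 * q * np.log(n), degenerate


def sweep_k(
    vs: InputVectorSet | np.ndarray,
    k_values: Sequence[int],
    seed_method: Literal["max_dist_from_mean", "max_abs_time_correlation"] = "max_dist_from_mean",
    update: Literal["mean", "median"] = "mean",
) -> "pd.DataFrame":
    """Fit d-k-means++ across candidate k and tabulate selection metrics."""
    import pandas as pd

    rows = []
    for k in k_values:
        model = dkmeanspp(vs, k=k, seed_method=seed_method, update=update)
        bic, degenerate = bic_score(model)
        row = {
            "k": k,
            "D": model.D,
            "D_closest10": model.d_closest10,
            "wcss": model.wcss,
            "bic": bic,
            "bic_degenerate": degenerate,
        }
        if len(np.unique(model.assignment)) >= 2:
            _, row["silhouette"] = silhouette_width(model)
        else:
            row["silhouette"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")
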