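import numpy as np
import pytest

from metabotrend import (
    bic_score,
    dispersion,
    dkmeanspp,
    farthest_point_centers,
    kmeans_baseline,
    lloyd_refine,
    select_seed,
    silhouette_width,
)
from metabotrend.clustering import assign_nearest


def brute_force_farthest_points(X, seed, k=None, d_stop=None):
    """Independent O(n^2 k) oracle: recompute every distance at every step."""
    chosen = [seed]
    while True:
        d = np.array(
            [min(np.linalg.norm(x - X[c]) for c in chosen) for x in X]
        )
        if d_stop is not None and d.max() < d_stop:
            break
        if k is not None and len(chosen) >= k:
            break
        if len(chosen) >= len(X):
            break
        chosen.append(int(d.argmax()))
    return chosen


def col(vals):
    return np.asarray(vals, dtype=float)[:, None]


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def test_seed_tie_breaks_to_lowest_index():
    # distances from mean 5 are {5,4,4,5}: 0 and 10 tie -> index of 0
    assert select_seed(col([0, 1, 9, 10])) == 0


def test_single_vector_is_its_own_seed():
    assert select_seed(col([3.0])) == 0


def test_time_correlation_seed_prefers_time_like_vector():
    rng = np.random.default_rng(0)
    t = np.arange(8.0)
    X = rng.normal(0, 1, (5, 8))
    X[3] = t  # |r| = 1
    assert select_seed(X, "max_abs_time_correlation", times=t) == 3


def test_constant_vector_correlation_is_zero():
    t = np.arange(4.0)
    X = np.vstack([np.full(4, 2.0), t])
    assert select_seed(X, "max_abs_time_correlation", times=t) == 1


# ---------------------------------------------------------------------------
# farthest-point center generation
# ---------------------------------------------------------------------------

def test_farthest_point_small_example():
    idx = farthest_point_centers(col([0, 1, 9, 10]), seed=0, k=2)
    assert list(idx) == [0, 3]  # farthest from 0 is 10


def test_k_equals_n_covers_every_vector():
    X = col([0, 1, 9, 10])
    idx = farthest_point_centers(X, seed=0, k=4)
    assert sorted(idx) == [0, 1, 2, 3]
    _, dist = assign_nearest(X, X[idx])
    assert dist.max() == 0.0


def test_d_stop_halts_when_space_covered():
    # after centers {0, 10} all distances are <= 1 < 2
    idx = farthest_point_centers(col([0, 1, 9, 10]), seed=0, d_stop=2.0)
    assert list(idx) == [0, 3]


def test_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n, d = int(rng.integers(5, 60)), int(rng.integers(1, 10))
        k = int(rng.integers(1, min(8, n) + 1))
        X = rng.normal(0, 1, (n, d))
        seed = select_seed(X)
        assert list(farthest_point_centers(X, seed, k=k)) == brute_force_farthest_points(
            X, seed, k=k
        )


def test_k_larger_than_n_errors():
    with pytest.raises(ValueError):
        farthest_point_centers(col([0, 1]), seed=0, k=3)


# ---------------------------------------------------------------------------
# Lloyd refinement
# ---------------------------------------------------------------------------

def test_lloyd_hand_iteration():
    X = col([0, 1, 9, 10])
    model = lloyd_refine(X, X[[0, 3]], update="mean")
    np.testing.assert_allclose(sorted(model.centers[:, 0]), [0.5, 9.5])
    assert list(model.assignment) == [0, 0, 1, 1]


def test_centers_at_cluster_means_are_a_fixed_point():
    X = col([0, 1, 9, 10])
    start = np.array([[0.5], [9.5]])
    model = lloyd_refine(X, start, update="mean")
    np.testing.assert_allclose(model.centers, start)


def test_median_update_single_center():
    model = lloyd_refine(col([0, 1, 100]), col([0.0]), update="median")
    assert model.centers[0, 0] == pytest.approx(1.0)


def test_empty_cluster_center_is_frozen_and_flagged():
    X = col([0.0, 1.0, 2.0])
    # second center far away never wins an assignment
    model = lloyd_refine(X, np.array([[1.0], [99.0]]), update="mean")
    assert model.empty_clusters == [1]
    assert model.centers[1, 0] == pytest.approx(99.0)


def test_wcss_non_increasing_along_iterations():
    rng = np.random.default_rng(11)
    X = rng.normal(0, 1, (60, 5))
    for _ in range(10):
        init = X[rng.choice(60, size=4, replace=False)]
        trace: list[float] = []
        lloyd_refine(X, init, update="mean", _wcss_trace=trace)
        diffs = np.diff(trace)
        assert (diffs <= 1e-8 * max(trace)).all()


# ---------------------------------------------------------------------------
# baseline k-means
# ---------------------------------------------------------------------------

def test_baseline_is_reproducible_from_seed():
    rng = np.random.default_rng(5)
    X = rng.normal(0, 1, (30, 4))
    a = kmeans_baseline(X, k=3, runs=5, rng_seed=123)
    b = kmeans_baseline(X, k=3, runs=5, rng_seed=123)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    np.testing.assert_array_equal(a.centers, b.centers)


def test_baseline_finds_global_optimum_on_separated_pairs():
    model = kmeans_baseline(col([0, 1, 9, 10]), k=2, runs=10, rng_seed=0)
    np.testing.assert_allclose(sorted(model.centers[:, 0]), [0.5, 9.5])


def test_k1_center_is_grand_mean_regardless_of_seed():
    rng = np.random.default_rng(9)
    X = rng.normal(3, 2, (20, 3))
    for seed in (0, 99):
        model = kmeans_baseline(X, k=1, runs=3, rng_seed=seed)
        np.testing.assert_allclose(model.centers[0], X.mean(axis=0), atol=1e-9)


def test_dkmeans_within_5pct_of_best_of_100_random_kmeans():
    rng = np.random.default_rng(21)
    centers = rng.normal(0, 10, (4, 6))
    X = np.vstack([c + rng.normal(0, 1, (30, 6)) for c in centers])
    det = dkmeanspp(X, k=4)
    rand = kmeans_baseline(X, k=4, runs=100, rng_seed=1)
    assert det.wcss <= 1.05 * rand.wcss


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_dispersion_examples():
    X = col([0, 1, 9, 10])
    model = lloyd_refine(X, X, update="mean")  # k = n
    assert dispersion(model, 0.5) == 0.0 and model.D == 0.0

    model2 = lloyd_refine(col([0, 1, 2, 3]), col([0.0]), update="mean")
    # distances to center 1.5 are {1.5, 0.5, 0.5, 1.5}
    assert dispersion(model2, 0.5) == pytest.approx(0.5)
    assert dispersion(model2, 1.0) == pytest.approx(1.0)
    assert model2.d_closest10 <= model2.D


def test_distance_rank_dispersion_on_known_distances():
    from metabotrend import InputVectorSet
    from metabotrend.clustering import ClusterModel

    X = col([0, 1, 2, 3])
    vs = InputVectorSet(
        mode="raw", matrix=X, labels=list("abcd"), layout=[("*", 0.0)]
    )
    model = ClusterModel(
        vectors=vs,
        centers=col([0.0]),
        assignment=np.zeros(4, dtype=int),
        distances=np.array([0.0, 1.0, 2.0, 3.0]),
    )
    assert dispersion(model, 0.5) == pytest.approx(0.5)  # mean of {0, 1}
    assert dispersion(model, 1.0) == pytest.approx(1.5)


def test_silhouette_brute_force_example():
    X = col([0, 1, 10, 11])
    model = lloyd_refine(X, np.array([[0.5], [10.5]]), update="mean")
    s, mean_s = silhouette_width(model)
    assert s[0] == pytest.approx((10.5 - 1.0) / 10.5, abs=1e-4)  # 0.9048
    assert mean_s == pytest.approx(0.8997, abs=1e-4)
    assert (s <= 1.0).all()


def test_silhouette_all_singletons_is_zero_by_convention():
    X = col([0, 5, 11])
    model = lloyd_refine(X, X, update="mean")
    _, mean_s = silhouette_width(model)
    assert mean_s == 0.0


def test_silhouette_matches_sklearn_on_random_data():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, (40, 3))
    model = dkmeanspp(X, k=4)
    s, mean_s = silhouette_width(model)
    ref = sklearn_metrics.silhouette_samples(X, model.assignment)
    np.testing.assert_allclose(s, ref, atol=1e-9)


@pytest.mark.parametrize(
    "vals,expected",
    [([-1.0, 1.0], -3.5310), ([-2.0, 2.0], -4.9173)],
)
def test_bic_closed_form_examples(vals, expected):
    X = col(vals)
    model = lloyd_refine(X, np.array([[0.0]]), update="mean")
    bic, degenerate = bic_score(model)
    assert not degenerate
    assert bic == pytest.approx(expected, abs=1e-4)


def test_bic_degenerate_at_k_equals_n():
    X = col([0, 1, 2])
    model = lloyd_refine(X, X, update="mean")
    _, degenerate = bic_score(model)
    assert degenerate


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_full_pipeline_is_deterministic():
    rng = np.random.default_rng(13)
    X = rng.normal(0, 1, (80, 10))
    a = dkmeanspp(X.copy(), k=6)
    b = dkmeanspp(X.copy(), k=6)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    np.testing.assert_array_equal(a.centers, b.centers)
    assert a.D == b.D and a.wcss == b.wcss
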