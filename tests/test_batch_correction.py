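import logging

import numpy as np
import pandas as pd
import pytest

from metabotrend import (
    CorrectionFactors,
    apply_correction,
    correction_factors,
    correction_quality,
    impute_missing,
    scale_peaks,
)
from metabotrend.batch_correction import CorrectionError, bhattacharyya_gaussian
from tests.conftest import make_dataset


def qc_batch_dataset():
    """One batch, 3 QCs with intensities 8/10/12 and 3 samples."""
    return make_dataset(
        [[8.0], [10.0], [12.0], [1.0], [2.0], [3.0]],
        groups=["QC", "QC", "QC", "a", "a", "a"],
        times=[np.nan, np.nan, np.nan, 1, 2, 3],
    )


def test_qc_mean_factor_constant_per_batch():
    cf = correction_factors(qc_batch_dataset(), "qc_mean")
    assert np.allclose(cf.C.to_numpy(), 10.0)


def test_qc_linear_matches_least_squares_oracle():
    # QCs at acquisition order 1,3,5 with intensities 1,3,5 -> fitted line y = x
    ds = make_dataset(
        [[1.0], [3.0], [5.0], [7.0]],
        groups=["QC", "QC", "QC", "a"],
        times=[np.nan, np.nan, np.nan, 1],
        acq=[1, 3, 5, 4],
    )
    cf = correction_factors(ds, "qc_linear")
    # independent oracle: normal equations on the QC points
    x = np.array([1.0, 3.0, 5.0])
    y = np.array([1.0, 3.0, 5.0])
    A = np.column_stack([x, np.ones(3)])
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    assert cf.C.loc["O3", "P0"] == pytest.approx(slope * 4 + intercept)
    assert cf.C.loc["O3", "P0"] == pytest.approx(4.0)


def test_qc_trend_correction_with_qc_median_rescale():
    # drift modelled by the QC regression, removed by X - C + R with
    # R = median of the original QC intensities
    ds = make_dataset(
        [[1.0], [3.0], [5.0], [2.0], [4.0], [6.0]],
        groups=["QC", "QC", "QC", "a", "a", "a"],
        times=[np.nan, np.nan, np.nan, 1, 2, 3],
        acq=[1, 3, 5, 2, 4, 6],
    )
    cf = correction_factors(ds, "qc_linear", rescale="qc_median")
    out = apply_correction(ds, cf)
    # samples sit exactly on the QC regression line, so after X - C + R the
    # drift is gone and every sample lands on R = median(QCs) = 3
    assert np.allclose(out.values.loc[["O3", "O4", "O5"], "P0"], 3.0)


@pytest.mark.parametrize(
    "form,x,c,r,expected",
    [("additive", 10.0, 12.0, 5.0, 3.0), ("multiplicative", 10.0, 5.0, 2.0, 4.0)],
)
def test_apply_correction_formulas(form, x, c, r, expected):
    ds = make_dataset([[x], [x]], groups=["a", "a"], times=[1, 2])
    cf = CorrectionFactors(
        C=pd.DataFrame(c, index=ds.values.index, columns=ds.values.columns),
        R=pd.DataFrame(r, index=ds.values.index, columns=ds.values.columns),
        method="qc_mean",
        form=form,
    )
    out = apply_correction(ds, cf)
    assert np.allclose(out.values.to_numpy(), expected)


@pytest.mark.parametrize("form", ["additive", "multiplicative"])
def test_c_equal_r_is_identity(form):
    rng = np.random.default_rng(0)
    ds = make_dataset(rng.uniform(1, 10, (4, 3)), groups=list("aabb"), times=[1, 2, 1, 2])
    same = pd.DataFrame(7.0, index=ds.values.index, columns=ds.values.columns)
    cf = CorrectionFactors(C=same, R=same.copy(), method="qc_mean", form=form)
    out = apply_correction(ds, cf)
    np.testing.assert_allclose(out.values.to_numpy(), ds.values.to_numpy())


def test_missing_values_must_be_imputed_first():
    ds = make_dataset([[1.0], [np.nan]], groups=["a", "a"], times=[1, 2])
    cf = CorrectionFactors(
        C=pd.DataFrame(0.0, index=ds.values.index, columns=ds.values.columns),
        R=pd.DataFrame(0.0, index=ds.values.index, columns=ds.values.columns),
        method="qc_mean",
    )
    with pytest.raises(CorrectionError, match="impute"):
        apply_correction(ds, cf)
    filled = impute_missing(ds)
    assert filled.n_missing == 0
    assert filled.values.loc["O1", "P0"] == pytest.approx(1.0)  # per-peak median


def test_batch_without_enough_qcs_names_batch():
    ds = make_dataset(
        [[1.0], [2.0], [3.0]],
        groups=["QC", "a", "a"],
        times=[np.nan, 1, 2],
        batches=["B7", "B7", "B7"],
    )
    with pytest.raises(CorrectionError, match="B7"):
        correction_factors(ds, "qc_linear")


def test_additive_qc_mean_preserves_within_batch_differences():
    # C constant per (peak, batch) -> pairwise differences inside a batch survive
    rng = np.random.default_rng(3)
    ds = make_dataset(
        rng.uniform(5, 20, (8, 4)),
        groups=["QC", "a", "a", "a", "QC", "b", "b", "b"],
        times=[np.nan, 1, 2, 3, np.nan, 1, 2, 3],
        batches=["B1"] * 4 + ["B2"] * 4,
    )
    out = apply_correction(ds, correction_factors(ds, "qc_mean"))
    for batch in ("B1", "B2"):
        rows = ds.obs.index[ds.obs["batch"] == batch]
        before = np.diff(ds.values.loc[rows].to_numpy(), axis=0)
        after = np.diff(out.values.loc[rows].to_numpy(), axis=0)
        np.testing.assert_allclose(after, before, atol=1e-12)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def test_auto_scaling_gives_zero_mean_unit_sd():
    rng = np.random.default_rng(1)
    ds = make_dataset(rng.normal(50, 5, (10, 3)), groups=["a"] * 10, times=range(10))
    out = scale_peaks(ds, "auto")
    assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-9)


@pytest.mark.parametrize(
    "method,expected",
    [
        ("pareto", [-0.8409, +0.8409]),  # mean 1, sd sqrt(2), divisor 2**0.25
        ("range", [-0.5, +0.5]),
    ],
)
def test_two_point_scaling_examples(method, expected):
    ds = make_dataset([[0.0], [2.0]], groups=["a", "a"], times=[1, 2])
    out = scale_peaks(ds, method)
    np.testing.assert_allclose(out.values["P0"].to_numpy(), expected, atol=5e-5)


def test_vast_scaling_definition():
    rng = np.random.default_rng(2)
    vals = rng.normal(10, 2, (12, 1))
    ds = make_dataset(vals, groups=["a"] * 12, times=range(12))
    out = scale_peaks(ds, "vast")
    mean, sd = vals.mean(), vals.std(ddof=1)
    expected = (vals[:, 0] - mean) / sd * (mean / sd)
    np.testing.assert_allclose(out.values["P0"].to_numpy(), expected)


def test_zero_variance_peak_dropped_with_warning(caplog):
    ds = make_dataset([[1.0, 5.0], [2.0, 5.0]], groups=["a", "a"], times=[1, 2])
    with caplog.at_level(logging.WARNING):
        out = scale_peaks(ds, "auto")
    assert list(out.values.columns) == ["P0"]
    assert any("zero-variance" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

def test_bhattacharyya_closed_form():
    assert bhattacharyya_gaussian(0, 1, 0, 1) == pytest.approx(0.0)
    # means 0 and 2, equal unit variances -> (1/4) * 4 / 2 = 0.5
    assert bhattacharyya_gaussian(0, 1, 2, 1) == pytest.approx(0.5)


def test_identical_replicates_have_zero_rsd():
    vals = np.tile([[4.0, 9.0]], (6, 1))
    ds = make_dataset(
        vals,
        groups=["a"] * 3 + ["b"] * 3,
        times=[1, 1, 1, 1, 1, 1],
        replicates=["r1", "r2", "r3"] * 2,
    )
    q = correction_quality(ds, ds)
    assert np.allclose(q.per_peak["rsd_before"], 0.0)


def test_quality_flags_underpopulated_terms():
    ds = make_dataset([[1.0], [2.0]], groups=["a", "b"], times=[1, 1])
    q = correction_quality(ds, ds)
    assert q.flags  # single-member groups / batches cannot support the metrics
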