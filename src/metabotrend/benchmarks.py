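"""Reference benchmark scenarios with known ground truth.

Each function builds a simulated study exercising one pipeline property —
cluster recovery, batch-correction effectiveness, filter calibration,
annotation round-trip — runs the relevant stages, and returns the measured
quantities together with the ground-truth expectation.  They are used by the
test suite and the reproduction script, and are convenient for eyeballing
behavior on new parameter choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import annotate_peaks, expected_mz
from .batch_correction import apply_correction, correction_factors, correction_quality
from .clustering import dkmeanspp, silhouette_width
from .core_data import Dataset, KnowledgeBase
from .significance_filter import significance_filter
from .simulate import SimulationSpec, simulate_null_dataset, simulate_timecourse
from .time_profiles import build_input_vectors, group_profiles


# ---------------------------------------------------------------------------
# clustering recovery
# ---------------------------------------------------------------------------

def clustering_recovery(
    n_peaks: int = 500, noise_sd: float = 0.2, seed: int = 0
) -> dict:
    """Five well-separated trend templates; cluster the smoothed profiles.

    The template amplitude (10) against the replicate noise keeps the
    minimum between-template separation far above the noise level, so an
    exact recovery of the template partition is the expected outcome.
    Returns the template/cluster partitions, whether they match exactly (up
    to cluster relabelling), the mean silhouette, and the separation/noise
    ratio actually realized.
    """
    spec = SimulationSpec(
        n_peaks=n_peaks,
        noise_sd=noise_sd,
        n_batches=1,
        batch_offsets=(0.0,),
        qc_every=0,
        base_intensity=(100.0, 100.0),
        seed=seed,
    )
    ds, _, truth = simulate_timecourse(spec)
    profiles = group_profiles(ds, window=0, stat="median")
    vs = build_input_vectors(profiles, group_order=list(spec.groups))
    model = dkmeanspp(vs, k=5)
    _, mean_sil = silhouette_width(model)

    truth_labels = np.array([truth.template_of[p] for p in vs.labels])
    exact = _partitions_match(truth_labels, model.assignment)

    # realized separation between template centroids vs per-coordinate noise
    centroids = np.vstack(
        [vs.matrix[truth_labels == t].mean(axis=0) for t in np.unique(truth_labels)]
    )
    sep = min(
        np.linalg.norm(centroids[i] - centroids[j])
        for i in range(len(centroids))
        for j in range(i + 1, len(centroids))
    )
    return {
        "exact_recovery": exact,
        "silhouette": mean_sil,
        "separation_over_noise": sep / noise_sd if noise_sd > 0 else np.inf,
        "model": model,
        "truth_labels": truth_labels,
    }


def _partitions_match(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition (bijective relabel)."""
    fwd: dict = {}
    rev: dict = {}
    for x, y in zip(a, b):
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True


# ---------------------------------------------------------------------------
# batch-correction effectiveness
# ---------------------------------------------------------------------------

def offset_correction_ratio(seed: int = 0, n_peaks: int = 60) -> dict:
    """Constant between-batch offsets: how much of the between-batch
    Bhattacharyya distance does QC-mean correction remove?"""
    spec = SimulationSpec(
        n_peaks=n_peaks, batch_offsets=(0.0, 5.0), noise_sd=0.5, seed=seed
    )
    ds, _, _ = simulate_timecourse(spec)
    corrected = apply_correction(ds, correction_factors(ds, "qc_mean"))
    q = correction_quality(ds, corrected)
    before = q.summary["median_bhattacharyya_before"]
    after = q.summary["median_bhattacharyya_after"]
    return {"before": before, "after": after, "ratio": after / before}


def drift_correction_comparison(seed: int = 0, n_peaks: int = 60) -> dict:
    """Linear drift in one batch only (drift magnitude commonly differs
    between batches): QC-linear should beat QC-mean on residual
    between-batch Bhattacharyya distance, because a constant per-batch
    factor cannot remove the variance the drift adds to the drifting batch."""
    spec = SimulationSpec(
        n_peaks=n_peaks,
        batch_offsets=(0.0, 0.0),
        drift_slopes=(0.0, 0.12),
        noise_sd=0.3,
        seed=seed,
    )
    ds, _, _ = simulate_timecourse(spec)
    out = {}
    for method in ("qc_mean", "qc_linear"):
        corrected = apply_correction(ds, correction_factors(ds, method))
        q = correction_quality(ds, corrected)
        out[method] = q.summary["median_bhattacharyya_after"]
    return out


def background_correction_comparison(seed: int = 0, n_peaks: int = 60) -> dict:
    """QC trend decoupled from the sample trend: background correction
    (trend from the samples themselves) should yield lower replicate RSD
    than the misled QC regression."""
    spec = SimulationSpec(
        n_peaks=n_peaks,
        batch_offsets=(0.0, 0.0),
        drift_slopes=(0.1, 0.1),
        qc_tracks_drift=False,
        noise_sd=0.3,
        seed=seed,
    )
    ds, _, _ = simulate_timecourse(spec)
    out = {}
    for method in ("qc_linear", "background"):
        corrected = apply_correction(ds, correction_factors(ds, method))
        q = correction_quality(ds, corrected)
        out[method] = q.summary["median_rsd_after"]
    return out


# ---------------------------------------------------------------------------
# filter calibration
# ---------------------------------------------------------------------------

def null_retention(alpha: float, n_peaks: int = 2000, seed: int = 0) -> dict:
    """Retention rate of the flatness filter on pure-null peaks vs the
    closed form 1 - (1 - alpha)^G for G independent group tests."""
    ds = simulate_null_dataset(n_peaks=n_peaks, n_groups=3, seed=seed)
    res = significance_filter(ds, "control", alpha=alpha)
    retained = len(res.included_peaks) / n_peaks
    expected = 1.0 - (1.0 - alpha) ** 3
    se = float(np.sqrt(expected * (1 - expected) / n_peaks))
    return {"retained": retained, "expected": expected, "mc_se": se}


# ---------------------------------------------------------------------------
# annotation round trip
# ---------------------------------------------------------------------------

def annotation_roundtrip(tol_ppm: float = 5.0, seed: int = 0) -> dict:
    """Peaks placed exactly at every (compound, adduct) target must all be
    recovered at tolerance; peaks shifted by twice the tolerance, never."""
    rng = np.random.default_rng(seed)
    comp_ids = [f"C{i:02d}" for i in range(15)]
    compounds = pd.DataFrame(
        {
            "name": comp_ids,
            "monoisotopic_mass": np.sort(rng.uniform(120, 600, len(comp_ids))),
        },
        index=pd.Index(comp_ids, name="compound_id"),
    )
    from .simulate import default_adducts

    adducts = default_adducts()
    kb = KnowledgeBase(
        compounds=compounds, adducts=adducts, pathways=pd.DataFrame(
            columns=["pathway_id", "pathway_name", "compound_id"], dtype=str
        )
    )
    rows = []
    for aname, ad in adducts.iterrows():
        mode = "+" if ad["charge"] > 0 else "-"
        for cid in comp_ids:
            mz = expected_mz(
                float(compounds.loc[cid, "monoisotopic_mass"]),
                int(ad["n"]),
                int(ad["charge"]),
                float(ad["mass_shift"]),
            )
            rows.append({"mz": mz, "mode": mode, "cid": cid, "adduct": aname})
    peaks_exact = pd.DataFrame(
        {
            "mz": [r["mz"] for r in rows],
            "rt": 60.0,
            "mode": [r["mode"] for r in rows],
        },
        index=pd.Index([f"p{i:03d}" for i in range(len(rows))], name="peak_id"),
    )
    shift = np.where(np.arange(len(rows)) % 2 == 0, 1.0, -1.0) * 2 * tol_ppm * 1e-6
    peaks_shifted = peaks_exact.assign(mz=peaks_exact["mz"] * (1.0 + shift))

    ann_exact = annotate_peaks(peaks_exact, kb, tol_ppm=tol_ppm)
    ann_shifted = annotate_peaks(peaks_shifted, kb, tol_ppm=tol_ppm)

    truth = {(f"p{i:03d}", r["cid"], r["adduct"]) for i, r in enumerate(rows)}
    found = set(
        zip(ann_exact["peak_id"], ann_exact["compound_id"], ann_exact["adduct"])
    )
    recovered = len(truth & found) / len(truth)
    # shifted peaks must not match their own true target (accidental
    # matches to a different nearby target are not misses of this check)
    shifted_hits = set(
        zip(ann_shifted["peak_id"], ann_shifted["compound_id"], ann_shifted["adduct"])
    )
    false_rate = len(truth & shifted_hits) / len(truth)
    return {"recovered": recovered, "shifted_recovered": false_rate}
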