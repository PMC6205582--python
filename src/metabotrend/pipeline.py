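"""Config-driven end-to-end pipeline with cached, restartable intermediates.

A single YAML config names the input tables and an ordered set of optional
stage blocks (``correct, scale, profiles, filter, cluster, annotate,
pathways`` — import and cluster are mandatory, everything else may be
omitted).  Each stage writes its outputs under its own subdirectory of the
output directory together with a hash of everything upstream of it; rerunning
with an unchanged upstream config reuses the cached outputs, so downstream
parameters can be explored without recomputing the expensive early stages.
A ``manifest.json`` records the fully-defaulted config, per-stage hashes and
row/column counts, making every run self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_peaks, export_pathway_lists, pathway_overlap
from .batch_correction import (
    apply_correction,
    correction_factors,
    correction_quality,
    impute_missing,
    scale_peaks,
)
from .clustering import bic_score, dkmeanspp, kmeans_baseline, silhouette_width
from .core_data import Dataset, load_dataset, load_knowledge_base, write_dataset
from .significance_filter import optimize_alpha, significance_filter
from .time_profiles import build_input_vectors, group_profiles

logger = logging.getLogger(__name__)

STAGE_ORDER = ["import", "correct", "scale", "profiles", "filter", "cluster", "annotate", "pathways"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "correct": {
        "method": "qc_mean",
        "form": "additive",
        "rescale": None,
        "window": None,
    },
    "scale": {"method": "auto", "center": True},
    "profiles": {
        "control_group": None,
        "control_window": 0.0,
        "control_stat": "median",
        "window": 0.0,
        "stat": "median",
        "vector_mode": "concatenated",
    },
    "filter": {"alpha": 0.05, "optimize_alpha": False, "labels": None},
    "cluster": {
        "k": None,
        "d_stop": None,
        "seed_method": "max_dist_from_mean",
        "update": "mean",
        "baseline_runs": 0,
        "rng_seed": 0,
        "outlier_z": None,
    },
    "annotate": {"tol_ppm": 5.0},
    "pathways": {},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return normalize_config(cfg)


def normalize_config(cfg: dict) -> dict:
    """Fill defaults for every present stage; validate stage names."""
    out = {
        "inputs": dict(cfg.get("inputs", {})),
        "output_dir": cfg.get("output_dir", "metabotrend_out"),
        "seed": int(cfg.get("seed", 0)),
        "log_level": cfg.get("log_level", "INFO"),
        "stages": {},
    }
    stages = cfg.get("stages", {}) or {}
    unknown = set(stages) - set(DEFAULTS) - {"import"}
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
    if "cluster" not in stages:
        raise ValueError("the cluster stage is mandatory")
    for name in STAGE_ORDER[1:]:
        if name in stages:
            block = dict(DEFAULTS[name])
            block.update(stages[name] or {})
            out["stages"][name] = block
    return out


def _hash(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_sig(path: str | Path) -> dict:
    p = Path(path)
    return {"path": str(p), "size": p.stat().st_size, "mtime": p.stat().st_mtime_ns}


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order; returns the artifact directory.

    Any stage error aborts with the stage name and cause; outputs of stages
    that already completed are retained.
    """
    cfg = load_config(config) if not isinstance(config, dict) else normalize_config(config)
    out_dir = Path(output_dir or cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    fh = logging.FileHandler(out_dir / "run.log")
    logging.getLogger().addHandler(fh)

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "stages": {},
    }
    inputs = cfg["inputs"]
    upstream: list[Any] = [
        {k: _file_sig(v) for k, v in sorted(inputs.items()) if v},
        cfg["seed"],
    ]

    try:
        ds = load_dataset(inputs["intensities"], inputs["observations"], inputs["peaks"])
    except Exception as e:  # noqa: BLE001 - rewrapped with stage context
        raise PipelineError("import", e) from e
    kb = None
    if inputs.get("compounds") and inputs.get("adducts"):
        kb = load_knowledge_base(
            inputs["compounds"], inputs["adducts"], inputs.get("pathways")
        )
    manifest["stages"]["import"] = {"n_obs": ds.n_obs, "n_peaks": ds.n_peaks}

    stages = cfg["stages"]
    ds_raw = ds
    ds_unscaled = ds  # post-correction, pre-scaling state (filter input)
    vectors = None
    filter_result = None
    model = None
    annotations = None

    def stage_dir(name: str, block: dict) -> tuple[Path, bool]:
        """Per-stage output dir + whether a valid cache exists."""
        upstream.append({name: block})
        h = _hash(upstream)
        d = out_dir / name
        tag = d / ".hash"
        cached = tag.exists() and tag.read_text() == h
        d.mkdir(exist_ok=True)
        manifest["stages"][name] = {"hash": h, "cached": cached}
        return d, cached

    # ---- correct ---------------------------------------------------------
    if "correct" in stages:
        blk = stages["correct"]
        d, cached = stage_dir("correct", blk)
        if cached:
            logger.info("correct: reusing cached output")
            ds = load_dataset(d / "intensities.csv", d / "observations.csv", d / "peaks.csv")
        else:
            try:
                ds = impute_missing(ds)
                cf = correction_factors(
                    ds,
                    method=blk["method"],
                    window=blk["window"],
                    rescale=blk["rescale"],
                    form=blk["form"],
                )
                corrected = apply_correction(ds, cf)
                quality = correction_quality(ds, corrected)
                quality.to_csv(d / "quality.csv")
                (d / "quality_summary.json").write_text(json.dumps(quality.summary, indent=2))
                write_dataset(corrected, d)
                ds = corrected
            except Exception as e:  # noqa: BLE001
                raise PipelineError("correct", e) from e
        _finish(d, manifest, "correct", n_obs=ds.n_obs, n_peaks=ds.n_peaks)
        ds_unscaled = ds

    # ---- scale -----------------------------------------------------------
    if "scale" in stages:
        blk = stages["scale"]
        d, cached = stage_dir("scale", blk)
        if cached:
            logger.info("scale: reusing cached output")
            ds = load_dataset(d / "intensities.csv", d / "observations.csv", d / "peaks.csv")
        else:
            try:
                ds = scale_peaks(ds, method=blk["method"], center=blk["center"])
                write_dataset(ds, d)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("scale", e) from e
        _finish(d, manifest, "scale", n_obs=ds.n_obs, n_peaks=ds.n_peaks)

    # ---- profiles --------------------------------------------------------
    blk = stages.get("profiles", dict(DEFAULTS["profiles"]))
    d, cached = stage_dir("profiles", blk)
    if cached:
        logger.info("profiles: reusing cached output")
        profiles = pd.read_csv(d / "profiles.csv", dtype={"peak_id": str})
        vectors = build_input_vectors(profiles, mode=blk["vector_mode"])
    else:
        try:
            work = ds
            if blk["control_group"]:
                from .time_profiles import control_correct

                work = control_correct(
                    ds,
                    control=blk["control_group"],
                    window=blk["control_window"],
                    stat=blk["control_stat"],
                )
            profiles = group_profiles(work, window=blk["window"], stat=blk["stat"])
            profiles.to_csv(d / "profiles.csv", index=False)
            vectors = build_input_vectors(profiles, mode=blk["vector_mode"])
        except Exception as e:  # noqa: BLE001
            raise PipelineError("profiles", e) from e
    _finish(d, manifest, "profiles", n_vectors=vectors.n, vector_length=vectors.length)

    # ---- filter ----------------------------------------------------------
    if "filter" in stages:
        blk = stages["filter"]
        d, cached = stage_dir("filter", blk)
        try:
            control = stages.get("profiles", {}).get("control_group")
            if not control:
                raise ValueError("filter requires profiles.control_group")
            alpha = blk["alpha"]
            if blk["optimize_alpha"]:
                if not blk["labels"]:
                    raise ValueError("optimize_alpha requires a labels CSV")
                probe = significance_filter(ds_unscaled, control, alpha=0.5)
                labels = pd.read_csv(blk["labels"], index_col=0).iloc[:, 0]
                alpha, rate = optimize_alpha(probe.p_min, labels)
                (d / "alpha.json").write_text(json.dumps({"alpha": alpha, "match_rate": rate}))
            filter_result = significance_filter(ds_unscaled, control, alpha=alpha)
            filter_result.to_csv(d / "filter.csv")
            kept = set(filter_result.included_peaks)
            keep_mask = [vectors.peak_of(l) in kept for l in vectors.labels]
            from .time_profiles import InputVectorSet

            vectors = InputVectorSet(
                mode=vectors.mode,
                matrix=vectors.matrix[keep_mask],
                labels=[l for l, m in zip(vectors.labels, keep_mask) if m],
                layout=vectors.layout,
            )
            logger.info("filter retained %d/%d vectors", vectors.n, len(keep_mask))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("filter", e) from e
        _finish(d, manifest, "filter", n_retained=vectors.n)
    else:
        logger.info("no filter stage: all %d vectors proceed to clustering", vectors.n)

    # ---- cluster ---------------------------------------------------------
    blk = stages["cluster"]
    d, cached = stage_dir("cluster", blk)
    try:
        model = dkmeanspp(
            vectors,
            k=blk["k"],
            d_stop=blk["d_stop"],
            seed_method=blk["seed_method"],
            update=blk["update"],
            outlier_z=blk["outlier_z"],
        )
        pd.DataFrame(
            {"label": model.vectors.labels, "cluster": model.assignment, "distance": model.distances}
        ).to_csv(d / "assignments.csv", index=False)
        pd.DataFrame(model.centers).to_csv(d / "centers.csv", index_label="cluster")
        metrics = {
            "k": model.k,
            "D": model.D,
            "D_closest10": model.d_closest10,
            "wcss": model.wcss,
            "n_iter": model.n_iter,
        }
        if model.k >= 2:
            _, metrics["silhouette"] = silhouette_width(model)
            bic, degenerate = bic_score(model)
            metrics["bic"] = bic
            metrics["bic_degenerate"] = degenerate
        if blk["baseline_runs"]:
            baseline = kmeans_baseline(
                vectors, k=model.k, runs=blk["baseline_runs"], rng_seed=blk["rng_seed"]
            )
            metrics["baseline_wcss"] = baseline.wcss
            metrics["baseline_D"] = baseline.D
        (d / "metrics.json").write_text(json.dumps(metrics, indent=2))
        try:
            from .plots import cluster_small_multiples

            cluster_small_multiples(model, d / "clusters.png")
        except Exception as plot_err:  # noqa: BLE001 - plots are best-effort
            logger.warning("cluster plot failed: %s", plot_err)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cluster", e) from e
    _finish(d, manifest, "cluster", k=model.k, n_vectors=model.n)

    # ---- annotate --------------------------------------------------------
    if "annotate" in stages:
        blk = stages["annotate"]
        d, cached = stage_dir("annotate", blk)
        try:
            if kb is None:
                raise ValueError("annotate requires compound and adduct inputs")
            annotations = annotate_peaks(ds_raw.peaks, kb, tol_ppm=blk["tol_ppm"])
            annotations.to_csv(d / "annotations.csv", index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("annotate", e) from e
        _finish(d, manifest, "annotate", n_annotations=len(annotations))

    # ---- pathways --------------------------------------------------------
    if "pathways" in stages:
        blk = stages["pathways"]
        d, cached = stage_dir("pathways", blk)
        try:
            if annotations is None or kb is None:
                raise ValueError("pathways requires the annotate stage")
            overlaps = pathway_overlap(model, annotations, kb)
            overlaps.to_csv(d / "overlaps.csv", index=False)
            export_pathway_lists(overlaps, d / "compound_lists")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("pathways", e) from e
        _finish(d, manifest, "pathways", n_pairs=len(overlaps))

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logging.getLogger().removeHandler(fh)
    fh.close()
    return out_dir


def _finish(stage_dir: Path, manifest: dict, name: str, **counts) -> None:
    manifest["stages"][name].update(counts)
    (stage_dir / ".hash").write_text(manifest["stages"][name]["hash"])
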