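"""Ground-truthed simulation of multi-batch LC-MS time-course studies.

The generator emulates a plant-stress study design: several experimental
groups (one of them a control) sampled daily with a few biological replicates
per day, acquired in randomized injection order across analytical batches,
with a pooled QC injected after every few samples.  Each peak follows one of
a small set of per-group trend templates on top of a baseline intensity; the
instrument adds a per-batch offset, an optional within-batch drift along
acquisition order, and Gaussian (or log-normal) noise.

Everything injected — template membership, batch offsets, drift slopes, true
compound/adduct identities of the peaks — is returned as ground truth, so
every pipeline stage (correction, smoothing, filtering, clustering,
annotation, pathway overlap) can be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import expected_mz
from .core_data import Dataset, KnowledgeBase, QC_GROUP, empty_pathways

# Trend template families: value added to the baseline as a function of
# u = (t - t_min) / (t_max - t_min) in [0, 1].
_FAMILIES = {
    "flat": lambda u: np.zeros_like(u),
    "linear_up": lambda u: u,
    "linear_down": lambda u: -u,
    "quadratic": lambda u: 4.0 * u * (1.0 - u),  # mid-course bump
    "step": lambda u: (u >= 0.5).astype(float),
}

#: Eight frequently observed electrospray adducts (four per polarity),
#: mass shifts in Da including the electron correction.
_DEFAULT_ADDUCTS = [
    ("[M+H]+", 1, 1, 1.007276),
    ("[M+Na]+", 1, 1, 22.989218),
    ("[M+K]+", 1, 1, 38.963158),
    ("[M+NH4]+", 1, 1, 18.033823),
    ("[M-H]-", 1, -1, -1.007276),
    ("[M+Cl]-", 1, -1, 34.969402),
    ("[M+FA-H]-", 1, -1, 44.998201),
    ("[2M-H]-", 2, -1, -1.007276),
]


def default_adducts() -> pd.DataFrame:
    """The default eight-adduct table used when a study supplies none."""
    df = pd.DataFrame(_DEFAULT_ADDUCTS, columns=["adduct", "n", "charge", "mass_shift"])
    return df.set_index("adduct")


def default_templates(groups: Sequence[str], control: str, amplitude: float = 10.0):
    """Five distinguishable per-group trend templates.

    Template 0 is a null peak (flat everywhere); the others combine the
    families so that each template's concatenated profile is well separated
    from the rest.  The control group is always flat (its shared growth
    trend is added separately).
    """
    exp = [g for g in groups if g != control]
    a = amplitude

    def spread(fams):
        # cycle the family list over however many experimental groups exist
        return {g: fams[i % len(fams)] for i, g in enumerate(exp)}

    return [
        {g: ("flat", 0.0) for g in exp},
        spread([("linear_up", a), ("linear_up", a), ("flat", 0.0)]),
        spread([("linear_down", a), ("flat", 0.0), ("linear_down", a)]),
        spread([("quadratic", a), ("quadratic", a), ("quadratic", a)]),
        spread([("step", a), ("linear_down", a), ("step", a)]),
    ]


@dataclass
class SimulationSpec:
    """Study-design parameters for :func:`simulate_timecourse`.

    Defaults emulate a four-group daily time course over 13 days with three
    biological replicates, two analytical batches and a pooled QC after
    every sixth sample; intensities are on an arbitrary LC-MS-like scale
    with baseline ~100 and template amplitudes of 10.
    """

    n_peaks: int = 100
    groups: tuple[str, ...] = ("control", "drought", "fusarium", "dual")
    control_group: str = "control"
    times: tuple[float, ...] = tuple(float(t) for t in range(1, 14))
    replicates: int = 3
    control_replicates: int | None = None  # None -> same as replicates
    n_batches: int = 2
    batch_offsets: tuple[float, ...] | None = (0.0, 5.0)
    batch_offset_peak_sd: float = 0.0  # per-(batch, peak) jitter around the offset
    drift_slopes: tuple[float, ...] | None = None  # per batch, intensity / injection
    qc_every: int = 6  # one pooled QC after every qc_every samples; 0 = none
    qc_tracks_drift: bool = True  # False: QC trend no longer mirrors the samples
    noise_sd: float = 0.5
    noise: str = "gaussian"  # or "lognormal" (multiplicative)
    base_intensity: tuple[float, float] = (80.0, 120.0)
    growth_amplitude: float = 0.0  # shared linear trend in all groups incl. control
    template_amplitude: float = 10.0
    templates: list[dict] | None = None  # None -> default_templates(...)
    template_assignment: Sequence[int] | None = None  # None -> round-robin
    annotation_fraction: float = 0.5
    n_compounds: int = 20
    n_pathways: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_peaks < 1 or self.replicates < 1 or self.n_batches < 1:
            raise ValueError("counts must be >= 1")
        if self.control_replicates is not None and self.control_replicates < 1:
            raise ValueError("control_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.qc_every < 0:
            raise ValueError("qc_every must be >= 0")
        if self.control_group not in self.groups:
            raise ValueError("control group must be listed in groups")
        if self.batch_offsets is not None and len(self.batch_offsets) != self.n_batches:
            raise ValueError("need one batch offset per batch")
        if self.drift_slopes is not None and len(self.drift_slopes) != self.n_batches:
            raise ValueError("need one drift slope per batch")
        if not 0 <= self.annotation_fraction <= 1:
            raise ValueError("annotation_fraction must be in [0, 1]")
        if self.noise not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        for tpl in self.templates or []:
            for fam, _ in tpl.values():
                if fam not in _FAMILIES:
                    raise ValueError(f"unknown template family {fam!r}")


@dataclass
class GroundTruth:
    """Everything injected by the simulator, for scoring pipeline output."""

    template_of: dict[str, int]  # peak_id -> template index
    batch_offsets: dict[str, dict[str, float]]  # batch -> peak_id -> offset
    drift_slopes: dict[str, float]  # batch -> slope
    annotations: dict[str, tuple[str, str]]  # peak_id -> (compound_id, adduct)
    templates: list[dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "template_of": self.template_of,
            "batch_offsets": self.batch_offsets,
            "drift_slopes": self.drift_slopes,
            "annotations": {k: list(v) for k, v in self.annotations.items()},
            "templates": [
                {g: list(fa) for g, fa in tpl.items()} for tpl in self.templates
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _signal(tpl: Mapping[str, tuple[str, float]], group: str, u: float) -> float:
    fam, amp = tpl.get(group, ("flat", 0.0))
    return float(amp * _FAMILIES[fam](np.asarray(u)))


def simulate_timecourse(spec: SimulationSpec) -> tuple[Dataset, KnowledgeBase, GroundTruth]:
    """Generate a ground-truthed dataset, knowledge base and truth record.

    Deterministic given ``spec.seed``: the same spec always produces
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    templates = (
        spec.templates
        if spec.templates is not None
        else default_templates(spec.groups, spec.control_group, spec.template_amplitude)
    )

    peak_ids = [f"P{i:04d}" for i in range(spec.n_peaks)]
    if spec.template_assignment is not None:
        if len(spec.template_assignment) != spec.n_peaks:
            raise ValueError("template_assignment must cover every peak")
        assignment = list(spec.template_assignment)
    else:
        assignment = [i % len(templates) for i in range(spec.n_peaks)]
    if any(not 0 <= a < len(templates) for a in assignment):
        raise ValueError("template_assignment index out of range")
    base = rng.uniform(*spec.base_intensity, size=spec.n_peaks)

    # ---- knowledge base ---------------------------------------------------
    kb, peak_meta, true_ann = _make_knowledge_base(spec, peak_ids, rng)

    # ---- injection sequence ----------------------------------------------
    samples = [
        (g, t, r)
        for g in spec.groups
        for t in spec.times
        for r in range(
            spec.control_replicates
            if (g == spec.control_group and spec.control_replicates is not None)
            else spec.replicates
        )
    ]
    order = rng.permutation(len(samples))
    run: list[tuple[str, float | None, str]] = []  # (group, time, replicate label)
    since_qc = 0
    for idx in order:
        g, t, r = samples[idx]
        run.append((g, t, f"rep{r + 1}"))
        since_qc += 1
        if spec.qc_every and since_qc == spec.qc_every:
            run.append((QC_GROUP, None, "pool"))
            since_qc = 0

    n_obs = len(run)
    batch_bounds = np.linspace(0, n_obs, spec.n_batches + 1).astype(int)
    batch_of = np.empty(n_obs, dtype=int)
    for b in range(spec.n_batches):
        batch_of[batch_bounds[b] : batch_bounds[b + 1]] = b

    offsets = np.zeros((spec.n_batches, spec.n_peaks))
    if spec.batch_offsets is not None:
        offsets += np.asarray(spec.batch_offsets)[:, None]
    if spec.batch_offset_peak_sd > 0:
        offsets += rng.normal(0, spec.batch_offset_peak_sd, size=offsets.shape)
    slopes = (
        np.asarray(spec.drift_slopes, dtype=float)
        if spec.drift_slopes is not None
        else np.zeros(spec.n_batches)
    )

    t_arr = np.asarray(spec.times, dtype=float)
    t_span = t_arr.max() - t_arr.min() if len(t_arr) > 1 else 1.0

    def u_of(t: float) -> float:
        return (t - t_arr.min()) / t_span

    # pooled-QC expectation: grand mean of every (group, time) aliquot signal
    qc_signal = np.zeros(spec.n_peaks)
    for p in range(spec.n_peaks):
        tpl = templates[assignment[p]]
        vals = [
            _signal(tpl, g, u_of(t)) + spec.growth_amplitude * u_of(t)
            for g in spec.groups
            for t in spec.times
        ]
        qc_signal[p] = float(np.mean(vals))

    X = np.empty((n_obs, spec.n_peaks))
    obs_rows = []
    for i, (g, t, rep) in enumerate(run):
        b = batch_of[i]
        pos_in_batch = i - batch_bounds[b]
        drift = slopes[b] * pos_in_batch
        if g == QC_GROUP:
            signal = qc_signal
            if not spec.qc_tracks_drift:
                drift = 0.0
        else:
            u = u_of(t)
            signal = np.array(
                [
                    _signal(templates[assignment[p]], g, u)
                    + spec.growth_amplitude * u
                    for p in range(spec.n_peaks)
                ]
            )
        clean = base + signal + offsets[b] + drift
        if spec.noise == "gaussian":
            X[i] = clean + rng.normal(0, spec.noise_sd, size=spec.n_peaks)
        else:  # lognormal: multiplicative noise, keeps intensities positive
            X[i] = clean * rng.lognormal(0, spec.noise_sd, size=spec.n_peaks)
        obs_rows.append(
            {
                "obs_id": f"O{i:04d}",
                "group": g,
                "time": t if t is not None else np.nan,
                "batch": f"B{b + 1}",
                "acq_order": i + 1,
                "replicate": rep,
            }
        )

    obs = pd.DataFrame(obs_rows).set_index("obs_id")
    values = pd.DataFrame(X, index=obs.index, columns=peak_ids)
    ds = Dataset(values=values, obs=obs, peaks=peak_meta)

    truth = GroundTruth(
        template_of={pid: a for pid, a in zip(peak_ids, assignment)},
        batch_offsets={
            f"B{b + 1}": {pid: float(offsets[b, p]) for p, pid in enumerate(peak_ids)}
            for b in range(spec.n_batches)
        },
        drift_slopes={f"B{b + 1}": float(slopes[b]) for b in range(spec.n_batches)},
        annotations=true_ann,
        templates=templates,
    )
    return ds, kb, truth


def _make_knowledge_base(spec: SimulationSpec, peak_ids, rng):
    """Compounds with random masses, the default adducts, random pathways,
    and peak m/z placed exactly at true adduct targets for an annotation-
    eligible fraction of peaks (other peaks kept >= 50 ppm from any target)."""
    adducts = default_adducts()
    comp_ids = [f"C{i:03d}" for i in range(spec.n_compounds)]
    masses = np.sort(rng.uniform(120.0, 600.0, size=spec.n_compounds))
    compounds = pd.DataFrame(
        {"name": [f"compound-{cid}" for cid in comp_ids], "monoisotopic_mass": masses},
        index=pd.Index(comp_ids, name="compound_id"),
    )

    if spec.n_pathways > 0 and spec.n_compounds > 0:
        rows = []
        for j in range(spec.n_pathways):
            size = int(rng.integers(2, max(3, spec.n_compounds // 2) + 1))
            members = rng.choice(comp_ids, size=min(size, spec.n_compounds), replace=False)
            for cid in members:
                rows.append(
                    {
                        "pathway_id": f"PWY{j:03d}",
                        "pathway_name": f"pathway-{j}",
                        "compound_id": cid,
                    }
                )
        pathways = pd.DataFrame(rows)
    else:
        pathways = empty_pathways()
    kb = KnowledgeBase(compounds=compounds, adducts=adducts, pathways=pathways)

    targets = []  # (mz, mode, compound, adduct)
    for name, ad in adducts.iterrows():
        mode = "+" if ad["charge"] > 0 else "-"
        for cid in comp_ids:
            mz = expected_mz(
                float(compounds.loc[cid, "monoisotopic_mass"]),
                int(ad["n"]),
                int(ad["charge"]),
                float(ad["mass_shift"]),
            )
            targets.append((mz, mode, cid, name))

    true_ann: dict[str, tuple[str, str]] = {}
    meta_rows = []
    n_annotated = int(round(spec.annotation_fraction * spec.n_peaks))
    target_mz = np.array([t[0] for t in targets])
    for p, pid in enumerate(peak_ids):
        mode = "+" if p % 2 == 0 else "-"
        if p < n_annotated and targets:
            eligible = [t for t in targets if t[1] == mode]
            mz, _, cid, aname = eligible[int(rng.integers(len(eligible)))]
            true_ann[pid] = (cid, aname)
        else:
            while True:
                mz = float(rng.uniform(100.0, 900.0))
                if np.min(np.abs(target_mz - mz) / target_mz) * 1e6 >= 50.0:
                    break
        meta_rows.append({"peak_id": pid, "mz": mz, "rt": float(rng.uniform(30, 1200)), "mode": mode})
    peak_meta = pd.DataFrame(meta_rows).set_index("peak_id")
    return kb, peak_meta, true_ann


def simulate_null_dataset(
    n_peaks: int = 2000,
    n_groups: int = 3,
    times: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
    replicates: int = 4,
    control_replicates: int = 12,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> Dataset:
    """Null dataset for filter calibration: every group, control included,
    drawn from the same flat distribution (no trends, offsets or drift).

    The control pool is larger than each group pool by design: the
    closed-form retention rate 1 - (1 - alpha)^G assumes independent tests,
    and a large shared control pool keeps the between-test correlation
    induced by sharing it negligible.
    """
    groups = tuple(["control"] + [f"G{i + 1}" for i in range(n_groups)])
    spec = SimulationSpec(
        n_peaks=n_peaks,
        groups=groups,
        control_group="control",
        times=times,
        replicates=replicates,
        control_replicates=control_replicates,
        n_batches=1,
        batch_offsets=(0.0,),
        drift_slopes=None,
        qc_every=0,
        noise_sd=noise_sd,
        templates=[{g: ("flat", 0.0) for g in groups if g != "control"}],
        annotation_fraction=0.0,
        n_compounds=1,
        n_pathways=0,
        seed=seed,
    )
    ds, _, _ = simulate_timecourse(spec)
    return ds
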