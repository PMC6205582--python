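# Methods

This note documents the models and procedures implemented in `metabotrend`,
the defaults chosen where the underlying method leaves the choice open, and
what the simulation-based tests do and do not demonstrate.

## Data model

A study is an intensity matrix `X` (observations × peaks) with observation
metadata (experimental group, study time, analytical batch, acquisition
order, biological replicate) and peak metadata (m/z, retention time,
ionization mode).  Pooled-QC injections carry the reserved group label `QC`
and no time.  Missing intensities are kept as explicit missing values at
import; stages that require completeness refuse to run until
`impute_missing` fills them (per peak-group-time median, falling back to the
per-peak median, with every filled cell logged).  Time is in whatever unit
the metadata supplies (days in the intended use case); all smoothing windows
are in the same unit.

## Batch and drift correction

Corrections have the common form

    additive        X'_{p,b,i} = X_{p,b,i} − C_{p,b,i} + R_p
    multiplicative  X'_{p,b,i} = X_{p,b,i} · R_p / C_{p,b,i}

with the correction factor `C` estimated per batch and the rescale value `R`
restoring the peak's working scale.  Additive is the default form; the
multiplicative variant is offered for data whose batch effects are
proportional rather than level shifts (pair it with the simulator's
log-normal noise option when testing).

`C` estimators:

* `qc_mean` — the batch's QC mean; a constant per (peak, batch).
* `qc_linear` — least-squares line of QC intensity against acquisition
  order, evaluated at every observation's position; needs ≥ 2 QCs per batch.
* `qc_moving_median` — centered moving median of the QCs over acquisition
  order (window in acquisition-order units, truncated at batch edges,
  nearest-QC fallback when a window is empty).
* `background` — moving median of the *non-QC* observations themselves.
  This tracks the experimental trend directly and is the method of choice
  when the QC trend demonstrably does not follow the samples (a failure
  mode QC-based correction is known to have).  The default window is 10% of
  the batch's acquisition-order span.  The moving-median estimator is this
  package's own defined behavior for background correction.

`R` defaults to the per-peak **whole-run** QC median for the QC methods and
the per-peak global mean for background correction.  A batch-level `R`
(`rescale=batch_mean`) is available, but note that a batch-level `R`
re-introduces the batch level it contains: `C` and `R` then cancel and
between-batch offsets survive.  Removing offsets requires a
batch-independent `R`; this is why the whole-run median is the default.

Correction quality is reported per peak before and after: replicate RSD
(sd/|mean| across replicates within each group-time cell, averaged; computed
on the unscaled intensity scale), the one-way ANOVA F statistic across
experimental groups (between/within variance ratio — good correction raises
it by shrinking technical variance), and the mean pairwise between-batch
Bhattacharyya distance under a univariate Gaussian model,

    D_B = ¼ ln(¼(v₁/v₂ + v₂/v₁ + 2)) + ¼ (m₁−m₂)²/(v₁+v₂),

which should approach zero once batches are indistinguishable.  Groups or
batches with fewer than two members are skipped and flagged.

## Scaling

Per-peak scaling uses the sample (ddof = 1) standard deviation:
auto `(x−m)/s`, pareto `(x−m)/√s`, range `(x−m)/(max−min)`, and vast
`(x−m)/s · (m/s)`.  Zero-variance peaks cannot be scaled; they are dropped
with a logged warning rather than raising, since a flat peak carries no
trend information and the significance filter would remove it anyway.
Scaling may be applied before or after correction; both orderings are
deterministic and the pipeline config makes the order explicit.

## Time profiles and control correction

Group trends collapse replicates at each time point by mean or median
(median default — robust to outlier replicates), then smooth with a
centered moving window: each value becomes the statistic of all points
within half the total window width, closed interval, truncated at the
series edges (no data is fabricated beyond the series).  A window of 0 is
the identity; a window spanning the series collapses it to the global
statistic.  The median of an even neighborhood is the mean of the two
central values.

Control correction subtracts the control group's smoothed trend from every
experimental observation at replicate level, evaluating the trend at the
nearest control time; a gap larger than the window is an error rather than
an extrapolation.  Control and QC rows are dropped from the result.  The
control-trend stat/window are independent of the profile-generation
stat/window, since a smoother control trend avoids transferring control
noise into the experimental groups.

Input vectors are the flattened profiles: `concatenated` mode yields one
vector per peak with the groups laid end to end (groups may have different
time grids — e.g. 12 + 13 + 12 points concatenate to length 37);
`per_group` mode yields one vector per (peak, group) and requires a shared
grid so vectors are comparable.

## Significance filter

For each peak and experimental group, all time points and replicates are
pooled and compared to the pooled control with a two-sided Welch t-test
(unequal variances — the safe choice when group variances differ, and the
method does not specify a variant).  The per-peak summary is
`p_min = min over groups`; peaks with `p_min > α` are excluded from
clustering as flat.  The test is a flatness detector, not an inference: no
multiple-testing correction is applied and no conclusions are drawn from the
p-values.  Zero variance in both pools resolves to p = 1 when the means
agree and p = 0 otherwise, logged.

`optimize_alpha` tunes α against manual clear-trend / no-clear-trend /
undecided labels over the fixed grid 0.001…0.500 (step 0.001), maximizing
the agreement rate (clear peaks retained + unclear peaks excluded) over
decided peaks, taking the smallest α on ties.

Calibration: for G independent null tests the retained fraction is
`1 − (1−α)^G`.  Because the G groups share one control pool, the t
statistics are positively correlated with
ρ ≈ Var(mean_ctrl)/(Var(mean_ctrl)+Var(mean_grp)); the calibration fixture
therefore gives the control three times the replicates of each group
(ρ ≈ 0.25), keeping the deviation from the closed form well inside Monte
Carlo noise at 2000 peaks.  With equal pool sizes (ρ = 0.5) the closed form
overstates retention by a percent or two — worth knowing when choosing α on
real designs.

## Deterministic clustering (d-k-means++)

The clustering objects are the input vectors, compared by Euclidean
distance (the vectors are expected to be scaled already).  The k-means++
idea — spread the initial centers — is made deterministic:

1. **Seed** on the edge of the space: the vector farthest from the grand
   mean, or the one with maximal |Pearson r| against the time axis
   (constant vectors get r = 0).
2. **Farthest-point generation**: repeatedly add the vector with the
   largest (squared) distance to its nearest center — a parsimony rule in
   place of k-means++'s probability sampling.
3. **Stop** at `k` centers, or, when `D_stop` is given, as soon as
   `max_i D_i < D_stop` (the space is covered to the preferred minimum
   cluster radius); with both given, whichever triggers first.  The
   `D_stop` form means k need not be chosen in advance.
4. **Lloyd refinement**: alternate nearest-center assignment and
   componentwise mean (k-means) or median (k-medians) updates until
   assignments stabilize and the largest center shift drops below `tol`
   (default 1e-9), or `max_iter` (300).

Every tie — seed, farthest point, nearest center — breaks to the lowest
index, which is what makes repeated runs bit-identical and the determinism
claim testable.  Clusters that lose all members keep their center frozen
(and are flagged) instead of being re-seeded, again for determinism.  The
mean update makes the within-cluster sum of squares non-increasing at every
iteration; the farthest-point rule is sensitive to outliers (they are
maximally distant by definition), so an optional pre-step drops vectors
whose distance to the grand mean exceeds a z-score threshold (off by
default; the median update is robust without it).

A seeded best-of-runs randomized k-means (`kmeans_baseline`, uniform draws
of initial centers from the vectors) provides the comparison baseline; on
the packaged benchmark the deterministic pipeline's WCSS is within 5% of
best-of-100 random restarts.

Cluster-count selection and tightness:

* **Silhouette width** `s = (b−a)/max(a,b)` with Euclidean distances;
  vectors in singleton clusters score 0 by convention.
* **BIC** under a spherical Gaussian model with one pooled MLE variance
  `σ² = ΣD_i²/(nd)` (floored at 1e-12; hitting the floor flags the score as
  degenerate, e.g. k = n): classification log-likelihood with cluster
  weights, penalized by `(q/2)·ln n` with `q = k·d + 1` free parameters.
  This standard formulation is this package's choice of BIC for clustering.
* **D** (mean distance to the assigned center, over vectors — "per
  metabolite") and **D_closest10** (mean over the closest 10%), the
  tightness summaries used to compare clusterings at fixed k.

## Annotation and pathway overlap

Expected ion m/z is `(n·M + shift)/|z|` with the electron correction folded
into the adduct's mass shift.  A peak matches a (compound, adduct) pair of
its own polarity when the relative error is within the ppm tolerance
(default 5 ppm; the tolerance is a config knob, and retention time is not
used as a secondary filter).  **All** matches within tolerance are kept —
several compounds may explain one peak and one compound several peaks —
and every annotation carries the fixed label "putative (MSI level 5)":
accurate mass alone is the lowest identification confidence tier.

Pathway overlap counts, per (cluster, pathway), the annotated peaks in the
cluster matching pathway members and the distinct member compounds matched,
sorted by peak count then compound count.  It is a raw overlap ranking, not
an enrichment test — no p-value is attached.  Compound-ID lists per
(cluster, pathway) are exported one ID per line for pasting into an online
pathway browser.

## Simulator

`simulate_timecourse` emulates a multi-batch plant-stress design: by
default four groups (one control) × 13 daily time points × 3 biological
replicates, injection order randomized, one pooled QC after every 6th
sample (156 samples + 26 QCs = 182 injections), two batches split
contiguously along the run.  Peak intensity = baseline (uniform 80–120)
+ per-group template trend (flat / linear up / linear down / quadratic bump
/ step, amplitude 10) + optional shared growth trend + per-(batch, peak)
offset + per-batch drift × position-in-batch + Gaussian noise (SD 0.5
default; log-normal multiplicative noise available for testing the
multiplicative correction).  QCs follow the grand-mean signal of all
group-time aliquots, as a pooled sample would; `qc_tracks_drift=False`
decouples the QC trend from the sample trend to reproduce the scenario in
which QC-based correction fails and background correction is needed.
Compound masses, the eight-adduct table, pathway memberships and true peak
identities are generated alongside, with annotation-eligible peaks placed
exactly at their adduct m/z and the rest kept ≥ 50 ppm from any target.

What the simulator does **not** emulate: chromatographic peak shapes,
correlated noise between co-eluting peaks, intensity-dependent
(heteroscedastic) noise, missingness mechanisms, or retention-time drift.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not performance on any particular instrument's
data; on real data the correction method and α still need to be chosen by
inspecting the quality report.

## Benchmark problem sizes

The packaged benchmarks use 500 peaks for cluster recovery (5 templates,
noise SD 0.2, realized between-template separation ≈ 150× noise), 60 peaks
for the three correction scenarios, 2000 peaks for filter calibration and
120 synthetic target peaks for the annotation round trip — sizes chosen so
the whole benchmark suite runs in seconds while keeping Monte Carlo errors
small relative to the effects being measured.

## Known limitations

* Background correction's moving-median trend is a deliberately simple
  estimator; it will absorb genuine experimental trends that vary faster
  than the window.
* The BIC and silhouette formulations are the standard ones stated above;
  other formulations would rank k differently on flat spectra of profiles.
* `D_stop` is in the units of the (scaled) vectors, so its interpretation
  changes with the scaling method.
* Concatenated vectors weight groups by their number of time points;
  groups with more time points dominate the distance.
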