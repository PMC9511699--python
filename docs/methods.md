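# Methods

## The problem

When a machine-learning model is trained on medical images, the usual
independence assumption is quietly violated if several frames of the same
subject's video are used as separate training instances: consecutive frames
of one case resemble each other far more than images of different cases, so
frame-level cross-validation leaks subject identity and inflates apparent
performance.  `frameindep` implements a statistical pre-test for this
situation: it asks, before any model is trained, whether regions sampled
from two frames of the *same* case differ as much as regions sampled from
two *different* cases.

## Divergence sampling

Each rectangular ROI on each frame yields a 256-bin gray-level histogram.
Histograms are smoothed with an additive pseudocount (default `1e-6` per
bin, then renormalized) so that Kullback–Leibler terms are always defined;
the paper-silent smoothing choice only matters in the 10th decimal of JS
for ROIs of practical size.  Divergence between two histograms P, Q is
Jensen–Shannon divergence in log base 2,

    JS(P, Q) = ½ KL(P‖M) + ½ KL(Q‖M),   M = ½(P + Q),

which is symmetric, zero iff P = Q, and bounded in [0, 1].

Two pair populations are sampled per group:

* **intra-case** — ROI *k* on frame *t* against the same ROI id on frame
  *t + Δ*, for every admissible *t* and every shift Δ = 1..F−1, giving
  (F−Δ)·R samples per shift per case.  Pairing the *same* roi_id isolates
  temporal from spatial divergence; cross-ROI intra pairs would conflate
  the two.
* **inter-case** — (case, frame, ROI) slots drawn uniformly at random
  (with replacement) across all ordered pairs of distinct cases of the same
  group, capped at `max_pairs` (default 2000) and reproducible from a seed.
  Pairs are restricted to one pathology group because the question is
  whether *within-group* subjects are interchangeable as training
  instances.

Each sampled pair counts as one observation in the test below.  This
mirrors the source workflow but is a known pseudo-replication caveat: JS
samples sharing a frame or a case are themselves correlated, so the
nominal n overstates the information content and p-values are
anti-conservative in absolute terms.  The tool is used comparatively
(intra vs inter populations built the same way), which limits but does not
remove the issue.

## The noninferiority test

With M₁/σ₁/n₁ the inter-case JS mean/SD/count and M₂/σ₂/n₂ the intra-case
ones, the hypotheses are

    H₀: M₁ − M₂ ≥ δ   (intra divergence meaningfully lower → dependent)
    H₁: M₁ − M₂ < δ   (within the margin → independent)

with margin δ = 0.05·M₁ ("no more than a 5% reduction in intra-divergence
is acceptable").  The statistic is the pooled two-sample t,

    t = (M₁ − M₂ − δ) / (s_p √(1/n₁ + 1/n₂)),
    s_p² = [(n₁−1)σ₁² + (n₂−1)σ₂²] / (n₁ + n₂ − 2),

with df = n₁ + n₂ − 2 and one-sided p = P(T_df ≤ t); p < α (default 0.05)
declares the frames independent.  A Welch (unpooled) variant is available
(`welch=True`).  With δ = 0 the procedure reduces exactly to the standard
one-sided pooled t-test, which the test suite verifies against scipy on
random configurations.  Degenerate inputs (zero pooled variance) are
flagged and decided by the sign of M₁ − M₂ − δ.

## Shift curves and period estimation

The mean intra-case JS at each shift Δ forms the shift curve.  Periodic
physiological motion (breathing) makes this curve oscillate: regions
sampled in phase diverge less than regions sampled half a period apart.
`estimate_period` linearly detrends the mean-JS sequence (slow divergence
drift would both mask the oscillation and drag the autocorrelation peak),
computes the unbiased autocorrelation, and reports the first local maximum
at lag ≥ 2 exceeding 2/√L (the conventional white-noise band), refined by
parabolic interpolation.  The threshold is a per-lag band: scanning many
lags of a pure-noise curve can exceed it by chance, so a reported period
should be read together with the curve itself.  Cohort-level estimates
pool per-case curves weighted by their pair counts
(`pool_shift_curves`).

## Texture features

Six per-ROI/per-case features support the downstream classification
stage: echo intensity (ROI mean), internal heterogeneity (within-ROI
population SD), case heterogeneity (population SD of ROI means across all
frames and ROIs of a case), GLNU and RLNU from the gray-level run-length
matrix, and first-order histogram entropy in bits.  Conventions that the
source description leaves open and that are fixed here:

* all standard deviations use the population (divisor n) convention;
* run-length quantization uses G = 16 equal-width bins over [0, 255]
  (configurable), horizontal and vertical directions averaged;
* GLNU = Σᵢ(Σⱼ R(i,j))²/N², RLNU = Σⱼ(Σᵢ R(i,j))²/N² — the classic
  Galloway nonuniformities divided by the squared run count N², which
  bounds both in (0, 1] and matches the ~0.2–0.4 scale of published liver
  values;
* entropy is first-order histogram entropy over the raw 256 levels; the
  common alternative (co-occurrence entropy) measures a different
  quantity, and the choice is recorded here rather than silently made.

## Classification harness

Leave-one-out (round-robin) cross-validation scores every instance with a
model trained on all other instances.  Logistic regression (standardized
features, effectively unregularized — C = 10⁴ ridge for solver stability)
handles two-class tasks; a 100-tree random forest (√p features per split,
seeded) handles multicategory one-vs-rest tasks.  All preprocessing is fit
inside each training fold.  AUC uses the Mann–Whitney midrank definition
(ties ½); the reported sensitivity/specificity operating point maximizes
Youden's J, since published single Sn/Sp values rarely state their
threshold rule.  Instances are per-ROI rows by default — deliberately
reproducing the leakage-prone practice the divergence test audits —
with `aggregate_by_case` available for the honest case-level alternative.
Group-difference tables use unpaired two-sided t-tests and one-way ANOVA;
a paired test is not applicable to independent animal groups.

## The synthetic phantom

No public dataset accompanies the method, so every claim is exercised on
a synthetic speckle phantom that reproduces the *statistical* structure
the analysis assumes — not acoustic physics.  Frame t of a case is

    clip₀…₂₅₅( base + ρ·persistent + √(1−ρ²)·fresh_t
               + A(t)·sin(2πt/T) + drift·t )

* `base = μ_group + N(0, σ_between)` — the case's global mean;
* `persistent` — one speckle field fixed per case; `fresh_t` — a new
  field per frame; ρ ∈ [0, 1] is the within-case frame correlation, the
  parameter the independence test must recover;
* `A(t) = breath_amplitude·amp_growth^(t/T)` — respiratory modulation
  with period T (default 35 frames = 4.5 s at 7.78 Hz) whose amplitude
  grows over successive cycles, matching the observed growth of the
  divergence oscillation;
* `drift·t` — slow monotone intensity drift.

Each speckle field is the sum of a **fine** component — mean-zero rescaled
multiplicative gamma noise (shape 4), SD `sigma_within` — and a **smooth
structural** component — Gaussian-filtered noise (correlation length
`struct_scale_px` = 8 px), SD `sigma_structure` — emulating regional
tissue heterogeneity.

The structural component is essential, and its absence is the phantom's
most instructive failure mode: 256-bin *value* histograms cannot see
pixel-level texture persistence once the uncorrelated jitter between two
frames exceeds the 1-gray-level bin width (at ρ = 0.9 and σ_within ≈ 13
the jitter is ≈ 6 levels), so a phantom with purely fine speckle shows
nearly identical intra-divergence at ρ = 0 and ρ = 0.9.  What region
histograms *do* see is each region's mean offset.  Giving the ρ-mixed
fields a smooth regional component makes those offsets persist exactly
when frames are correlated: at ρ near 1 corresponding regions share their
offsets (intra ≪ inter), at ρ = 0 the offsets regenerate every frame
(intra ≈ inter).  The same reasoning explains why `sigma_between` must be
small (default 0.5): a large frame-constant case offset would separate
intra from inter divergence *regardless* of ρ, conflating case identity
with frame dependence.  Similarly `sigma_within` is held fixed within a
group; per-case spread of the texture variance would add a ρ-independent
inter-case divergence term.

Group presets (`presets/table1.yaml`) put μ at the published liver-scale
echo-intensity means (normal 25.4 / steatosis 34.7 / fibrosis 55.9) and
σ_within at the internal-heterogeneity means (13.2 / 12.0 / 16.3).
σ_structure (6 / 7 / 10) follows the published regional-heterogeneity
*ordering* (fibrosis > steatosis > normal) at roughly half its scale —
full scale would push several percent of the low-mean normal group below
gray level 0.  With the defaults ≲ 2% of normal-group pixels clip at 0
and none at 255.  `breath_amplitude` = 4 gray levels, `amp_growth` = 1.15
per cycle and `drift` = 0.02/frame have no published values; they are
phantom parameters chosen to make the periodicity clearly detectable at
phantom scale, not estimates of any real acquisition.

What the phantom does **not** model: tissue displacement (breathing is an
intensity modulation, not motion), point-spread functions, attenuation,
scan geometry, per-case texture-variance variation, ROI placement error.
Passing tests therefore show that the statistical machinery recovers the
dependence structure it is pointed at — not that real ultrasound data
behave like the phantom.

## Problem sizes used in the automated checks

Parameter-recovery runs use 3 groups × 4 cases × 60 frames × 5 ROIs
(96×96 frames, 24×24 ROIs), pooling all shifts for intra pairs and 2000
inter pairs per group, over 20 replicate seeds per ρ; recovery is the
fraction of (replicate, group) decisions.  Period-recovery runs use
single-group cohorts of 4 cases × 120 frames — about 3.4 breathing
cycles, the shortest clip length at which the lag-35 autocorrelation peak
is stably inside the scanned range (the 60-frame default yields fewer
than two cycles in the shift curve and the estimate degrades).
Classification checks use 6 frames per case (360 per-ROI instances), a
size at which leave-one-out forests run in seconds.  These sizes are the
package's chosen verification scale; all of them are plain `PhantomConfig`
fields.

## Known limitations

* Observation-level pseudo-replication in the noninferiority test (above).
* The 2/√L period-significance band is per-lag, not family-wise.
* The per-ROI instance convention in the ML stage is intentionally
  leakage-prone; it is the behavior under audit, not a recommendation.
* JS magnitudes depend on ROI size through histogram sampling noise, so
  absolute divergence values are not comparable across ROI geometries —
  only intra-vs-inter contrasts built with the same geometry are.
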