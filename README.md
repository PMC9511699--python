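# frameindep

**Are sequential image frames from the same subject independent enough to
be used as separate machine-learning training instances?**

Medical-imaging datasets are chronically small, so a common workaround is
to treat every frame of a subject's video (ultrasound cine loop, cardiac
sequence, …) as its own training example.  If frames of one subject
resemble each other more than images of different subjects, frame-level
cross-validation leaks subject identity and the reported model
performance is inflated.  `frameindep` implements a statistical pre-test
for exactly this question, aimed at quantitative-imaging and radiomics
researchers.

## The test

For each region of interest (ROI) on each frame, build a smoothed 256-bin
gray-level histogram.  Measure Jensen–Shannon (JS) divergence — symmetric,
bounded in [0, 1] with log base 2 — between histogram pairs drawn two
ways within each pathology group:

* **intra-case**: the same ROI on frames *t* and *t + Δ* of one case, for
  every possible time shift Δ;
* **inter-case**: ROIs drawn from two different cases.

With M₁ the inter-case mean divergence and M₂ the intra-case mean, a
one-sided noninferiority t-test with margin δ = 0.05·M₁ asks whether
intra-case divergence is *at most marginally* lower than inter-case
divergence:

    H₀: M₁ − M₂ ≥ δ,   t = (M₁ − M₂ − δ) / (s_p √(1/n₁ + 1/n₂)),
    df = n₁ + n₂ − 2,   p = P(T_df ≤ t)

p < 0.05 rejects H₀: regions of the same case diverge (almost) as much as
regions of different cases, so the frames may be treated as independent
instances.  The divergence-vs-shift curve additionally exposes periodic
structure (breathing motion) via an autocorrelation period estimate, and a
texture-feature + leave-one-out classification harness reproduces the
modeling workflow the test is meant to audit (echo intensity,
heterogeneity, internal heterogeneity, GLNU, RLNU, entropy; logistic
regression and random forests; Mann–Whitney AUC with Youden operating
points).

Because the method's original in-vivo data are not public, the package
ships a synthetic B-mode-like speckle phantom with controllable
frame-to-frame correlation ρ, group-dependent intensity/heterogeneity,
periodic respiratory modulation and drift — so every claim is testable
end to end.  See `docs/methods.md` for the model and its limitations.

## Worked example

Simulate a strongly correlated cohort (ρ = 0.9, liver-scale presets) and
run the full pipeline (≈ 3 min, dominated by the leave-one-out forests):

```sh
cat > example.yaml <<'YAML'
groups:
  normal:    {mu: 25.4, sigma_within: 13.2, sigma_structure: 6.0}
  steatosis: {mu: 34.7, sigma_within: 12.0, sigma_structure: 7.0}
  fibrosis:  {mu: 55.9, sigma_within: 16.3, sigma_structure: 10.0}
cases_per_group: 4
frames_per_case: 12
rho: 0.9
seed: 7
YAML
frameindep simulate --preset example.yaml --out ex_cohort
frameindep analyze --cohort ex_cohort --out ex_out --seed 1
frameindep report --dir ex_out
```

```
# Intra- vs inter-case JS divergence

| group | intra (mean ± sd) | inter (mean ± sd) | p | independent |
|---|---|---|---|---|
| fibrosis | 0.0834 ± 0.0216 | 0.1055 ± 0.0454 | 1 | no |
| normal | 0.0634 ± 0.0193 | 0.0956 ± 0.0562 | 1 | no |
| steatosis | 0.0673 ± 0.0230 | 0.1110 ± 0.0698 | 1 | no |

# Classification (leave-one-out)

| task | AUC | Sn % | Sp % | n |
|---|---|---|---|---|
| disease_vs_normal | 0.977 | 91.2 | 91.7 | 720 |
| fibrosis_vs_rest | 1.000 | 100.0 | 100.0 | 720 |
| normal_vs_rest | 0.996 | 99.6 | 95.4 | 720 |
| steatosis_vs_rest | 0.996 | 95.8 | 97.3 | 720 |
```

Read together, the two tables are the package's point: per-ROI
classification looks excellent (AUC ≥ 0.98 everywhere), yet every group
*fails* the independence test (p = 1: intra-case divergence is well below
inter-case divergence, because ρ = 0.9 makes frames of one case resemble
each other).  Those AUCs therefore cannot be trusted as subject-level
performance.  Rerunning the simulation with `rho: 0` flips the picture:
intra- and inter-case divergences coincide and the groups pass the test
(normal p ≈ 0.018, fibrosis p ≈ 0.011; steatosis stays borderline at
p ≈ 0.064 — a 12-frame clip is near the power floor, and the rate climbs
above 90% at the 60-frame default used by `scripts/acceptance.py`).  The
bundled full-scale preset is available as `--preset table1`;
periodicity analysis needs
longer clips (the 35-frame breathing period is only resolvable with a few
cycles per clip, e.g. `frames_per_case: 120`).

The same functionality is available as a library (`import frameindep`):
`read_sequence`/`read_rois` ingest PNG/TIFF stacks with CSV/JSON ROI
specs, `extract_features`, `intra_pairs`/`inter_pairs`/`shift_curve`/
`estimate_period`, `equivalence_t_test`, `loo_cv_scores`/`roc_auc`, and
the `phantom` module generate everything the CLI uses.

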