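# Methods

## What the pipeline computes

`petreach` analyzes a paired small-animal [^18F]FDG-PET experiment in a
rat photothrombotic-stroke model with subthalamic deep-brain stimulation
(DBS), together with the accompanying behavioral and structural
endpoints:

1. **Regional PET contrast.** Each animal is scanned once without and
   once with stimulation. Regional mean activities (kBq/cm³, from atlas
   VOIs or a pre-tabulated TSV) are normalized per scan to a reference
   region, and the per-animal ratio
   `r_a = stimulated / unstimulated` (cerebellum-normalized) is formed
   per region. The effect measure is `Δratio% = (mean_a r_a − 1) × 100`,
   with a percentile bootstrap confidence interval over animals; a
   region is called significant when the CI excludes 1.0.
2. **Skilled reaching.** Per-reach 0/1 scoring of the single-pellet
   reaching task; post-stroke session scores are normalized to the last
   pre-intervention score; arms (stimulated vs sham) are compared with
   the exact Mann–Whitney U test.
3. **Lesion volumetry.** Planimetric volume: summed traced slice areas
   times slice thickness; arms compared by pooled two-sample t-test.

## Reference-region normalization

The reference region is selected as the region whose standardized uptake
value (SUV = activity ÷ (injected dose / body weight), density 1 g/cm³)
has the lowest coefficient of variation across all scans. CV rather than
raw sd is used because regions differ in mean uptake; ties break
lexicographically so selection is deterministic. Because a per-scan
global factor (dose, uptake efficiency, scanner calibration) multiplies
every region of a scan, dividing by the within-scan reference value
removes it exactly; the pipeline's contrast is therefore invariant to
rescaling any scan by a positive constant (verified by test).

Ratios are formed within animal (the paired reading of the two scan
sessions). The alternative — ratio of group means — is not the default
because it discards the pairing; per-animal ratios feed the bootstrap
with n = number of animals.

## Bootstrap confidence intervals

The CI is the percentile interval: B resamples of the n per-animal
ratios drawn with replacement, the mean of each resample, and the
empirical α/2 and 1−α/2 quantiles of those B means (defaults
B = 10,000, α = 0.05). Quantiles use linear interpolation between order
statistics (the "type 7" rule); the exact enumeration oracle
(`exact_resample_ci`) applies the same rule to the full set of nⁿ
equiprobable resamples, so the Monte-Carlo interval converges to it as B
grows. Significance uses the closed-interval convention: an interval
touching 1.0 exactly is *not* significant.

Known calibration properties, measured by this package's own tests:

- At n = 20 (mean-one lognormal ratios, log-sd 0.1) the CI-excludes-1.0
  rule fires in about 7.2% of null datasets at α = 0.05 — the familiar
  mild anticonservatism of percentile intervals at moderate n (z-vs-t
  critical values plus the 1/n narrowness bias).
- At n = 4 only 256 distinct resamples exist and the rule is markedly
  anticonservative (null rate ≈ 21%). Small-cohort significance calls
  should be read accordingly; the exact oracle makes the coarseness
  explicit.

No multiplicity correction is applied across regions; reports state the
number of regions tested.

## Rank and t tests

`mann_whitney_u` computes U from midrank sums. The p-value is exact by
full enumeration of all C(n1+n2, n1) group assignments whenever that
count is at most 200,000 — ties included, since the assignment set *is*
the exact permutation distribution — which covers the study's 8-vs-8
comparisons (12,870 assignments). Larger problems use a seeded
random-permutation estimate with ≥ 100,000 permutations and add-one
smoothing. Two-sided p doubles the smaller tail, capped at 1; this makes
identical groups report p = 1. The lesion comparison uses the classical
pooled-variance two-tailed t-test with df = n1 + n2 − 2 and refuses
degenerate (zero pooled variance) input.

## Behavioral scoring and exclusions

A reach scores 1 only for reach–grasp–retrieve–eat; drops and knock-offs
score 0. Success rate on day d is `100 × score_d / score_final_pre`.
For the day-7-vs-day-2 contrast three modes exist:

- `sr_d7` (default headline): baseline-normalized day-7 rate compared
  between arms. Chosen as default because animals with zero day-2
  success (the typical severe-deficit case — in the motivating study
  most animals had none) make a per-animal day7/day2 ratio undefined;
  this mode keeps every animal in the test.
- `d7_vs_d2_ratio`: `100 × sr_d7 / sr_d2`, NaN when `sr_d2 = 0`
  (undefined animals are dropped from the test and counted).
- `d7_vs_d2_difference`: `sr_d7 − sr_d2` in percentage points, always
  defined.

Exclusion rules, applied in order and logged per animal: (1) no
macroscopic lesion; (2) zero successes in the final pre-intervention
session. Exclusion is idempotent. Paw preference is the side with
strictly more grasp attempts; ties are reported as undetermined rather
than resolved arbitrarily.

## Lesion volumetry

Volume = (Σ traced slice areas) × slice thickness, with no partial-slice
interpolation — fidelity to the planimetric procedure is preferred over
geometric accuracy. `area_from_mask` converts a binary slice mask to an
area as foreground-pixel count × pixel area.

## The synthetic cohort generator

No per-animal data are deposited with the motivating study, so the
generator emulates the statistical structure the analysis assumes, with
known ground truth:

- **PET:** activity `A(s,r) = G_s · μ_r · (1 + δ_r·[stim]) · ε`, with
  `G_s` a per-scan global factor proportional to injected dose per gram
  times a residual lognormal (log-sd 0.10 by default), and `ε`
  lognormal with region log-sd `σ_r` (defaults: 0.02 for the cerebellum
  reference — which carries δ = 0 by construction — and 0.05
  elsewhere). Multiplicative lognormal noise is used because uptake is
  positive and scan-to-scan variation is scale-like, which is exactly
  the error structure reference normalization removes. Default region
  panel: 10 basal-ganglia/cortex/brainstem regions with effects from
  −12% to +25%; default n = 4 PET animals (the analyzed group size),
  n = 6 for reference-selection checks (the full scanned group).
  Injected doses are drawn at the study's reported means/sds
  (46.5 ± 17.3 and 48.0 ± 12.6 MBq) into ~320 g animals. Regions are
  independent within animal; no inter-regional covariance or
  animal-level random effect is modeled, since none is identifiable
  from the study's reporting.
- **Behavior:** per-animal grasp probability Beta(24, 6) (mean 0.8,
  matching ~20+ successes per ~25-attempt session), attempts per 10-min
  session Poisson(25) floored at 20, stroke deficit factor 0.08 on the
  success probability, day-7 recovery factor 3.0 in the stimulated arm
  and 1.0 in sham. Cohorts can include animals with forced zero
  final-pre scores and absent lesions so the exclusion filters have
  material to act on.
- **Lesions:** ellipsoids (default semi-axes 3.0×2.2×2.0 mm stimulated,
  3.3×2.5×2.2 mm sham, i.e. ~55 and ~76 mm³) sliced at 1 mm with
  midpoint sampling, a per-animal mean-one lognormal size factor
  (log-sd 0.4, matching the study's between-animal volume CVs of
  ~0.4) and per-slice lognormal area noise (log-sd 0.1).

What the generator does **not** emulate: voxel-level PET physics
(resolution, partial volume, spill-over), registration error, session
learning effects, or attrition. Passing tests therefore demonstrate
correctness of the statistical pipeline under its own assumptions, not
robustness to those real-data effects.

Determinism: one master seed; the three generators draw from
independent streams spawned from it, so cohorts are bit-identical under
a fixed seed and regeneration with one knob changed keeps all other
draws matched (used by the normalization-identifiability test).

## Numerical and design choices

- Exact Mann–Whitney enumeration is preferred over the random-permutation
  fallback whenever the assignment count permits, ties or not; the
  fallback exists for larger groups only.
- The exact-enumeration CI interpolates quantiles of the nⁿ-vector with
  the same type-7 rule as the Monte-Carlo path. For samples with heavy
  atoms (near-tied values) interpolated enumeration quantiles and
  limiting empirical quantiles can differ by a local atom gap; the
  oracle-equivalence tests therefore target generic (distinct-valued)
  samples.
- TSV outputs are written at 6 significant digits, JSON at full
  precision; reruns with the same seed are byte-identical (hashes in
  `manifest.json`).
- Simulation sizes in tests and the acceptance script (200–2,000
  cohorts, B = 1,000–100,000) were chosen so each check's Monte-Carlo
  error is small against its asserted band while the whole suite runs
  in minutes on one CPU.

## Known limitations

- The percentile CI's small-n anticonservatism (above) is a property of
  the method, not an implementation artifact; BCa or studentized
  intervals are out of scope.
- `voi_mean` assumes the activity and label grids are co-registered and
  congruent; no registration is performed.
- The day-7/day-2 group values depend on the metric mode; all three are
  reported rather than privileging an unverifiable construction.
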