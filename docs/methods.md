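# Methods notes

## Scope and data model

The package analyses subject-level tables: a cohort table
(group, sex, ages, gestational age, birth weight, SES Largo score,
ICV, intellectual functioning), a 20-column volumetric matrix
(9 bilateral amygdala nuclei — lateral, basal, accessory basal,
central, medial, cortical, paralaminar, anterior amygdaloid area,
cortico-amygdaloid transition area — plus left/right whole-amygdala
totals, mm³), four raw socio-emotional scores, and for the
longitudinal subgroup paired left/right amygdala volumes and ages at
term-equivalent age (TEA) and school age. Because no real cohort is
distributed with the package, a synthetic generator produces tables
with the same statistical structure; all tests and the acceptance
script run on generated data.

## Synthetic cohort generator

`SimulationConfig` defaults encode the emulated study conditions:
75 VPT / 41 FT subjects aged 72–180 months; per-group gestational age,
birth weight, SES and intellectual-functioning distributions matching
the published group means/SDs (FT reference levels plus VPT offsets,
both configurable); ICV ~ N(1.45 × 10⁶, 1.2 × 10⁵) mm³.

Volumes for the 18 nucleus measures are

```
v_ij = base_j · (ICV_i / ICV_mean) + sex_effect · male_i · 1[j ∈ left set]
       + 60 mm³ · latent_strength · f_i · s_j
       + 0.05 · base_j · noise_sd · ε_ij
```

with `f_i ~ N(0,1)` a single shared subject factor and `s` the
unit-norm planted volumetric salience. Hemisphere totals are the sum
of that side's nuclei plus a nonnegative half-normal remainder
(SD 8 mm³), so totals always dominate their nuclei and the total's
effective latent loading is the sum of its nuclei's loadings;
`default_volumetric_salience()` builds a 20-vector whose total entries
equal those sums so the configured vector coincides with the planted
direction. Nominal nucleus volumes follow typical school-age
automated-subfield values (lateral 700 mm³ … medial 25 mm³), right
side scaled by 1.03. The additive male > female effect (default
40 mm³) is planted on the left basal, accessory basal, central and
paralaminar nuclei; the left total inherits the summed effect by
construction.

Raw behavior scores are linear in age and SES with instrument-typical
locations and dispersions (e.g. BRIEF T ~ 50 ± 10), plus the same
subject factor scaled by a group-specific unit-norm behavioral pattern
(default: VPT loads on emotional control, FT negatively on affect
recognition — a common volumetric pattern with group-specific
behavioral patterns, matching the group-wise PLSC design). Setting
`latent_strength = 0` makes volumes and behavior independent by
construction; `latent_strength = k · noise_sd` gives per-column
signal-to-noise ratios of order `k · s_j`. Raw scores are kept
continuous (no integer rounding of count-like instruments) to preserve
the exact linear structure the residualization tests rely on.

The longitudinal subgroup (default n = 20 VPT) draws per-side TEA
volumes ~ N(250, 35) mm³, TEA ages uniform on 0.5–1.5 months, and
school-age volumes from a saturating growth curve
`V(t) = V_TEA · (1 + a·t/(t + t_half) + σ_g·ε)` with a = 6,
t_half = 30 months, σ_g = 0.35: relative growth over the scan interval
then decreases with age at the school-age scan, reproducing the
faster-growth-in-younger-children pattern. An optional latent coupling
links TEA volumes to school-age behavior for planted-signal tests.

What the generator does **not** emulate: segmentation error,
scanner/site effects, non-Gaussian score distributions, missing-data
mechanisms beyond complete-case deletion, and longitudinal FT
controls. Passing tests therefore certify the statistical machinery
under the assumed generative model, not robustness to those real-data
features.

## Score preparation

"Standardized residual" is the raw OLS residual divided by the sample
SD of the residuals (denominator n − 1); internally studentized
residuals are not used. Residualization pools both groups in
cross-sectional analyses and is refitted within each analysis sample
(the longitudinal subgroup refits its own regressions);
`per_group=True` and `adjust_ga=True` expose the within-group and
gestational-age-adjusted variants. Covariate columns that are constant
in a given sample are dropped (the regression degenerates to the
z-score); exact-fit inputs raise a degenerate-fit error rather than
returning 0/0. Complete-case handling with logged exclusion counts; no
imputation.

## Univariate statistics

Demographic rows use the pooled two-sample t (integer df); behavior
scores use Welch's t (Satterthwaite df), matching the df conventions
of the two table sections they emulate. Cohen's d uses the pooled SD
and is reported as a magnitude. The sex comparison uses Pearson's
chi-square without continuity correction (the uncorrected form is what
the printed statistic corresponds to). The ANCOVA stage fits 20
separate univariate linear models (not a single multivariate test),
with sum-to-zero contrasts and Type III partial F-tests so main
effects remain interpretable alongside the group × age interaction;
age centering is optional and off by default. Partial η² is the
reported effect size. BH-FDR families are the 20 p-values of a given
term across models (group and group × age corrected separately,
m = 20). The 5-SD outlier filter computes each measure's mean/SD once
on the full sample (no iterative re-filtering).

## PLSC

Design choices, in the package's own words:

- **Within-group z-scoring** of X and Y before the cross-covariance,
  making each stacked block a correlation matrix. A literal covariance
  over raw mm³ against unit-variance residual scores would be
  dominated by the volume scale; `zscore=False` exposes that raw
  alternative.
- **Permutation scheme**: rows of Y are permuted across the whole
  sample while X and the group labels stay fixed (group membership of
  a permuted row follows its new position); singular values are
  compared rank-for-rank. A Procrustes-rotated variant
  (`perm_procrustes=True`, Milan–Whittaker-style rotated singular
  values) is available but off by default.
- **p-value estimator**: `(1 + #exceed) / (1 + n_perm)` — never zero;
  the minimum attainable value is `1/(n_perm + 1)`.
- **Bootstrap**: subjects resampled with replacement within group
  (group sizes preserved); each resample's singular vectors are
  aligned to the reference by an orthogonal Procrustes rotation
  computed on the stacked behavioral + volumetric saliences, which
  treats both blocks symmetrically and resolves sign/rotation
  indeterminacy. Resamples producing a zero-variance column are
  redrawn (logged, bounded at 100).
- **Sign convention**: each component's sign is fixed so the largest-
  magnitude volumetric salience entry is positive, applied before
  reporting and before bootstrap alignment.
- **Stacking order** is fixed (VPT block first) and recorded in the
  result; covariance normalization is n_g − 1 (immaterial to
  saliences, fixed for reproducible singular values).
- Energy conservation (Σ s_k² = ‖R‖²_F) holds exactly by construction
  and is asserted across the suite at 10⁻⁸ relative.

Planted-signal recovery is measured on the scale the signal is planted
on: the generator plants a covariance-scale direction, so the salience
correlation check uses the `zscore=False` estimate (the z-scored
estimate deliberately reweights columns by their dispersions and is
checked instead via its permutation p and bootstrap ratios).

## Longitudinal analysis

`mean_age` is the arithmetic mean of the two scan ages; `inter_age`
is mean_age × Δage. The trajectory regression is ΔVolume on
{intercept, inter_age} only — the intercept is included because
residual standardization assumes a fitted mean; Δage/mean_age main
effects are not added (the score definition names inter_age alone).
Growth-rate denominators use raw (not ICV-corrected) TEA volumes. Age
bands 6–9 y and 10–14 y are implemented as [72, 120) and [120, 180)
months. The secondary PLSC designs are single-group: X is the n × 2
TEA-volume (or trajectory-score) matrix, Y the subgroup's four
behavior scores, residualized within the subgroup.

## Numerical and testing choices

Tolerances: residual orthogonality 10⁻⁸, idempotence 10⁻¹⁰, oracle
equivalence 10⁻¹⁰–10⁻¹², SVD energy 10⁻⁸ relative. Calibration checks
run 200 replicate cohorts at 200 permutations (null rejection rate at
α = 0.05 within 5% ± 3%; KS distance of LC1 p-values to uniform
< 0.1) and 100 replicate longitudinal subgroups; the ANCOVA type-I
calibration uses 30 replicate cohorts of 120 subjects. The
planted-recovery condition uses `latent_strength = 5 · noise_sd`,
where LC1 reaches the minimum attainable permutation p and all planted
measures exceed |BSR| = 3 with 500 resamples. Determinism is enforced
end-to-end: a fixed config reproduces byte-identical output trees, and
the run manifest records the seeds and SHA-256 of every table.

## Known limitations

- The ANCOVA's Type III tests assume the sum-to-zero coding; results
  for unbalanced designs differ from sequential (Type I) analyses.
- Bootstrap SDs use the simple percentile-free SD of aligned
  resamples; no BCa correction or salience confidence intervals.
- The permutation test is exchangeability-based and does not model
  family structure or repeated measures.
- The generator's group covariate shifts act only on means; real
  cohorts may differ in higher moments and missingness patterns.
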