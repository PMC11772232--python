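# preterm-amygdala

Statistical analysis pipeline for studying amygdala (sub)nuclei volumes
and socio-emotional competencies in very-preterm (VPT) vs full-term
(FT) children and adolescents, with a synthetic cohort generator that
emulates the data structure of such a study so every stage is testable
without access to patient data.

The pipeline covers four stages:

1. **Score preparation** — each socio-emotional instrument's raw score
   (NEPSY-II theory of mind and affect recognition, SDQ internalizing
   problems, BRIEF emotional control) is regressed on its covariates
   (age at testing and SES Largo score; SES only for the BRIEF scale;
   optionally gestational age) and the standardized OLS residuals
   `r / sd(r)` are used as scores.
2. **Univariate group statistics** — pooled and Welch two-sample
   t-tests with Cohen's *d*, Pearson chi-square, a 5-SD volumetric
   outlier filter, and one ANCOVA per amygdala measure,
   `volume ~ group × age + ICV + sex + SES`, with Type III partial
   F-tests, partial η², and Benjamini–Hochberg FDR across the
   20 models.
3. **Group-wise partial least squares correlation (PLSC)** — within
   each group the volume matrix **X** (n × 20) and score matrix **Y**
   (n × 4) are z-scored and the cross-correlation blocks
   `R_g = Y_gᵀX_g / (n_g − 1)` are stacked (VPT above FT) and
   decomposed by SVD, `R = U S Vᵀ`. Each latent component (LC) pairs a
   volumetric salience pattern common to all participants (column of
   **V**) with group-specific behavioral patterns (blocks of the
   matching column of **U**). LC significance is assessed by permuting
   the rows of **Y** across the whole sample (1000 permutations,
   robust at *p* < 0.01); salience stability by resampling subjects
   with replacement within group (500 resamples, Procrustes-aligned),
   flagging variables whose bootstrap ratio `BSR = salience / SD_boot`
   has |BSR| ≥ 3.
4. **Longitudinal growth** — for subjects with a scan at
   term-equivalent age (TEA) and at school age, the relative growth
   rate `[(V_school − V_TEA)/(age_school − age_TEA)] · 100 / V_TEA`
   (%/month), a 6–9 y vs 10–14 y band contrast, and inter-age-adjusted
   trajectory scores (ΔVolume residualized on mean-age × Δage), which
   feed two further single-group PLSC designs.

## Worked example

The numbered drivers under `analysis/` run the full study narrative on
a synthetic cohort (75 VPT / 41 FT, moderate planted brain-behavior
association) and write their tables under `results/analysis/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_prepare_scores.py
python analysis/03_group_comparisons.py
python analysis/04_plsc_school_age.py
python analysis/05_longitudinal_growth.py
```

Output of steps 03–05 (abridged):

```
group differences at p < 0.05: ['Gestational age (weeks)', 'Birth weight (g)', 'SES (Largo score)']
ANCOVA icv: 20/20 measures at p < 0.05
ANCOVA sex: 5/20 measures at p < 0.05
[standard] LC1: singular value 3.167, p = 0.0010 (significant at p < 0.01)
  robust VPT behavioral contributors: ['emotional_control']
  robust FT behavioral contributors: ['affect_recognition', 'internalizing_problems']
6-9y: n=8, mean total growth 4.88 %/month
10-14y: n=12, mean total growth 3.36 %/month
PLSC tea vs behavior: LC1 p = 0.675 (ns)
PLSC trajectory vs behavior: LC1 p = 0.729 (ns)
```

Reading: the synthetic VPT group differs from FT on the neonatal and
SES variables but not on adjusted amygdala volumes (ICV dominates all
20 models; the planted male > female effect appears in 5 left-side
measures); one significant latent component links larger amygdala
volumes to more emotion-regulation difficulty in VPT and lower affect
recognition in FT; relative amygdala growth decelerates with age; and
at n = 20 the TEA and trajectory PLSC designs are null.

The same machinery is available programmatically
(`preterm_amygdala.run_cross_sectional`, `run_longitudinal`,
`run_plsc`, …) and through the `preterm-amygdala` CLI
(`simulate`, `prepare-scores`, `compare-demographics`, `ancova`,
`plsc`, `longitudinal`, `run-all`).

## Layout

- `src/preterm_amygdala/` — the library (simulation, scores,
  group statistics, PLSC, longitudinal, pipeline, CLI)
- `analysis/` — numbered narrative drivers
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — model and design notes
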