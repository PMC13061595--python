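# epifit

Blood DNA methylation can stand in for the circulating proteome: an
**EpiScore** estimates a plasma protein level as a weighted linear
combination of CpG beta values, `score = Σ_k w_k · β_k`, using published
CpG weights. Because many protein EpiScores carry known disease hazard
ratios from external Cox models, they link modifiable physiology —
aerobic capacity, grip strength, jump performance, BMI, cognition — to
the risk of aging-related disease through an interpretable molecular
layer.

`epifit` implements that analysis as a reusable, tested pipeline for
epidemiologists and exercise-science groups with matched methylation and
fitness measurements:

1. **Projection** — compute protein EpiScores from a CpG beta matrix,
   with reference-mean imputation for missing probes and harmonization of
   EpiScore naming conventions across platforms (SOMAscan / Olink).
2. **Association scan** — one OLS model per (fitness trait, EpiScore)
   pair, `EpiScore ~ trait_z + sex + age` (female = 0, male = 1), with
   nominal and Benjamini–Hochberg FDR significance.
3. **Linkage** — join significant trait→EpiScore coefficients to external
   EpiScore→disease log hazard ratios and check direction consistency
   along the chain.
4. **Risk scoring** — a per-patient, per-disease composite

   ```
   risk(s, d) = Σ_i log HR(i, d) · EpiScore_z(s, i)          (direct)
              + Σ_(j,i) β_{i←j} · log HR(i, d) · fitness_z(s, j)   (indirect)
   ```

   z-scored per disease across the cohort; z > 1.28 (top decile) flags
   high risk. Fitness is categorized low/normal/high against age- and
   sex-stratified mean ± 1.28 SD bands (10th/90th percentiles for
   cognition), and patients are ranked by flagged-disease count.
5. **Validation** — an external 45-protein CVD EpiScore benchmark is
   correlated (Spearman, BH-adjusted) with each disease risk score as a
   convergent-validity check.

A first-class synthetic-study generator produces a full cohort —
covariates, fitness, latent EpiScores with planted effects, a methylation
matrix constructed so the projection recovers the latent scores, hazard
and CVD weight tables — so the entire pipeline runs and is testable
without any data download. Defaults emulate a cohort of 290 participants
(age ~ N(60, 11²) truncated to 33–86 years, 52% female, 109 protein
EpiScores, 10 diseases).

## Worked example

```python
from epifit import (CohortSpec, simulate_study, project_episcores,
                    association_scan, significant_associations, SignificanceConfig,
                    link_fitness_disease, assess_direction_consistency,
                    standardize_columns, compute_direct_risk, compute_indirect_risk,
                    compute_risk_scores, rank_high_risk_patients,
                    compute_cvd_score, validate_against_benchmark)

study = simulate_study(CohortSpec(seed=1))
episcores, _ = project_episcores(study.methylation, study.weights, study.ref_means)

config = SignificanceConfig()
scan = association_scan(episcores, study.fitness, study.covariates, config)
sig = significant_associations(scan, config)

links, n_consistent = assess_direction_consistency(
    link_fitness_disease(sig, study.hazard))

direct = compute_direct_risk(standardize_columns(episcores), study.hazard)
indirect = compute_indirect_risk(standardize_columns(study.fitness), sig, study.hazard)
risk = compute_risk_scores(direct, indirect)

cvd = compute_cvd_score(standardize_columns(episcores), study.cvd_weights, strict=False)
report = validate_against_benchmark(risk, cvd)
```

With seed 1 this prints (via the obvious `print` statements):

```
EpiScores: 290 samples x 109 proteins
association scan: 545 tests, 50 significant at p < 0.05
links: 21 (trait, protein, disease) triples, 11 direction-consistent
high-risk flags: 296 across 10 diseases; 66.6% of patients flagged at least once
top patient S00020 flagged for 4 diseases
CVD benchmark: strongest correlation rho = 0.27 (COPD, q = 3.9e-05)
```

Reading this: 545 tests are the 5 traits × 109 proteins; 50 pass the
nominal p < 0.05 threshold (33 planted effects plus the expected ~5%
false positives). The 50 significant pairs join the hazard table at 21
(trait, protein, disease) triples, 11 of which propagate in the a-priori
expected direction (BMI risk-increasing, other traits protective — with
random synthetic hazard signs roughly half the chains agree). 296 flags
are spread over 290 patients × 10 diseases, and the top-decile rule puts
each patient above the threshold for ~1 disease on average. The CVD
benchmark correlates most strongly with the disease whose hazard-table
proteins happen to overlap its weight set.

The same flow is available from the shell:

```sh
epifit simulate --seed 1 --out sim/
epifit run --config run.yaml            # project → associate → link → score → validate
```

where `run.yaml` points at the simulated (or your own) tables; each stage
can also be run individually (`epifit project|associate|link|score|validate`).
All artifacts are plain CSV/TSV with a JSON run manifest, and reruns with
the same seed are byte-identical.

## Scope

`epifit` scores *relative* risk within the analyzed cohort; it does not
produce calibrated absolute risk, does not re-train EpiScore weights or
re-estimate hazard ratios (both are external fixed inputs), and does not
perform array-level preprocessing (IDAT parsing, normalization, probe
version translation).
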