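# Methods

## Model

The pipeline treats blood DNA methylation as a proxy proteome. A protein
EpiScore is a fixed linear functional of the CpG beta vector,
`score = Σ_k w_k β_k`, with published weights `w`; no intercept is applied
and betas enter on their natural [0, 1] scale (a plain weighted sum —
whether upstream tools standardize betas first is not observable from the
weight files, so the unstandardized sum is the documented convention
here).

Disease risk per patient `s` and disease `d` combines two layers:

* **direct**: `Σ_i log HR(i, d) · EpiScore_z(s, i)` — a polygenic-score
  style weighted sum of cohort-standardized EpiScores, with weights equal
  to external Cox log hazard ratios (fully adjusted models when both
  variants are available);
* **indirect**: `Σ_(j,i) β_{i←j} · log HR(i, d) · fitness_z(s, j)` — the
  product-of-coefficients (mediation) chain: the trait→EpiScore
  regression coefficient times the EpiScore→disease log HR times the
  patient's z-scored trait value. The hazard weight in each chain is
  the one attached to the chain's *EpiScore* for the target disease
  (indexing the log HR by the fitness trait would be ill-defined, as
  traits carry no hazard ratios). Only nominally significant (p < 0.05)
  trait→EpiScore pairs feed the indirect sum by default; a switch admits
  all pairs. When a protein contributes to both layers, both terms are
  kept — the composite is defined as their sum — with a sensitivity
  option to zero the duplicate.

Raw scores are z-scored per disease across the cohort (they are
*relative* rankings, not calibrated risk), and z > 1.28 — the top decile
of a normal distribution — flags high risk. Flags use strict inequality;
a value exactly at a boundary is never extreme.

### Association scan

One OLS model per (trait, protein): `EpiScore ~ trait_z + sex + age`,
with the trait z-scored (sample SD, n−1), sex coded female = 0 / male = 1
and age in years, both on natural scales. The reported β, SE and
two-sided t-test p-value belong to the trait term. Benjamini–Hochberg
q-values are computed across all 545 tests jointly (the conservative
family choice; a per-trait family is available). Two-sidedness and the
n−1 denominator are conventions applied uniformly; both are configurable
reading points rather than results-bearing choices.

### Fitness categorization

VO₂max, GripStrength, JumpMax and BMI are categorized against
mean ± 1.28 SD boundaries computed within (age decade × sex) strata —
the SD-band analogue of normative reference tables; strata with fewer
than two samples or zero variance fall back to cohort-wide boundaries
with a warning. Cognition uses cohort-wide empirical 10th/90th
percentiles (linear interpolation between order statistics; the
definition matters only at ties). Boundary values classify as "normal".
Under normality the bands hold Φ(1.28) − Φ(−1.28) ≈ 79.9% of values;
the acceptance suite verifies this law at n = 100,000.

### External validation

The CVD benchmark is `Σ_i weight_i · EpiScore_z(s, i)` over a fixed
45-protein weight table. It is correlated with each disease risk score
using Spearman rank correlation (mid-ranks for ties, t-approximation
p-values) — rank correlation is the robust default for scores with no
shared scale; Pearson is available. q-values are BH-adjusted across the
diseases through the same `bh_adjust` used by the scan, and stars mark
FDR < 0.01 (**) and < 0.001 (***). Standardized EpiScores are used by
default for internal consistency with the direct risk term; a `--raw`
switch exists because the benchmark's original scale convention is not
fixed by the weight table itself.

## Synthetic study generator

The generator emulates the statistical structure of a modest
observational cohort so every downstream stage is exercisable without
data access. Defaults (all configurable via `CohortSpec`):

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 290 | cohort size |
| age | N(60, 11²) truncated to [33, 86] | rejection sampling; truncation pulls the analytic mean to ≈ 59.95 y |
| `female_fraction` | 0.52 | Bernoulli sex, female = 0 |
| `n_proteins` / `cpgs_per_protein` | 109 / 20 | disjoint CpG blocks per protein |
| `n_diseases` / `n_cvd_proteins` | 10 / 45 | hazard and benchmark table sizes |
| effect matrix | 33 nonzero entries | BMI +0.3 on 18 proteins; JumpMax (7), GripStrength (4), Cognition (4) at −0.3; VO₂max none |
| `noise_sd` | 0.5 | EpiScore residual SD |
| weights / reference means | |w| ∈ (0.15, 0.35), ref ∈ (0.35, 0.65) | see embedding note |
| log HR | N(0, 0.2²) | per (disease, random protein subset of 3–8) |
| CVD weights | N(0, 0.2²) | 45 random proteins |

Fitness traits are drawn on natural scales (VO₂max 35 ± 7 mL·kg⁻¹·min⁻¹,
grip 0.55 ± 0.10 kg/BM, jump 0.22 ± 0.05 cm/BH, BMI 26 ± 4 kg/m²,
digit-span cognition 6 ± 1.5) with mild age and sex slopes, so the SD
categorizer sees realistic input; published normative tables do not pin
these moments down, so they are explicitly configurable placeholders.
Planted effects are applied to *cohort-standardized* fitness values:
since the association scan z-scores fitness before modeling, the scan's
estimand then equals the planted coefficient exactly, which makes the
confidence-interval coverage property exact rather than asymptotic.
Latent EpiScores add small age (0.01/y) and sex (0.1) slopes so that
"independent of age and sex" is a real adjustment, plus Gaussian noise.

**Methylation embedding.** For protein `i` with weights `w` and
reference means `b`, a sample with latent score `s` receives betas
`b + w (s − w·b) / (w·w)` — the minimum-norm perturbation of the
reference profile satisfying `w·β = s` — then clipped to [0, 1] because
betas are proportions. The per-CpG perturbation scales as
`(s − w·b) / (k·|w|)`, so more CpGs and larger weights mean smaller
perturbations; with the defaults clipping affects ≈ 0.05% of entries
(logged), and only clipped entries break the projection round trip.
Latent scores are offset by each protein's baseline `w·b` before
embedding so perturbations are centred on the reference profile.

What the generator does **not** emulate: genome-wide methylation beyond
the projector's CpGs, probe sharing between proteins (CpG sets are
disjoint to keep the embedding exactly solvable), array batch effects,
beta-distribution marginals, and missing data (the pipeline models a
complete-case cohort). Passing tests therefore demonstrate correctness
of the *computational chain* and its statistical calibration — not that
real methylation data would yield any particular association structure.

## Numerical choices

* OLS via `numpy.linalg.lstsq` with SEs from σ̂²(XᵀX)⁻¹, σ̂² = RSS/df and
  t-distributed p-values; a shared multi-response solver fits all protein
  columns of one design in a single call. Rank-deficient designs raise,
  naming the dependent columns found by pivoted QR.
* BH step-up q-values restore input order; monotonicity is enforced by
  the cumulative-minimum form. p-values outside [0, 1] are rejected.
* Missing-probe policy: reference-mean imputation, per-protein counts
  reported, scores with > 20% imputed values flagged unreliable
  (configurable) — a probe missing from matrix *and* reference is an
  error, not a silent zero.
* Ranking ties: flagged-disease count desc, total z-score sum desc,
  sample ID asc — fully deterministic.
* Floats are written with 10 significant digits; identical config + seed
  reproduces every artifact byte-for-byte.
* All randomness flows from one integer seed through independent
  `SeedSequence` streams per generator, so enlarging one table never
  perturbs another.

## Problem sizes in the test suite

The statistical suites run at sizes chosen for tight Monte-Carlo bounds
at interactive cost: analytic band laws at n = 100,000 draws;
planted-effect recovery at n = 5,000; confidence-interval coverage over
200 replicate cohorts of n = 400; null calibration over 50 replicates of
1,000 tests (50,000 null p-values, binomial SE ≈ 0.1 pp on the 5%
rate). Generator calibration is assessed on the mean of 20 replicate
cohorts of 290, since a single 290-sample draw carries ~0.65 y of noise
on the mean age.

## Known limitations

* Linear, homoscedastic OLS only — no robust SEs, mixed models, or
  cell-composition covariates.
* Hazard ratios are trusted external inputs; transportability to the
  analyzed cohort is assumed, not tested.
* The indirect term inherits all causal caveats of cross-sectional
  product-of-coefficients mediation.
* High-risk flags are cohort-relative; prevalence differences between
  diseases are not modeled.
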