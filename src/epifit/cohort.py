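"""Synthetic study generator.

Builds a complete in-silico cohort with the statistical structure the
pipeline expects: demographic covariates, five fitness traits with mild
age/sex dependence, latent protein EpiScores driven by a sparse planted
fitness->EpiScore effect matrix, CpG weight sets with reference mean betas,
a methylation beta matrix constructed so the weighted projection recovers
the latent scores, and randomized EpiScore->disease hazard and CVD weight
tables.  Everything is deterministic under the spec's seed.

The generative model for a latent EpiScore is

    score_i = baseline_i + sum_j beta_ij * z(fitness_j)
              + g_age * (age - age_mean) + g_sex * sex + N(0, noise_sd^2)

where ``z`` standardizes each trait within the generated cohort.  Applying
the planted effects on the standardized scale means the downstream
association scan (which z-scores fitness before modeling) estimates the
planted coefficients directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateWeightsError, SpecificationError

logger = logging.getLogger(__name__)

FITNESS_TRAITS = ("VO2max", "GripStrength", "JumpMax", "BMI", "Cognition")

#: Disease labels used by the default hazard table.
DISEASES = (
    "bowel_cancer",
    "COPD",
    "depression",
    "diabetes",
    "IBD",
    "IHD",
    "lung_cancer",
    "pain",
    "RA",
    "stroke",
)

#: Per-trait (mean, SD, slope per year of age, additive shift for males).
#: Natural units: VO2max mL/kg/min, GripStrength kg per kg body mass,
#: JumpMax cm per cm body height, BMI kg/m^2, Cognition digit-span score.
DEFAULT_TRAIT_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "VO2max": (35.0, 7.0, -0.25, 6.0),
    "GripStrength": (0.55, 0.10, -0.003, 0.12),
    "JumpMax": (0.22, 0.05, -0.002, 0.05),
    "BMI": (26.0, 4.0, 0.03, 0.5),
    "Cognition": (6.0, 1.5, -0.03, 0.0),
}


def protein_ids(n: int) -> list[str]:
    return [f"PROT_{i:03d}" for i in range(1, n + 1)]


def default_effect_matrix(n_proteins: int = 109, magnitude: float = 0.3) -> pd.DataFrame:
    """Sparse planted fitness->EpiScore coefficient matrix (traits x proteins).

    33 nonzero entries: BMI positive on 18 proteins; JumpMax (7),
    GripStrength (4) and Cognition (4) negative; VO2max unassociated.
    """
    cols = protein_ids(n_proteins)
    eff = pd.DataFrame(0.0, index=list(FITNESS_TRAITS), columns=cols)
    blocks = [("BMI", 0, 18, magnitude), ("JumpMax", 18, 25, -magnitude),
              ("GripStrength", 25, 29, -magnitude), ("Cognition", 29, 33, -magnitude)]
    for trait, lo, hi, value in blocks:
        hi = min(hi, n_proteins)
        eff.loc[trait, cols[lo:hi]] = value
    return eff


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic study.

    Defaults emulate the target cohort: 290 participants, age ~ N(60, 11^2)
    truncated to [33, 86], 52% female, 109 protein EpiScores, 10 diseases
    and a 45-protein CVD benchmark table.
    """

    n_samples: int = 290
    age_mean: float = 60.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (33.0, 86.0)
    female_fraction: float = 0.52
    n_proteins: int = 109
    cpgs_per_protein: int = 20
    n_diseases: int = 10
    n_cvd_proteins: int = 45
    effect_matrix: pd.DataFrame | None = None
    noise_sd: float = 0.5
    episcore_age_slope: float = 0.01
    episcore_sex_slope: float = 0.1
    trait_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_PARAMS)
    )
    weight_abs_range: tuple[float, float] = (0.15, 0.35)
    ref_mean_range: tuple[float, float] = (0.35, 0.65)
    hazard_proteins_per_disease: tuple[int, int] = (3, 8)
    hazard_log_hr_sd: float = 0.2
    cvd_weight_sd: float = 0.2
    seed: int = 0

    def resolved_effects(self) -> pd.DataFrame:
        if self.effect_matrix is None:
            return default_effect_matrix(self.n_proteins)
        return self.effect_matrix

    def validate(self) -> None:
        if self.n_samples < 2:
            raise SpecificationError(f"n_samples must be >= 2, got {self.n_samples}")
        if not 0.0 < self.female_fraction < 1.0:
            raise SpecificationError("female_fraction must lie strictly in (0, 1)")
        if not self.age_range[0] < self.age_range[1]:
            raise SpecificationError("age_range must be increasing")
        if self.noise_sd <= 0:
            raise SpecificationError("noise_sd must be positive")
        if self.n_proteins < 1 or self.cpgs_per_protein < 1:
            raise SpecificationError("n_proteins and cpgs_per_protein must be positive")
        if self.n_cvd_proteins > self.n_proteins:
            raise SpecificationError(
                f"n_cvd_proteins ({self.n_cvd_proteins}) exceeds n_proteins ({self.n_proteins})"
            )
        eff = self.resolved_effects()
        if eff.shape[1] != self.n_proteins:
            raise SpecificationError(
                f"effect_matrix has {eff.shape[1]} protein columns, expected {self.n_proteins}"
            )
        missing = [t for t in eff.index if t not in self.trait_params]
        if missing:
            raise SpecificationError(f"effect_matrix traits without parameters: {missing}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Rejection sampler; the envelope is the untruncated normal."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled: filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw covariates, fitness traits, and latent EpiScores.

    Returns ``(covariates, fitness, latent)``: covariates has columns
    ``age`` and ``sex`` (female = 0, male = 1), fitness one column per
    trait, latent one column per protein; all indexed by sample_id.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = [f"S{i:05d}" for i in range(1, spec.n_samples + 1)]

    age = _truncated_normal(rng, spec.age_mean, spec.age_sd,
                            spec.age_range[0], spec.age_range[1], spec.n_samples)
    sex = (rng.random(spec.n_samples) < 1.0 - spec.female_fraction).astype(int)
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(ids, name="sample_id"))

    fitness = pd.DataFrame(index=covariates.index)
    for trait in FITNESS_TRAITS:
        mean, sd, age_slope, sex_shift = spec.trait_params[trait]
        fitness[trait] = (
            mean
            + age_slope * (age - spec.age_mean)
            + sex_shift * sex
            + rng.normal(0.0, sd, spec.n_samples)
        )

    effects = spec.resolved_effects()
    fitness_z = (fitness - fitness.mean()) / fitness.std(ddof=1)
    signal = fitness_z[list(effects.index)].to_numpy() @ effects.to_numpy()
    latent_values = (
        signal
        + spec.episcore_age_slope * (age - spec.age_mean)[:, None]
        + spec.episcore_sex_slope * sex[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, effects.shape[1]))
    )
    latent = pd.DataFrame(latent_values, index=covariates.index, columns=effects.columns)
    return covariates, fitness, latent


def generate_weight_sets(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw disjoint CpG weight sets and reference mean betas.

    Returns a long-format weight table (protein_id, cpg_id, weight) and a
    Series of reference mean betas indexed by cpg_id.  Each protein owns a
    disjoint block of ``cpgs_per_protein`` CpGs; weight magnitudes are
    uniform on ``weight_abs_range`` with random sign, reference means
    uniform on ``ref_mean_range``.
    """
    spec.validate()
    # Offset stream so weights do not share draws with generate_cohort.
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rows = []
    ref: dict[str, float] = {}
    lo_w, hi_w = spec.weight_abs_range
    lo_b, hi_b = spec.ref_mean_range
    k = 0
    for pid in protein_ids(spec.n_proteins):
        for _ in range(spec.cpgs_per_protein):
            k += 1
            cpg = f"cg{k:08d}"
            weight = rng.uniform(lo_w, hi_w) * rng.choice([-1.0, 1.0])
            rows.append((pid, cpg, weight))
            ref[cpg] = rng.uniform(lo_b, hi_b)
    weights = pd.DataFrame(rows, columns=["protein_id", "cpg_id", "weight"])
    ref_means = pd.Series(ref, name="mean_beta").rename_axis("cpg_id")
    return weights, ref_means


def baseline_scores(weights: pd.DataFrame, ref_means: pd.Series) -> pd.Series:
    """Per-protein projection of the reference means, sum_k w_k * ref_k."""
    merged = weights.assign(term=weights["weight"].to_numpy()
                            * ref_means.reindex(weights["cpg_id"]).to_numpy())
    return merged.groupby("protein_id", sort=False)["term"].sum()


def embed_methylation(latent: pd.DataFrame, weights: pd.DataFrame,
                      ref_means: pd.Series) -> tuple[pd.DataFrame, int]:
    """Construct a beta matrix whose weighted projection equals the latent scores.

    For protein i with weight vector ``w`` and reference baseline ``b`` the
    sample's betas are ``b + w * (s - w.b) / (w.w)`` — the minimum-norm
    perturbation of the reference profile that projects exactly to the
    latent score ``s`` — then clipped to [0, 1].  Returns the probes x
    samples matrix and the number of clipped entries (clipped proteins no
    longer project exactly; occurrences are logged).
    """
    blocks = []
    n_clipped = 0
    grouped = weights.groupby("protein_id", sort=False)
    for pid in latent.columns:
        if pid not in grouped.groups:
            raise SpecificationError(f"no weight set for protein {pid!r}")
        grp = grouped.get_group(pid)
        w = grp["weight"].to_numpy()
        wtw = float(w @ w)
        if wtw == 0.0:
            raise DegenerateWeightsError(f"zero-norm weight vector for protein {pid!r}")
        b = ref_means.reindex(grp["cpg_id"]).to_numpy()
        s = latent[pid].to_numpy()
        betas = b[:, None] + np.outer(w, s - w @ b) / wtw
        clipped = (betas < 0.0) | (betas > 1.0)
        n_clipped += int(clipped.sum())
        blocks.append(pd.DataFrame(np.clip(betas, 0.0, 1.0),
                                   index=grp["cpg_id"].to_numpy(), columns=latent.index))
    if n_clipped:
        logger.warning("embed_methylation clipped %d beta entries to [0, 1]; "
                       "affected scores will not round-trip exactly", n_clipped)
    meth = pd.concat(blocks)
    meth.index.name = "cpg_id"
    meth.columns.name = "sample_id"
    return meth, n_clipped


def generate_hazard_table(spec: CohortSpec) -> pd.DataFrame:
    """Random EpiScore->disease log hazard ratio table.

    Each of ``n_diseases`` diseases gets a random protein subset of size
    uniform on ``hazard_proteins_per_disease`` with log(HR) ~ N(0, sd^2).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    pids = np.array(protein_ids(spec.n_proteins))
    diseases = list(DISEASES[: spec.n_diseases])
    diseases += [f"disease_{i}" for i in range(len(diseases) + 1, spec.n_diseases + 1)]
    lo, hi = spec.hazard_proteins_per_disease
    rows = []
    for disease in diseases:
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(pids, size=min(size, pids.size), replace=False)
        for pid in sorted(chosen):
            rows.append((disease, pid, rng.normal(0.0, spec.hazard_log_hr_sd)))
    return pd.DataFrame(rows, columns=["disease", "protein_id", "log_hr"])


def generate_cvd_weights(spec: CohortSpec) -> pd.DataFrame:
    """Random external CVD benchmark: n_cvd_proteins (protein, weight) pairs."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    chosen = rng.choice(np.array(protein_ids(spec.n_proteins)),
                        size=spec.n_cvd_proteins, replace=False)
    return pd.DataFrame({
        "protein_id": sorted(chosen),
        "weight": rng.normal(0.0, spec.cvd_weight_sd, spec.n_cvd_proteins),
    })


@dataclass
class SimulatedStudy:
    """Bundle of every table one simulated study produces."""

    spec: CohortSpec
    covariates: pd.DataFrame
    fitness: pd.DataFrame
    latent: pd.DataFrame          # ground-truth EpiScores incl. baseline
    weights: pd.DataFrame
    ref_means: pd.Series
    methylation: pd.DataFrame     # probes x samples
    hazard: pd.DataFrame
    cvd_weights: pd.DataFrame
    n_clipped: int


def simulate_study(spec: CohortSpec) -> SimulatedStudy:
    """Run every generator and assemble a consistent study.

    Latent scores are shifted by each protein's reference baseline
    (sum w*ref) before embedding so the beta perturbations stay centred on
    the reference profile and clipping stays rare.
    """
    covariates, fitness, latent = generate_cohort(spec)
    weights, ref_means = generate_weight_sets(spec)
    base = baseline_scores(weights, ref_means)
    latent = latent + base.reindex(latent.columns)
    meth, n_clipped = embed_methylation(latent, weights, ref_means)
    hazard = generate_hazard_table(spec)
    cvd = generate_cvd_weights(spec)
    return SimulatedStudy(spec, covariates, fitness, latent, weights, ref_means,
                          meth, hazard, cvd, n_clipped)


def respec(spec: CohortSpec, **changes) -> CohortSpec:
    """Convenience wrapper around dataclasses.replace."""
    return replace(spec, **changes)
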