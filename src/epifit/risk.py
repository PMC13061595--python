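"""Patient-level composite disease risk scores.

For each patient and disease the raw score sums a direct molecular term
and an indirect fitness term:

    risk(s, d) = sum_i logHR(i, d) * episcore_z(s, i)
               + sum_(j,i) beta(i<-j) * logHR(i, d) * fitness_z(s, j)

The direct term weights standardized EpiScores by external log hazard
ratios (polygenic-score style); the indirect term propagates each
significant fitness->EpiScore coefficient through the same hazard weights
(product-of-coefficients chain).  Raw scores are z-scored per disease
across the cohort; z > 1.28 (top decile of a normal) flags high risk.
Fitness is categorized low/normal/high against age x sex stratum
mean +/- 1.28 SD bands, except Cognition which uses cohort-wide 10th/90th
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateScaleError, ValidationError

logger = logging.getLogger(__name__)

SD_TRAITS = ("VO2max", "GripStrength", "JumpMax", "BMI")
PERCENTILE_TRAITS = ("Cognition",)


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds for flagging and categorization (all in SD units except percentiles)."""

    z_flag_threshold: float = 1.28
    fitness_sd_threshold: float = 1.28
    cognition_percentiles: tuple[float, float] = (10.0, 90.0)
    age_bin_width: float = 10.0
    stratify_by_sex: bool = True

    def __post_init__(self):
        if self.z_flag_threshold <= 0 or self.fitness_sd_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        lo, hi = self.cognition_percentiles
        if not 0.0 < lo < hi < 100.0:
            raise ValidationError("cognition percentiles must be ordered within (0, 100)")


@dataclass
class RiskTable:
    """Samples x diseases: raw scores, cohort z-scores, high-risk flags."""

    raw: pd.DataFrame
    z: pd.DataFrame
    high_risk: pd.DataFrame
    threshold: float = 1.28
    direct: pd.DataFrame | None = field(default=None, repr=False)
    indirect: pd.DataFrame | None = field(default=None, repr=False)


def compute_direct_risk(episcores_std: pd.DataFrame, hazard: pd.DataFrame) -> pd.DataFrame:
    """Direct term: per disease, log(HR)-weighted sum of standardized EpiScores.

    Hazard-table proteins missing from the matrix are skipped with a
    warning; a disease with no overlapping protein scores 0.
    """
    diseases = list(dict.fromkeys(hazard["disease"]))
    out = pd.DataFrame(0.0, index=episcores_std.index, columns=diseases)
    for disease, grp in hazard.groupby("disease", sort=False):
        present = grp["protein_id"].isin(episcores_std.columns)
        if not present.all():
            logger.warning("disease %r: %d hazard proteins absent from the EpiScore matrix",
                           disease, int((~present).sum()))
        grp = grp.loc[present]
        if grp.empty:
            logger.warning("disease %r has no overlapping proteins; direct term is 0", disease)
            continue
        out[disease] = episcores_std[grp["protein_id"]].to_numpy() @ grp["log_hr"].to_numpy()
    return out


def compute_indirect_risk(
    fitness_std: pd.DataFrame,
    sig: pd.DataFrame,
    hazard: pd.DataFrame,
) -> pd.DataFrame:
    """Indirect term: product-of-coefficients chains through significant pairs.

    For every significant (trait j, protein i) association and every
    disease d with (i, d) in the hazard table, add
    beta(i<-j) * logHR(i, d) * fitness_z(s, j).
    """
    diseases = list(dict.fromkeys(hazard["disease"]))
    out = pd.DataFrame(0.0, index=fitness_std.index, columns=diseases)
    if sig.empty:
        logger.warning("no significant associations; indirect term is 0 everywhere")
        return out
    chains = sig.merge(hazard, on="protein_id", how="inner")
    if chains.empty:
        logger.warning("no significant association matches a hazard protein; "
                       "indirect term is 0 everywhere")
        return out
    for disease, grp in chains.groupby("disease", sort=False):
        weights = grp["beta"].to_numpy() * grp["log_hr"].to_numpy()
        out[disease] = fitness_std[grp["fitness_trait"]].to_numpy() @ weights
    return out


def compute_risk_scores(
    direct: pd.DataFrame,
    indirect: pd.DataFrame,
    config: ThresholdConfig = ThresholdConfig(),
) -> RiskTable:
    """Combine terms, z-score per disease across the cohort, flag z > threshold."""
    if not direct.index.equals(indirect.index) or list(direct.columns) != list(indirect.columns):
        raise AlignmentError("direct and indirect tables must share samples and diseases")
    raw = direct + indirect
    sds = raw.std(ddof=1)
    zero = sds[sds == 0.0]
    if not zero.empty:
        raise DegenerateScaleError(
            f"disease {zero.index[0]!r} has zero risk-score variance across the cohort"
        )
    z = (raw - raw.mean()) / sds
    flags = z > config.z_flag_threshold
    return RiskTable(raw=raw, z=z, high_risk=flags, threshold=config.z_flag_threshold,
                     direct=direct, indirect=indirect)


def _age_bins(ages: pd.Series, width: float) -> pd.Series:
    lo = np.floor(ages.min() / width) * width
    edges = np.arange(lo, ages.max() + width, width)
    labels = [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    return pd.cut(ages, bins=edges, labels=labels, right=False, include_lowest=True)


def categorize_fitness(
    fitness: pd.DataFrame,
    covariates: pd.DataFrame,
    config: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Label each sample low/normal/high per trait.

    SD-based traits use stratum mean +/- ``fitness_sd_threshold`` * SD
    boundaries within (age bin x sex) strata; strata with fewer than two
    samples or zero variance fall back to cohort-wide boundaries with a
    warning.  Cognition uses cohort-wide empirical percentiles (linear
    interpolation).  Values exactly on a boundary are "normal".
    """
    if not fitness.index.equals(covariates.index):
        raise AlignmentError("fitness and covariates must share the same sample IDs")
    bins = _age_bins(covariates["age"], config.age_bin_width)
    if config.stratify_by_sex:
        group_id = bins.astype(str) + "|sex=" + covariates["sex"].astype(str)
    else:
        group_id = bins.astype(str)

    out = pd.DataFrame(index=fitness.index)
    out["group_id"] = group_id
    for trait in fitness.columns:
        x = fitness[trait]
        if trait in PERCENTILE_TRAITS:
            lo, hi = np.percentile(x.to_numpy(), config.cognition_percentiles)
            lower = pd.Series(lo, index=x.index)
            upper = pd.Series(hi, index=x.index)
        else:
            stats_ = x.groupby(group_id, observed=True).agg(["mean", "std", "count"])
            degenerate = (stats_["count"] < 2) | (stats_["std"].fillna(0.0) == 0.0)
            if degenerate.any():
                logger.warning("trait %r: %d strata fall back to cohort-wide thresholds",
                               trait, int(degenerate.sum()))
                stats_.loc[degenerate, "mean"] = x.mean()
                stats_.loc[degenerate, "std"] = x.std(ddof=1)
            mean = group_id.map(stats_["mean"])
            sd = group_id.map(stats_["std"])
            lower = mean - config.fitness_sd_threshold * sd
            upper = mean + config.fitness_sd_threshold * sd
        category = pd.Series("normal", index=x.index)
        category[x < lower] = "low"
        category[x > upper] = "high"
        out[trait] = category
    return out


def rank_high_risk_patients(risk: RiskTable, k: int = 10) -> pd.DataFrame:
    """Rank patients by number of flagged diseases.

    Ties break by total z-score sum (descending), then sample_id
    (ascending).  Returns the top ``k`` rows with the flagged disease
    names joined by ';'.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(risk.high_risk)
    if k > n:
        logger.warning("k=%d exceeds cohort size %d; returning all patients", k, n)
        k = n
    flags = risk.high_risk
    report = pd.DataFrame({
        "sample_id": flags.index,
        "n_flagged": flags.sum(axis=1).to_numpy(),
        "flagged_diseases": [";".join(flags.columns[row]) for row in flags.to_numpy()],
        "z_sum": risk.z.sum(axis=1).to_numpy(),
    })
    report = report.sort_values(
        by=["n_flagged", "z_sum", "sample_id"], ascending=[False, False, True]
    ).head(k)
    return report.reset_index(drop=True)
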