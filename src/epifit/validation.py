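"""External CVD benchmark and correlation-based convergent validation.

An independent cardiovascular-disease EpiScore benchmark — a fixed
weighted sum over 45 protein EpiScores — is computed per patient and
correlated (Spearman by default) with each disease-specific risk score.
p-values are BH-adjusted across diseases, with significance stars at
FDR < 0.01 (**) and FDR < 0.001 (***).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .errors import AlignmentError, DegenerateScaleError, UnresolvableProbeError, ValidationError
from .risk import RiskTable


def compute_cvd_score(
    episcores: pd.DataFrame,
    cvd_weights: pd.DataFrame,
    strict: bool = True,
) -> pd.Series:
    """Weighted sum of EpiScores: score(s) = sum_i weight_i * episcore(s, i).

    Higher values mean higher epigenetic CVD risk.  Missing weighted
    proteins raise in strict mode and are dropped otherwise.
    """
    present = cvd_weights["protein_id"].isin(episcores.columns)
    if not present.all():
        missing = cvd_weights.loc[~present, "protein_id"].tolist()
        if strict:
            raise UnresolvableProbeError(
                f"CVD-weighted proteins absent from the EpiScore matrix: {missing}"
            )
        cvd_weights = cvd_weights.loc[present]
    score = episcores[cvd_weights["protein_id"]].to_numpy() @ cvd_weights["weight"].to_numpy()
    return pd.Series(score, index=episcores.index, name="cvd_score")


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AlignmentError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateScaleError("constant input has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateScaleError("constant input has no correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    return ""


def validate_against_benchmark(
    risk: RiskTable | pd.DataFrame,
    cvd_scores: pd.Series,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate each disease risk score with the CVD benchmark.

    Returns one row per disease: coefficient, p_value, q_value (BH across
    diseases) and significance stars.
    """
    scores = risk.z if isinstance(risk, RiskTable) else risk
    if not scores.index.equals(cvd_scores.index):
        raise AlignmentError("risk scores and CVD scores must share the same sample IDs")
    corr = {"spearman": spearman_corr, "pearson": pearson_corr}.get(method)
    if corr is None:
        raise ValidationError(f"unknown correlation method {method!r}")
    rows = [(d, *corr(scores[d].to_numpy(), cvd_scores.to_numpy())) for d in scores.columns]
    report = pd.DataFrame(rows, columns=["disease", "coefficient", "p_value"])
    report["q_value"] = bh_adjust(report["p_value"].to_numpy())
    report["stars"] = report["q_value"].map(_stars)
    return report


def correlation_matrix(
    left: pd.DataFrame,
    right: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlations between the columns of two aligned tables."""
    if not left.index.equals(right.index):
        raise AlignmentError("tables must share the same sample IDs")
    corr = {"spearman": spearman_corr, "pearson": pearson_corr}[method]
    out = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    for a in left.columns:
        for b in right.columns:
            out.loc[a, b] = corr(left[a].to_numpy(), right[b].to_numpy())[0]
    return out
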