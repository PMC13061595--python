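"""Covariate-adjusted OLS association scan between fitness traits and EpiScores.

One model per (trait, protein) pair:

    EpiScore ~ trait_z + sex + age

with the trait z-scored, sex coded female = 0 / male = 1, and age in
years.  The reported coefficient and two-sided t-test p-value belong to
the trait term; Benjamini-Hochberg q-values are computed across the whole
scan (or per trait, by configuration).

The least-squares core is a vectorized multi-response solver: for a fixed
design all protein columns are fit in one ``lstsq`` call, which keeps the
null-calibration and replicate-recovery simulations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, CollinearityError, DegenerateScaleError, ValidationError
from .projection import standardize_columns


@dataclass(frozen=True)
class SignificanceConfig:
    alpha: float = 0.05
    use_fdr: bool = False
    fdr_family: str = "global"  # "global" | "per-trait"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fdr_family not in ("global", "per-trait"):
            raise ValidationError(f"unknown fdr_family {self.fdr_family!r}")


@dataclass
class OLSFit:
    """Coefficients and inference for a single least-squares fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    rsquared: float
    rss: float


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Pivoted QR exposes which columns are linearly dependent on the rest.
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dependent = [names[i] for i in sorted(piv[rank:])]
        raise CollinearityError(f"design is rank deficient; dependent columns: {dependent}")


def _ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Fit Y (n x m responses) on a shared design X (n x p, incl. intercept).

    Returns (beta, se, t, p) each of shape (p, m), plus the residual df.
    SEs come from sigma2 * diag((X'X)^-1) with sigma2 = RSS / (n - p).
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValidationError(f"need n > number of parameters; n={n}, p={p}")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, pvals, df


def fit_ols(y: pd.Series | np.ndarray, X: pd.DataFrame) -> OLSFit:
    """Ordinary least squares of ``y`` on a design ``X`` that includes its intercept.

    Standard errors use sigma2 (X'X)^-1 with sigma2 = RSS / df; p-values
    are two-sided from the t distribution on the residual df.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).reshape(-1, 1)
    if yv.shape[0] != Xv.shape[0]:
        raise AlignmentError("y and X have different numbers of rows")
    _check_rank(Xv, names)
    beta, se, t, p, df = _ols_multi(Xv, yv)
    rss = float(((yv - Xv @ beta) ** 2).sum())
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    idx = pd.Index(names)
    return OLSFit(
        params=pd.Series(beta[:, 0], index=idx),
        bse=pd.Series(se[:, 0], index=idx),
        tvalues=pd.Series(t[:, 0], index=idx),
        pvalues=pd.Series(p[:, 0], index=idx),
        df_resid=df,
        rsquared=r2,
        rss=rss,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, restored to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def association_scan(
    episcores: pd.DataFrame,
    fitness: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SignificanceConfig = SignificanceConfig(),
) -> pd.DataFrame:
    """Scan every (fitness trait, EpiScore) pair with an age/sex-adjusted OLS.

    All three tables must share an identical sample_id index.  Returns one
    row per pair with columns ``fitness_trait, protein_id, beta, se,
    p_value, q_value, significant_nominal, significant_fdr``.
    """
    if not (episcores.index.equals(fitness.index) and episcores.index.equals(covariates.index)):
        raise AlignmentError("episcores, fitness and covariates must share the same sample IDs")
    if (fitness.std(ddof=1) == 0).any():
        bad = fitness.columns[(fitness.std(ddof=1) == 0)][0]
        raise DegenerateScaleError(f"fitness trait {bad!r} is constant")

    fitness_z = standardize_columns(fitness)
    Y = episcores.to_numpy(dtype=float)
    n = Y.shape[0]
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)

    frames = []
    for trait in fitness.columns:
        X = np.column_stack([np.ones(n), fitness_z[trait].to_numpy(), sex, age])
        _check_rank(X, ["intercept", trait, "sex", "age"])
        beta, se, _, p, _ = _ols_multi(X, Y)
        frames.append(pd.DataFrame({
            "fitness_trait": trait,
            "protein_id": episcores.columns,
            "beta": beta[1], "se": se[1], "p_value": p[1],
        }))
    table = pd.concat(frames, ignore_index=True)

    if config.fdr_family == "per-trait":
        table["q_value"] = table.groupby("fitness_trait")["p_value"].transform(
            lambda p: bh_adjust(p.to_numpy())
        )
    else:
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant_nominal"] = table["p_value"] < config.alpha
    table["significant_fdr"] = table["q_value"] < config.alpha
    return table


def significant_associations(table: pd.DataFrame, config: SignificanceConfig) -> pd.DataFrame:
    """Subset of scan rows that pass the configured significance rule."""
    col = "significant_fdr" if config.use_fdr else "significant_nominal"
    return table.loc[table[col]].reset_index(drop=True)
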