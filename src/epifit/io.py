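"""Readers and writers for every table the pipeline touches.

All inter-stage artifacts are plain CSV/TSV so each stage is independently
testable and diffable.  Methylation is accepted as TSV with CpG probes as
rows and sample IDs as columns (the transposed layout common to
methylation toolchains); an orientation flag accepts samples-as-rows.
Floats are written with 10 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .projection import validate_betas
from .risk import ThresholdConfig
from .association import SignificanceConfig

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

SEX_RECODE = {"F": 0, "FEMALE": 0, "W": 0, "0": 0, "M": 1, "MALE": 1, "1": 1}


def _sep(path: Path | str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_methylation(path: Path | str, orientation: str = "probes-rows") -> pd.DataFrame:
    """Read a beta matrix; returns probes x samples regardless of file orientation."""
    meth = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "samples-rows":
        meth = meth.T
    elif orientation != "probes-rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    if meth.index.duplicated().any():
        dup = meth.index[meth.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated CpG probe {dup!r}")
    if meth.columns.duplicated().any():
        dup = meth.columns[meth.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicated sample ID {dup!r}")
    meth.index.name = "cpg_id"
    validate_betas(meth)
    return meth


def read_covariates(path: Path | str) -> pd.DataFrame:
    """Read sample_id, age, sex; recode F/M style sex labels to 0/1."""
    cov = pd.read_csv(path, sep=_sep(path))
    _require(cov, path, ["sample_id", "age", "sex"])
    cov = cov.set_index("sample_id")
    if cov.index.duplicated().any():
        raise ValidationError(f"{path}: duplicated sample IDs")
    if not pd.api.types.is_numeric_dtype(cov["sex"]):
        recoded = cov["sex"].astype(str).str.strip().str.upper().map(SEX_RECODE)
        if recoded.isna().any():
            bad = cov.loc[recoded.isna(), "sex"].iloc[0]
            raise ValidationError(f"{path}: unrecognized sex code {bad!r}")
        logger.info("recoded sex labels to numeric (female = 0, male = 1)")
        cov["sex"] = recoded
    cov["sex"] = cov["sex"].astype(int)
    if not cov["sex"].isin([0, 1]).all():
        raise ValidationError(f"{path}: sex must be coded 0 (female) / 1 (male)")
    return cov[["age", "sex"]]


def read_fitness(path: Path | str) -> pd.DataFrame:
    fit = pd.read_csv(path, sep=_sep(path))
    _require(fit, path, ["sample_id"])
    fit = fit.set_index("sample_id")
    if fit.isna().any().any():
        raise ValidationError(f"{path}: fitness table has missing values "
                              "(the pipeline models a complete-case cohort)")
    return fit


def read_weights(path: Path | str) -> pd.DataFrame:
    w = pd.read_csv(path, sep=_sep(path))
    _require(w, path, ["protein_id", "cpg_id", "weight"])
    if w.duplicated(["protein_id", "cpg_id"]).any():
        raise ValidationError(f"{path}: duplicated (protein, cpg) weight entries")
    return w


def read_reference_means(path: Path | str) -> pd.Series:
    ref = pd.read_csv(path, sep=_sep(path))
    _require(ref, path, ["cpg_id", "mean_beta"])
    if ((ref["mean_beta"] < 0) | (ref["mean_beta"] > 1)).any():
        raise ValidationError(f"{path}: reference mean betas must lie in [0, 1]")
    return ref.set_index("cpg_id")["mean_beta"]


def read_hazard(path: Path | str) -> pd.DataFrame:
    hz = pd.read_csv(path, sep=_sep(path))
    if "log_hr" not in hz.columns and "hr" in hz.columns:
        logger.warning("%s: 'hr' column supplied; taking natural logarithms", path)
        if (hz["hr"] <= 0).any():
            raise ValidationError(f"{path}: hazard ratios must be positive")
        hz["log_hr"] = np.log(hz["hr"])
    _require(hz, path, ["disease", "protein_id", "log_hr"])
    if hz.duplicated(["disease", "protein_id"]).any():
        raise ValidationError(f"{path}: duplicated (disease, protein) hazard entries")
    return hz[["disease", "protein_id", "log_hr"]]


def read_cvd_weights(path: Path | str) -> pd.DataFrame:
    w = pd.read_csv(path, sep=_sep(path))
    _require(w, path, ["protein_id", "weight"])
    return w


def read_name_mapping(path: Path | str) -> pd.DataFrame:
    m = pd.read_csv(path, sep=_sep(path))
    _require(m, path, ["raw_name", "standard_name"])
    return m


def read_episcores(path: Path | str) -> pd.DataFrame:
    e = pd.read_csv(path, sep=_sep(path), index_col=0)
    e.index.name = "sample_id"
    return e


def _require(df: pd.DataFrame, path, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}; "
                              f"found {list(df.columns)}")


def write_table(df: pd.DataFrame, path: Path | str, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=index, float_format=FLOAT_FORMAT)


def write_matrix(df: pd.DataFrame, path: Path | str) -> None:
    write_table(df, path, index=True)


def write_series(s: pd.Series, path: Path | str) -> None:
    write_table(s.reset_index(), path)


@dataclass
class PipelineConfig:
    """Paths and settings for a full pipeline run."""

    methylation: str
    covariates: str
    fitness: str
    weights: str
    ref_means: str
    hazard: str
    cvd_weights: str
    out_dir: str
    name_mapping: str | None = None
    orientation: str = "probes-rows"
    strict_names: bool = True
    seed: int = 0
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    expected_directions: dict[str, int] | None = None
    top_k: int = 10
    correlation_method: str = "spearman"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "significance" in raw:
            raw["significance"] = SignificanceConfig(**raw["significance"])
        if "thresholds" in raw:
            thr = raw["thresholds"]
            for key in ("cognition_percentiles",):
                if key in thr:
                    thr[key] = tuple(thr[key])
            raw["thresholds"] = ThresholdConfig(**thr)
        return cls(**raw)
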