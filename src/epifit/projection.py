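"""EpiScore projection: weighted linear combinations of CpG beta values.

An EpiScore estimates a circulating plasma protein level from blood DNA
methylation as score = sum_k w_k * beta_k over the protein's predictive
CpG set.  Probes missing from the input matrix (or individual missing
values) are imputed with population reference mean betas; the per-protein
imputation rate is reported and scores above a configurable imputed
fraction are flagged unreliable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, UnresolvableProbeError, ValidationError

logger = logging.getLogger(__name__)

#: Proteins with more than this fraction of imputed probe values are flagged.
DEFAULT_MAX_IMPUTED_FRACTION = 0.2


def validate_betas(meth: pd.DataFrame) -> None:
    """Betas are methylation proportions: NaN (missing) or within [0, 1]."""
    values = meth.to_numpy(dtype=float)
    bad = ~np.isnan(values) & ((values < 0.0) | (values > 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta outside [0, 1] at probe {meth.index[i]!r}, sample {meth.columns[j]!r}: "
            f"{values[i, j]!r}"
        )


def project_episcores(
    meth: pd.DataFrame,
    weights: pd.DataFrame,
    ref_means: pd.Series,
    max_imputed_fraction: float = DEFAULT_MAX_IMPUTED_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project a probes x samples beta matrix onto every weight set.

    Parameters
    ----------
    meth
        Beta values, CpG probes as rows and samples as columns; NaN marks
        a missing measurement.
    weights
        Long-format table with columns ``protein_id``, ``cpg_id``,
        ``weight``.
    ref_means
        Population mean beta per CpG, used to impute probes absent from
        ``meth`` and individual missing values.

    Returns
    -------
    (episcores, report)
        ``episcores`` is samples x proteins; ``report`` has one row per
        protein with ``n_cpgs``, ``n_imputed`` (imputed value count summed
        over samples), ``imputed_fraction`` and an ``unreliable`` flag.
    """
    validate_betas(meth)
    n_samples = meth.shape[1]
    scores: dict[str, np.ndarray] = {}
    report_rows = []
    for pid, grp in weights.groupby("protein_id", sort=False):
        cpgs = grp["cpg_id"].to_numpy()
        w = grp["weight"].to_numpy()
        block = meth.reindex(cpgs).to_numpy(dtype=float)
        missing = np.isnan(block)
        if missing.any():
            ref = ref_means.reindex(cpgs).to_numpy(dtype=float)
            unresolvable = missing.all(axis=1) & np.isnan(ref)
            if unresolvable.any():
                raise UnresolvableProbeError(
                    f"probe {cpgs[np.argmax(unresolvable)]!r} (protein {pid!r}) is absent "
                    "from the methylation matrix and has no reference mean"
                )
            if np.isnan(ref[missing.any(axis=1)]).any():
                bad = cpgs[missing.any(axis=1) & np.isnan(ref)][0]
                raise UnresolvableProbeError(
                    f"probe {bad!r} (protein {pid!r}) has missing values and no reference mean"
                )
            block = np.where(missing, ref[:, None], block)
        scores[pid] = w @ block
        n_imputed = int(missing.sum())
        frac = n_imputed / (len(cpgs) * n_samples)
        report_rows.append((pid, len(cpgs), n_imputed, frac,
                            frac > max_imputed_fraction))
    episcores = pd.DataFrame(scores, index=meth.columns)
    episcores.index.name = "sample_id"
    report = pd.DataFrame(
        report_rows,
        columns=["protein_id", "n_cpgs", "n_imputed", "imputed_fraction", "unreliable"],
    )
    n_flagged = int(report["unreliable"].sum())
    if n_flagged:
        logger.warning("%d protein EpiScores exceed the imputed-fraction limit", n_flagged)
    return episcores, report


def harmonize_names(
    raw_names: list[str],
    mapping: pd.DataFrame,
    strict: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Resolve raw EpiScore names to the standardized protein nomenclature.

    ``mapping`` has columns ``raw_name`` and ``standard_name`` (extra
    columns such as identifier/panel/note pass through untouched).  When
    several raw names resolve to the same standard name each is kept as a
    separate column with a ``.1``, ``.2``... suffix and flagged in the
    returned log.  Unmapped names raise in strict mode and pass through
    with a warning otherwise.
    """
    if mapping["raw_name"].duplicated().any():
        dup = mapping.loc[mapping["raw_name"].duplicated(), "raw_name"].iloc[0]
        raise ValidationError(f"raw name {dup!r} mapped more than once")
    lookup = mapping.set_index("raw_name")["standard_name"]
    standards = []
    flags = []
    for raw in raw_names:
        if raw in lookup.index:
            standards.append(lookup[raw])
            flags.append("mapped")
        elif strict:
            raise ValidationError(f"raw EpiScore name {raw!r} has no mapping entry")
        else:
            logger.warning("unmapped EpiScore name %r passed through", raw)
            standards.append(raw)
            flags.append("passthrough")
    counts = pd.Series(standards).value_counts()
    seen: dict[str, int] = {}
    resolved = []
    for raw, std in zip(raw_names, standards):
        if counts[std] > 1:
            seen[std] = seen.get(std, 0) + 1
            resolved.append(f"{std}.{seen[std]}")
            logger.warning("raw name %r shares standard name %r; kept as %r",
                           raw, std, resolved[-1])
        else:
            resolved.append(std)
    log = pd.DataFrame({"raw_name": raw_names, "standard_name": standards,
                        "resolved_name": resolved, "status": flags})
    log.loc[log["resolved_name"] != log["standard_name"], "status"] = "duplicate"
    return resolved, log


def standardize_columns(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """z-score every column: (x - mean) / SD with the sample SD (n - ddof).

    Raises :class:`DegenerateScaleError` naming the first constant column.
    """
    means = matrix.mean()
    sds = matrix.std(ddof=ddof)
    zero = sds[sds == 0.0]
    if not zero.empty:
        raise DegenerateScaleError(
            f"column {zero.index[0]!r} is constant and cannot be standardized"
        )
    return (matrix - means) / sds
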