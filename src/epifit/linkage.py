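"""Join fitness-EpiScore associations to external EpiScore-disease hazards.

The causal chain is evaluated in two published steps: (i) fitness trait ->
EpiScore, estimated here by the association scan; (ii) EpiScore ->
disease, taken from external Cox-model log hazard ratios.  A link's net
direction is sign(beta * log HR), and consistency compares that net sign
with an a-priori expected risk direction per trait (by default BMI is
risk-increasing, the other four traits protective).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Expected net risk direction per trait: +1 risk-increasing, -1 protective.
DEFAULT_EXPECTED_DIRECTIONS: dict[str, int] = {
    "BMI": +1,
    "VO2max": -1,
    "GripStrength": -1,
    "JumpMax": -1,
    "Cognition": -1,
}


def link_fitness_disease(sig: pd.DataFrame, hazard: pd.DataFrame) -> pd.DataFrame:
    """Inner-join significant associations with the hazard table on protein_id.

    One output row per (trait, protein, disease) triple with ``beta``,
    ``log_hr``, ``net_sign`` = sign(beta * log_hr) and a ``zero_product``
    flag for degenerate links.  An empty join is returned with a warning.
    """
    links = sig.merge(hazard, on="protein_id", how="inner")
    if links.empty:
        logger.warning("no significant association matched any hazard-table protein")
        return pd.DataFrame(columns=["fitness_trait", "protein_id", "disease",
                                     "beta", "log_hr", "net_sign", "zero_product"])
    links = links[["fitness_trait", "protein_id", "disease", "beta", "log_hr"]].copy()
    product = links["beta"].to_numpy() * links["log_hr"].to_numpy()
    links["net_sign"] = np.sign(product).astype(int)
    links["zero_product"] = product == 0.0
    if links["zero_product"].any():
        logger.warning("%d links have a zero beta x log(HR) product",
                       int(links["zero_product"].sum()))
    return links.reset_index(drop=True)


def assess_direction_consistency(
    links: pd.DataFrame,
    expected: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Flag each link as consistent when its net sign equals the expected direction.

    Zero net signs count as inconsistent.  Returns the annotated table and
    the consistent-link count.
    """
    expected = DEFAULT_EXPECTED_DIRECTIONS if expected is None else expected
    missing = set(links["fitness_trait"]) - set(expected)
    if missing:
        raise ConfigurationError(f"no expected direction for traits: {sorted(missing)}")
    out = links.copy()
    out["expected_sign"] = out["fitness_trait"].map(expected).astype(int) if len(out) else []
    out["consistent"] = (out["net_sign"] == out["expected_sign"]) & (out["net_sign"] != 0)
    return out, int(out["consistent"].sum())


def link_granularities(links: pd.DataFrame) -> dict[str, int]:
    """Association counts at both granularities: triples and (trait, disease) pairs."""
    return {
        "n_triples": len(links),
        "n_trait_disease_pairs": int(links.groupby(["fitness_trait", "disease"]).ngroups)
        if len(links) else 0,
    }
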