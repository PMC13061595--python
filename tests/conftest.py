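import numpy as np
import pandas as pd
import pytest

from epifit.cohort import FITNESS_TRAITS, CohortSpec, simulate_study


def small_effect_matrix(n_proteins: int = 6) -> pd.DataFrame:
    """Sparse planted effects for a desk-scale study: 3 nonzero chains."""
    cols = [f"PROT_{i:03d}" for i in range(1, n_proteins + 1)]
    eff = pd.DataFrame(0.0, index=list(FITNESS_TRAITS), columns=cols)
    eff.loc["BMI", cols[0]] = 0.4
    eff.loc["JumpMax", cols[1]] = -0.35
    eff.loc["GripStrength", cols[2]] = -0.3
    return eff


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    # 10 CpGs with larger weights keep the embedding perturbation per CpG
    # small (it scales as 1 / (k * |w|)), so clipping is rare at desk scale.
    return CohortSpec(
        n_samples=80,
        n_proteins=6,
        cpgs_per_protein=10,
        n_diseases=3,
        n_cvd_proteins=3,
        effect_matrix=small_effect_matrix(),
        noise_sd=0.3,
        weight_abs_range=(0.3, 0.5),
        ref_mean_range=(0.45, 0.55),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return simulate_study(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
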