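import numpy as np
import pandas as pd
import pytest

from exermap.simulate import EffectSpec, generate_cohort, generate_omics


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """24 participants, 8 per group, real profile proportions."""
    return generate_cohort(dict(EE=8, RE=8, CON=8), seed=11)


@pytest.fixture(scope="session")
def middle_cohort() -> pd.DataFrame:
    """20 pairs per group, all randomized to the middle (4hr) profile."""
    return generate_cohort(dict(EE=20, RE=20, CON=20),
                           profile_weights=(0.0, 1.0, 0.0), seed=12)


@pytest.fixture(scope="session")
def planted_omics(middle_cohort):
    """Protein-like matrix with strong planted delta-delta effects."""
    spec = EffectSpec(n_features_per_ome=300, frac_dd_affected=0.1,
                      dd_effect=1.0, n_modules=2, module_size=30,
                      trajectory_shapes=False, omes=("protein",), seed=21)
    matrices, truth = generate_omics(middle_cohort, spec)
    return matrices["protein"], truth, spec
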