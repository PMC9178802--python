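import warnings

import numpy as np
import pytest

from methylssl import (
    BetaMatrix,
    CohortSpec,
    FeatureSelectConfig,
    generate_cohort,
    select_features_by_sd,
)

warnings.filterwarnings("ignore", category=FutureWarning)

# SD cut used on desk-scale synthetic cohorts: above the uninformative-probe
# noise SD, below the informative between-class spread
DESK_SD = 0.2


@pytest.fixture(scope="session")
def separable_cohort():
    """Six tight subclasses in three families; 1-NN-perfect by construction."""
    spec = CohortSpec(
        n_families=3,
        subclasses_per_family=[2, 2, 2],
        samples_per_subclass=[12] * 6,
        n_probes=300,
        n_informative_per_subclass=20,
        concentration=500.0,
        seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_features(separable_cohort):
    beta = BetaMatrix.from_frame(separable_cohort.beta)
    return select_features_by_sd(beta, FeatureSelectConfig(DESK_SD))


@pytest.fixture(scope="session")
def midnoise_cohort():
    """Imbalanced cohort with within-family confusion (moderate noise)."""
    spec = CohortSpec(
        n_families=3,
        subclasses_per_family=[2, 2, 2],
        samples_per_subclass=[40, 40, 30, 30, 10, 10],
        n_probes=1000,
        n_informative_per_subclass=16,
        family_share=0.7,
        concentration=7.0,
        seed=200,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
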