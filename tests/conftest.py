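import numpy as np
import pytest

from devodiverge import AgeTransform, common_age_grid, fit_species_trajectories
from devodiverge.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def transform():
    return AgeTransform()


@pytest.fixture(scope="session")
def small_bundle():
    """A modest three-species study with all gene types and regulators."""
    cfg = SyntheticConfig(
        n_type1=50,
        n_type2=50,
        n_type3=60,
        n_null=50,
        n_coupled=3,
        n_decoy=20,
        targets_per_regulator=12,
        seed=101,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_models_grid(small_bundle):
    """Fitted trajectories and the common grid for the small bundle."""
    b = small_bundle
    grid = common_age_grid(b.expression.samples, b.transform)
    models = fit_species_trajectories(b.expression, b.transform)
    models.update(fit_species_trajectories(b.regulator_expression, b.transform))
    return models, grid


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
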