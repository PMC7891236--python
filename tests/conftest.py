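import numpy as np
import pytest

from gliotopo import fixtures


def small_config(seed: int = 7, **overrides) -> fixtures.SyntheticConfig:
    base = dict(
        seed=seed,
        grid_shape=(32, 32, 32),
        n_parcels_per_hemisphere=40,
        n_subcortical=4,
        n_patients=60,
        n_genes=300,
        n_samples=150,
        n_components=64,
        lesion_radius_median_mm=10.0,
    )
    base.update(overrides)
    return fixtures.SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_parc(small_cfg):
    return fixtures.make_parcellation(small_cfg)


@pytest.fixture(scope="session")
def small_fields(small_cfg, small_parc):
    return fixtures.make_ground_truth_fields(small_cfg, small_parc)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_parc, small_fields):
    return fixtures.make_lesion_cohort(small_cfg, small_parc, small_fields["frequency"])


@pytest.fixture(scope="session")
def small_atlas_bundle(small_cfg, small_parc, small_fields):
    return fixtures.make_expression_atlas(small_cfg, small_parc, small_fields["frequency"])


@pytest.fixture(scope="session")
def full_cfg():
    """Study-scale configuration (167 parcels per hemisphere)."""
    return fixtures.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def parc167(full_cfg):
    return fixtures.make_parcellation(full_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
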