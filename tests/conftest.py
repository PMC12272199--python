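import numpy as np
import pytest

from widedecode.bootstrap import BootstrapConfig
from widedecode.synthetic import (
    MapStudyConfig,
    SedationStudyConfig,
    gen_map_study,
    gen_sedation_study,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240729)


@pytest.fixture(scope="session")
def null_study():
    return gen_map_study(
        MapStudyConfig(n_subjects=20, n_voxels=400, signal_profile="null", seed=101)
    )


@pytest.fixture(scope="session")
def widespread_study():
    return gen_map_study(
        MapStudyConfig(n_subjects=30, n_voxels=2000, signal_profile="widespread", seed=102)
    )


@pytest.fixture(scope="session")
def latent_study():
    return gen_map_study(
        MapStudyConfig(
            n_subjects=30, n_voxels=2000, signal_profile="widespread",
            effect_scale=0.1, latent_rank=3, latent_strength=3.0, seed=103,
        )
    )


@pytest.fixture(scope="session")
def small_sedation_study():
    return gen_sedation_study(
        SedationStudyConfig(n_subjects=8, n_timepoints=100, background_voxels=100, seed=104)
    )


@pytest.fixture()
def quick_bootstrap():
    return BootstrapConfig(n_replicates=30, seed=7)
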