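"""Shared fixtures: small stimulus sets, synthetic cortices and datasets.

Everything is generated programmatically at session scope so expensive
objects (Gabor convolutions, simulations) are built once.
"""

import numpy as np
import pytest

from voxenc.cortex import (AreaSpec, CortexConfig, build_synthetic_cortex,
                           simulate_responses)
from voxenc.stimuli import generate_experiment_stimuli

RES = 24


def small_area_specs(n_voxels=8, noise_sd=0.7, jitter=0.0):
    return [
        AreaSpec(n_voxels=n_voxels, rf_slope=0.10, rf_intercept=4.0,
                 rf_jitter_sd=jitter, noise_sd=noise_sd),
        AreaSpec(n_voxels=n_voxels, rf_slope=0.15, rf_intercept=6.0,
                 rf_jitter_sd=jitter, noise_sd=noise_sd),
        AreaSpec(n_voxels=n_voxels, rf_slope=0.22, rf_intercept=8.0,
                 rf_jitter_sd=jitter, noise_sd=noise_sd),
        AreaSpec(n_voxels=n_voxels, rf_slope=0.30, rf_intercept=11.0,
                 rf_jitter_sd=jitter, noise_sd=noise_sd),
    ]


@pytest.fixture(scope="session")
def stimuli_small():
    return generate_experiment_stimuli(n_train=120, n_shared=60,
                                       resolution=RES, seed=11)


@pytest.fixture(scope="session")
def cortex_hier():
    cfg = CortexConfig(regime="hierarchical", resolution=RES, seed=21,
                       areas=small_area_specs())
    return build_synthetic_cortex(cfg)


@pytest.fixture(scope="session")
def cortex_par():
    cfg = CortexConfig(regime="parallel", resolution=RES, seed=21,
                       areas=small_area_specs())
    return build_synthetic_cortex(cfg)


@pytest.fixture(scope="session")
def dataset_small(cortex_hier, stimuli_small):
    return simulate_responses(cortex_hier, stimuli_small, n_repeats=3,
                              n_sessions=4, seed=31)


@pytest.fixture(scope="session")
def signals_small(cortex_hier, stimuli_small):
    return cortex_hier.voxel_signals(stimuli_small.images)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
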