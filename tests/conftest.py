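import numpy as np
import pytest

from flashgrab.synth import EEGSimConfig, VoxelSimConfig, simulate_eeg_study, simulate_voxel_table


@pytest.fixture(scope="session")
def noiseless_eeg_study():
    """Tiny study with components but no noise: analytic reconstructions."""
    cfg = EEGSimConfig(
        n_subjects=2, n_trials_per_cell=4, decimate=4,
        noise_white_sd_uv=0.0, noise_pink_sd_uv=0.0,
    )
    return cfg, simulate_eeg_study(cfg)


@pytest.fixture(scope="session")
def noisy_eeg_study():
    """Small noisy study shared across EEG analysis tests."""
    cfg = EEGSimConfig(n_subjects=3, n_trials_per_cell=30, decimate=8, seed=7)
    return cfg, simulate_eeg_study(cfg)


@pytest.fixture(scope="session")
def noiseless_voxels():
    cfg = VoxelSimConfig(
        areas=("V1", "V2"),
        noise_sd=0.0,
        illusion_shift={
            "V1": {"S": 10.0, "M": 0.0, "D": 5.0},
            "V2": {"S": 8.5, "M": 7.0, "D": 7.5},
        },
        seed=3,
    )
    return cfg, simulate_voxel_table(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
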