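import dataclasses

import numpy as np
import pytest

from brainage.nn import ArchitectureConfig, TrainConfig, build_model, train
from brainage.pipeline import default_study_config, run_study
from brainage.synthetic import CohortConfig, make_atlas, render_cohort, sample_cohort

DESK_ARCH = ArchitectureConfig(
    input_shape=(16, 16, 16), in_channels=2, n_blocks=2, base_channels=4
)


@pytest.fixture(scope="session")
def atlas16():
    return make_atlas((16, 16, 16), 5, seed=11)


@pytest.fixture(scope="session")
def strong_cohort(atlas16):
    """Small noiseless cohort with strong planted age slopes (easy signal)."""
    cfg = CohortConfig(
        name="strong",
        n_subjects=24,
        grid_shape=(16, 16, 16),
        roi_age_slopes={1: -0.030, 2: 0.020, 3: -0.010, 4: 0.0, 5: 0.0},
        noise_sd=0.0,
        smoothing_fwhm=0.0,
        site_offsets=(0.0, 0.0),
        sex_effect=0.0,
        seed=21,
    )
    records = sample_cohort(cfg)
    volumes = render_cohort(records, atlas16, cfg)
    ages = np.array([r.age for r in records], dtype=np.float32)
    return cfg, records, volumes, ages


@pytest.fixture(scope="session")
def overfit_model(strong_cohort):
    """Desk-scale CNN memorizing 20 noiseless phantoms (fixed seed)."""
    _, _, volumes, ages = strong_cohort
    model = build_model(DESK_ARCH, seed=3)
    tcfg = TrainConfig(batch_size=16, max_epochs=60, early_stop_patience=25, seed=3)
    train(model, volumes[:20], ages[:20], volumes[20:], ages[20:], tcfg)
    return model, volumes, ages


@pytest.fixture(scope="session")
def desk_study():
    """The two-cohort desk-scale study under the default conditions."""
    return run_study(default_study_config(master_seed=7))
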