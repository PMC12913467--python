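import numpy as np
import pytest

from pggan.cohort import PhantomParams, generate_cohort, split_cohort
from pggan.progress import map_bank
from pggan.training import prepare_cohort


@pytest.fixture(scope="session")
def small_params():
    """10-subject 16^3 cohort with moderate noise and heterogeneity."""
    return PhantomParams(grid_shape=(16, 16, 16), n_subjects=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    cohort, fields = generate_cohort(small_params)
    split_cohort(cohort, (8, 1, 1), seed=1)
    return cohort, fields


@pytest.fixture(scope="session")
def noiseless_params():
    return PhantomParams(
        grid_shape=(16, 16, 16),
        n_subjects=6,
        subject_heterogeneity_sd=0.0,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_params):
    return generate_cohort(noiseless_params)


@pytest.fixture(scope="session")
def trained_setup():
    """A tiny trained checkpoint shared by training/evaluation tests."""
    from pggan.model import GeneratorSpec
    from pggan.training import LossConfig, TrainConfig, train

    params = PhantomParams(grid_shape=(16, 16, 16), n_subjects=8, seed=11)
    cohort, _ = generate_cohort(params)
    split_cohort(cohort, (4, 2, 2), seed=2)
    cohort = prepare_cohort(cohort)
    bank = map_bank(cohort, ["1y", "4y"])
    spec = GeneratorSpec(fusion_mode="ffm", base_channels=2)
    tcfg = TrainConfig(batch_size=2, max_epochs=2, seed=5, task="multi_term")
    ckpt = train(cohort, params.intervals, bank, spec, tcfg, LossConfig())
    return params, cohort, bank, ckpt
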