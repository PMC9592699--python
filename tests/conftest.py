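import numpy as np
import pytest

from dualmatch import synthetic, training


@pytest.fixture(scope="session")
def tiny_task():
    """Small separable texture task shared across training tests."""
    return synthetic.gen_task(
        synthetic.SyntheticSpec(n_per_class=8, image_size=32, seed=5,
                                task_id="source1"))


@pytest.fixture(scope="session")
def tiny_source(tiny_task):
    """A pretrained, frozen source network on the tiny task."""
    cfg = training.PretrainConfig(lr=0.05, epochs=20, batch_size=8, seed=3,
                                  widths=(4, 8, 12, 16))
    return training.pretrain_source(tiny_task, cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    return synthetic.gen_patient_cohort(8, (3, 4), 0.5, seed=9, image_size=64,
                                        noise_sd=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
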