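import numpy as np
import pytest

from steatolens.synthetic import GeneratorConfig, make_dataset, render_case, sample_donor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def rendered_case(default_cfg):
    """One moderately steatotic rendered case with lighting distortion."""
    donor, hs = sample_donor(default_cfg, np.random.default_rng(11), hs=30.0)
    return render_case(default_cfg, donor, hs, seed=77)


@pytest.fixture(scope="session")
def tiny_dataset(default_cfg):
    """A 12-case synthetic dataset for pipeline-level tests."""
    import dataclasses

    cfg = dataclasses.replace(default_cfg, n_cases=12, seed=3)
    return make_dataset(cfg)
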