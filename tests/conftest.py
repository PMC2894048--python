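import pytest

from gagfib.multivariate import PredictiveModel
from gagfib.synthetic_data import GeneratorConfig, generate_entries, noise_for_target_r2


@pytest.fixture(scope="session")
def demo_entries():
    """The bundled synthetic 39-entry database."""
    from gagfib import load_demo_dataset

    return load_demo_dataset()


@pytest.fixture(scope="session")
def noiseless_entries():
    """39 entries generated exactly from the predictive equation (no noise)."""
    return generate_entries(GeneratorConfig(n_entries=39, seed=2, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_entries():
    """39 entries with noise calibrated so the equation explains ~74% of variance."""
    cfg = GeneratorConfig(n_entries=39, seed=11)
    cfg.noise_sd = noise_for_target_r2(cfg, 0.74)
    return generate_entries(cfg)


@pytest.fixture(scope="session")
def published_model():
    return PredictiveModel.published()
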