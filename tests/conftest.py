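import numpy as np
import pytest

from paddyfuse import phenosim

SMALL_COUNTS = {"single": 40, "double": 30, "regenerated": 20, "other": 30}

#: Fast hyperparameter overrides for pipeline-level tests (fewer boosting
#: stages / trees; identical code paths).
FAST_HP = {"rf": {"n_estimators": 25}, "gbdt": {"n_estimators": 25}}


@pytest.fixture(scope="session")
def default_params():
    return phenosim.default_pheno_params()


@pytest.fixture(scope="session")
def noiseless_curves(default_params):
    return {cid: p.noiseless_curve() for cid, p in default_params.items()}


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy labelled dataset shared across classifier tests."""
    return phenosim.simulate_samples(SMALL_COUNTS, noise_sd=0.03, seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return phenosim.simulate_samples(SMALL_COUNTS, noise_sd=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
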