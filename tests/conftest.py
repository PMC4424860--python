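import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import icsift as ic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg() -> ic.GeneratorConfig:
    return ic.GeneratorConfig(n_rfn=5, n_art=8, seed=3)


@pytest.fixture(scope="session")
def templates(small_cfg):
    return ic.make_templates(small_cfg)


@pytest.fixture(scope="session")
def gm(templates):
    return templates[0]


@pytest.fixture(scope="session")
def small_set(small_cfg):
    return ic.make_ica_set(small_cfg)


@pytest.fixture(scope="session")
def train_corpus(gm):
    """Labeled 50-component training corpus: raw features plus binary labels."""
    cfg = ic.GeneratorConfig(n_rfn=17, n_art=33, seed=11)
    ica_set, labels = ic.make_ica_set(cfg)
    table = ic.extract_feature_table(ica_set, gm)
    y = np.array([1 if labels[i] == ic.RFN else 0 for i in table.index])
    return ica_set, labels, table, y


@pytest.fixture(scope="session")
def test_corpus(gm):
    """Independent 30-component evaluation corpus (10 RFN / 20 ART)."""
    cfg = ic.GeneratorConfig(n_rfn=10, n_art=20, seed=23)
    ica_set, labels = ic.make_ica_set(cfg)
    return ica_set, labels


@pytest.fixture(scope="session")
def trained_model(train_corpus):
    _, _, table, y = train_corpus
    return ic.fit_conditioned(table, y, seed=5)
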