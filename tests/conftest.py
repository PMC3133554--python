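import numpy as np
import pytest

import epitopescan as es


@pytest.fixture(scope="session")
def best_config() -> es.FeatureConfig:
    """The best-performing feature combination: n-grams + PSSM + SS + accessibility."""
    return es.FeatureConfig(blocks=es.BEST_FEATURE_BLOCKS)


@pytest.fixture(scope="session")
def poly3() -> es.KernelSpec:
    return es.KernelSpec("poly", degree=3)


@pytest.fixture(scope="session")
def recovery_data():
    """Labeled peptides + annotations at the package's study conditions."""
    config = es.SyntheticConfig(seed=1)
    records, annotations = es.generate_labeled_peptides(config)
    return config, records, annotations


@pytest.fixture(scope="session")
def recovery_design(recovery_data, best_config):
    _, records, annotations = recovery_data
    X, y, ids = es.featurize_records(records, annotations, best_config)
    return X, y, ids


@pytest.fixture(scope="session")
def recovery_model(recovery_design, best_config, poly3) -> es.TrainedModel:
    X, y, _ = recovery_design
    return es.train(
        X, y, poly3, seed=1, feature_config=best_config, peptide_length=15
    )


@pytest.fixture(scope="session")
def ngram_model() -> es.TrainedModel:
    """A small, annotation-free peptide model for fast scanning unit tests."""
    config = es.SyntheticConfig(n_pos=40, n_neg=40, seed=7)
    records, _ = es.generate_labeled_peptides(config)
    feature_config = es.FeatureConfig(ngram_max=2, blocks=("ngram",))
    X, y, _ = es.featurize_records(records, None, feature_config)
    return es.train(
        X, y, es.KernelSpec("linear"), seed=7,
        feature_config=feature_config, peptide_length=15,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
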