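import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from crossdti.data import split_dataset
from crossdti.estimator import DTIClassifier
from crossdti.synthetic import SyntheticSpec, generate


def xy(samples):
    X = [(s.drug_smiles, s.protein_seq) for s in samples]
    return X, np.array([s.label for s in samples])


@pytest.fixture(scope="session")
def small_samples():
    """A 240-pair planted-signal dataset shared across tests."""
    return generate(SyntheticSpec(n_pairs=240, seed=42))


@pytest.fixture(scope="session")
def small_dataset(small_samples):
    return split_dataset(small_samples, seed=42)


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A small trained CA_P model for inference-path tests.

    Deliberately down-sized (hidden 96, short caps, 4 epochs) so the
    whole suite stays fast; accuracy is asserted elsewhere."""
    Xtr, ytr = xy(small_dataset.subset("train"))
    Xv, yv = xy(small_dataset.subset("valid"))
    clf = DTIClassifier(architecture="CA_P", scheme="fcs", hidden_size=96,
                        max_len_drug=48, max_len_protein=64,
                        max_vocab_drug=120, max_vocab_protein=300,
                        max_epochs=4, batch_size=64, random_state=0)
    clf.fit(Xtr, ytr, validation_data=(Xv, yv))
    return clf
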