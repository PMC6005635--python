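import numpy as np
import pytest

from ecotopics.corrlda import Hyperparameters, train
from ecotopics.synth import default_regime, generate_corpus


@pytest.fixture(scope="session")
def tiny_setup():
    """A fixed tiny paired corpus (D=2, K=2, V=3, S=2, N_d=3, M_d=1) small
    enough for exhaustive posterior enumeration, with its hyperparameters."""
    corpus, truth = generate_corpus(
        K=2, D=2, V=3, S=2, alpha=0.5, beta=0.5, gamma=0.5, N_d=3, M_d=1, seed=1
    )
    hyper = Hyperparameters(np.array([0.4, 0.7]), 0.5, 0.6)
    return corpus, hyper


@pytest.fixture(scope="session")
def recovery_setup():
    """The standard recovery regime plus a model trained on it; shared by the
    recovery, prediction and embedding tests to avoid re-training."""
    corpus, truth = default_regime(seed=11)
    model = train(corpus, K=5, iterations=500, seed=3)
    return corpus, truth, model
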