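import numpy as np
import pytest
from hypothesis import settings

import lncsieve as L

settings.register_profile("fixed", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_config():
    return L.GeneratorConfig(n_per_class=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small separable two-class set: (coding, noncoding)."""
    return L.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_labelled(small_dataset):
    """(sequences, labels) with lncRNA first, the CV-ready layout."""
    coding, noncoding = small_dataset
    seqs = noncoding + coding
    labels = ["lncRNA"] * len(noncoding) + ["coding"] * len(coding)
    return seqs, labels


@pytest.fixture(scope="session")
def small_features(small_labelled):
    """(feature matrix, labels) for the small set, extracted once."""
    seqs, labels = small_labelled
    return L.feature_frame(seqs), np.asarray(labels)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
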