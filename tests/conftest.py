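import numpy as np
import pytest

from clinmine import generate_corpus, preset
from clinmine.tagging import TagSet


@pytest.fixture(scope="session")
def tiny_corpus():
    return generate_corpus(preset("tiny"), seed=7)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(preset("small"), seed=11)


@pytest.fixture(scope="session")
def medium_corpus():
    return generate_corpus(preset("medium"), seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def one_label_tagset():
    return TagSet(("Disease",))


def random_crf_instance(rng, max_len=5, max_tags=4):
    """A random (emissions, transitions) pair small enough to enumerate."""
    L = int(rng.integers(1, max_len + 1))
    T = int(rng.integers(2, max_tags + 1))
    E = rng.normal(size=(L, T))
    A = rng.normal(size=(T + 2, T + 2))
    return E, A


def brute_force_paths(E, A):
    """Enumerate every tag path with its score; independent of the CRF
    module's recursions."""
    import itertools

    L, T = E.shape
    start, stop = T, T + 1
    out = {}
    for path in itertools.product(range(T), repeat=L):
        s = A[start, path[0]] + A[path[-1], stop]
        s += sum(E[i, t] for i, t in enumerate(path))
        s += sum(A[a, b] for a, b in zip(path, path[1:]))
        out[path] = s
    return out
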