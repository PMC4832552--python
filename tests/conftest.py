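import random

import pytest
from hypothesis import HealthCheck, settings

from bftrie import BFT, PanGenomeSim, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_sim():
    """Mini-preset simulated pan-genome with its exact truth table."""
    return simulate(PanGenomeSim.preset("mini", seed=11))


@pytest.fixture(scope="session")
def mini_trie(mini_sim):
    """Graph-mode trie holding the mini pan-genome's truth k-mers."""
    p = mini_sim.params
    t = BFT(k=p.k, l=p.l, c=20, graph_mode=True, seed=7)
    for kmer in sorted(mini_sim.truth):
        for color in sorted(mini_sim.truth[kmer]):
            t.insert(kmer, color)
    return t


@pytest.fixture()
def rng():
    return random.Random(0xBF7)


def random_kmer(rng, k):
    return "".join(rng.choice("acgt") for _ in range(k))
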