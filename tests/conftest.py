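import numpy as np
import pytest

from nmlsa.network import CoexpressionGraph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def graph_from_edges(n_features: int, edges) -> CoexpressionGraph:
    """A CoexpressionGraph from a bare edge list (r/lfdr filled with
    placeholders), for tests that exercise graph algorithms directly."""
    edges = np.array(sorted((min(i, j), max(i, j)) for i, j in edges),
                     dtype=int).reshape(-1, 2)
    m = len(edges)
    return CoexpressionGraph(n_features=n_features, edges=edges,
                             edge_r=np.ones(m), edge_lfdr=np.zeros(m),
                             threshold_used=0.2)


def clique_edges(members):
    members = list(members)
    return [(members[a], members[b])
            for a in range(len(members)) for b in range(a + 1, len(members))]


@pytest.fixture
def planted_module(rng):
    """A single 100-gene module driven by one factor at SNR 2, plus 1000
    pure-noise genes; returns (values, n_module_genes)."""
    n, q = 100, 100
    factor = rng.standard_normal(n)
    factor = (factor - factor.mean()) / factor.std()
    loadings = rng.choice([-1.0, 1.0], size=q)
    signal = np.outer(loadings, factor)
    noise_sd = signal.std(axis=1, keepdims=True) / 2.0
    module = signal + rng.standard_normal((q, n)) * noise_sd
    noise = rng.standard_normal((1000, n))
    return np.vstack([module, noise]), q
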