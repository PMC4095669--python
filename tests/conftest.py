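from fractions import Fraction
from math import comb

import networkx as nx
import pytest

from coexnet.network import CoexpressionNetwork


def exact_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Independent oracle: P(X >= k) by exact integer-arithmetic summation
    of the hypergeometric PMF."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(num, comb(N, n))


@pytest.fixture
def exact_tail():
    return exact_upper_tail


@pytest.fixture
def network_factory():
    """Build a CoexpressionNetwork directly from explicit nodes/edges."""

    def make(edges=(), nodes=(), threshold=0.3, rho=0.5, **kwargs):
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        for a, b in edges:
            graph.add_edge(a, b, rho=rho)
        return CoexpressionNetwork(graph, threshold=threshold, **kwargs)

    return make
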