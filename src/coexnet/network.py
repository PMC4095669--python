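"""Thresholded coexpression networks from expression matrices.

Every pair of genes is scored with a correlation coefficient (Spearman rank
correlation by default, Pearson optionally) and an undirected edge is kept
when the coefficient passes the threshold: rho >= t under the ``signed``
edge rule, |rho| >= t under ``absolute``.  The network keeps the full gene
universe - isolated genes included - because the universe size N is the
population of the downstream hypergeometric test.

The all-pairs computation rank-transforms the matrix once and takes a
single correlation-matrix product; at desk scale (up to ~20k genes) this is
the simple correct choice, and never more than one full gene x gene
coefficient matrix is materialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, DataFormatError, DegenerateInputError

__all__ = [
    "CoexpressionNetwork",
    "spearman_rho",
    "build_network",
    "write_edge_list",
    "read_edge_list",
]

logger = logging.getLogger("coexnet")

METHODS = ("spearman", "pearson")
EDGE_RULES = ("signed", "absolute")


@dataclass
class CoexpressionNetwork:
    """Gene universe plus thresholded correlation edges.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are the
    full gene universe and whose edges carry the surviving coefficient under
    the ``rho`` attribute.
    """

    graph: nx.Graph
    threshold: float = 0.3
    method: str = "spearman"
    edge_rule: str = "signed"

    @property
    def universe(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as canonically ordered (a, b) pairs with a < b."""
        return {tuple(sorted(e)) for e in self.graph.edges}


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive the mean of the ranks they span.  Requires two equal-length
    vectors of at least 3 observations, each with at least 2 distinct
    values (a constant vector has no defined rank correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ConfigurationError("spearman_rho requires two equal-length 1-d vectors")
    if x.size < 3:
        raise ConfigurationError(f"need at least 3 observations, got {x.size}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError(
            "correlation is undefined for a constant vector; see filter_uninformative"
        )
    r = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def _correlation_matrix(values: np.ndarray, method: str) -> np.ndarray:
    data = rankdata(values, axis=1) if method == "spearman" else values
    corr = np.corrcoef(data)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def build_network(
    matrix: pd.DataFrame,
    threshold: float = 0.3,
    method: str = "spearman",
    edge_rule: str = "signed",
) -> CoexpressionNetwork:
    """Build the thresholded coexpression network of an expression matrix.

    The universe is every gene of the matrix (isolated nodes included); an
    edge joins genes g != h iff rho(g, h) >= threshold (``signed``) or
    |rho(g, h)| >= threshold (``absolute``).  The matrix must already be
    free of constant rows (:func:`coexnet.expression.filter_uninformative`).
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
    if method not in METHODS:
        raise ConfigurationError(f"method must be one of {METHODS}, got {method!r}")
    if edge_rule not in EDGE_RULES:
        raise ConfigurationError(f"edge_rule must be one of {EDGE_RULES}, got {edge_rule!r}")

    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ConfigurationError("need at least 3 samples to correlate")
    if (values.max(axis=1) == values.min(axis=1)).any():
        raise DegenerateInputError(
            "matrix contains constant genes; apply filter_uninformative first"
        )

    corr = _correlation_matrix(values, method)
    coef = np.abs(corr) if edge_rule == "absolute" else corr
    iu, ju = np.triu_indices(len(matrix), k=1)
    keep = coef[iu, ju] >= threshold

    genes = matrix.index.astype(str)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j], {"rho": float(corr[i, j])})
        for i, j in zip(iu[keep], ju[keep])
    )
    logger.info(
        "build_network: %d genes, %d edges (threshold=%g, method=%s, edge_rule=%s)",
        graph.number_of_nodes(), graph.number_of_edges(), threshold, method, edge_rule,
    )
    return CoexpressionNetwork(graph, threshold=threshold, method=method, edge_rule=edge_rule)


def write_edge_list(network: CoexpressionNetwork, edges_path, nodes_path) -> None:
    """Write the edge list and the node (universe) file.

    Edges are written as ``gene_a<TAB>gene_b<TAB>rho`` with gene_a < gene_b
    lexicographically, sorted by pair; a leading comment line records the
    build parameters.  The node file holds one gene id per line so that
    isolated genes survive the round trip.
    """
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# threshold={network.threshold!r} method={network.method}"
            f" edge_rule={network.edge_rule}\n"
        )
        fh.write("gene_a\tgene_b\trho\n")
        rows = sorted(
            (min(a, b), max(a, b), data["rho"])
            for a, b, data in network.graph.edges(data=True)
        )
        for a, b, rho in rows:
            fh.write(f"{a}\t{b}\t{rho!r}\n")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for gene in sorted(network.graph.nodes):
            fh.write(f"{gene}\n")


def read_edge_list(edges_path, nodes_path) -> CoexpressionNetwork:
    """Inverse of :func:`write_edge_list`; read(write(x)) == x."""
    with open(nodes_path, encoding="utf-8") as fh:
        universe = [line.strip() for line in fh if line.strip()]
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    known = set(universe)

    threshold, method, edge_rule = 0.3, "spearman", "signed"
    with open(edges_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, val = token.partition("=")
                    if key == "threshold":
                        threshold = float(val)
                    elif key == "method":
                        method = val
                    elif key == "edge_rule":
                        edge_rule = val
                continue
            parts = line.split("\t")
            if parts[:3] == ["gene_a", "gene_b", "rho"]:
                continue
            if len(parts) != 3:
                raise DataFormatError(f"{edges_path}: line {lineno}: expected 3 fields")
            a, b, rho = parts
            if a not in known or b not in known:
                raise DataFormatError(
                    f"{edges_path}: line {lineno}: edge ({a}, {b}) references a gene"
                    " outside the node universe"
                )
            graph.add_edge(a, b, rho=float(rho))
    return CoexpressionNetwork(graph, threshold=threshold, method=method, edge_rule=edge_rule)
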