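"""Scoring every gene's connectivity to a grouped seed set.

The seed set (in the motivating study, the nuclear-encoded subunits of the
mitochondrial respiratory complexes) is treated as a single integrated
target.  A gene with total network degree n, of which k neighbours fall in
the seed set, is scored with the upper-tail hypergeometric probability of
drawing at least k seed genes in n draws from the network universe.  Genes
below a fixed cutoff (1e-8 by default) are called coexpression "friends"
of the seed set; seed genes passing the same test against the *other* seed
genes constitute the seed's self-connectivity.

Self-exclusion convention: the tested gene is removed from its own
population (N_eff = N - 1) and, when it is itself a seed gene, from the
seed set (K_eff = K - 1), since a gene cannot be its own network neighbour.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, DataFormatError, EmptyResultError
from .network import CoexpressionNetwork
from .stats import benjamini_hochberg, log_hypergeometric_upper_tail

__all__ = [
    "SeedSet",
    "SeedFriendResult",
    "FriendSet",
    "read_seed_list",
    "seed_neighbor_counts",
    "test_all_genes",
    "call_friends",
    "seed_self_connectivity",
    "write_friend_table",
    "read_friend_table",
]

logger = logging.getLogger("coexnet")

_TINY = 5e-324
LOG10E = math.log10(math.e)


@dataclass(frozen=True)
class SeedSet:
    """A named, non-empty set of seed gene symbols."""

    symbols: frozenset
    name: str = "seed"

    def __post_init__(self):
        if not self.symbols:
            raise ConfigurationError("seed set must be non-empty")
        object.__setattr__(self, "symbols", frozenset(self.symbols))

    def effective(self, universe) -> frozenset:
        """Seed symbols present in the network universe."""
        return self.symbols & frozenset(universe)


@dataclass(frozen=True)
class SeedFriendResult:
    """Per-gene seed-connectivity record.

    ``k``: neighbours inside the (effective) seed set; ``n``: total degree;
    ``K_eff``/``N_eff``: seed and universe sizes used for this gene's test;
    ``p_value``: upper-tail hypergeometric probability (floored at the
    smallest positive float); ``log10_p``: the same quantity in log10,
    exact below the underflow floor.
    """

    gene: str
    k: int
    n: int
    K_eff: int
    N_eff: int
    p_value: float
    log10_p: float


@dataclass(frozen=True)
class FriendSet:
    """Genes called coexpression friends of a seed set in one condition."""

    condition_label: str
    alpha: float
    members: frozenset
    seed_name: str = "seed"


def read_seed_list(path) -> SeedSet:
    """Read a seed list: one gene symbol per line, '#' comments allowed."""
    symbols = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    if not symbols:
        raise EmptyResultError(f"{path}: seed list is empty")
    from pathlib import Path

    return SeedSet(frozenset(symbols), name=Path(path).stem)


def seed_neighbor_counts(
    network: CoexpressionNetwork, seed: SeedSet
) -> list[tuple[str, int, int]]:
    """(gene, k, n) for every universe gene, isolated genes included.

    ``n`` is the gene's degree and ``k`` its number of neighbours inside
    seed ∩ universe; a gene is never its own neighbour.
    """
    universe = set(network.graph.nodes)
    effective = seed.effective(universe)
    if not effective:
        missing = sorted(seed.symbols)
        raise EmptyResultError(
            f"no seed genes present in the network universe; seed symbols: {missing}"
        )
    k_counts = dict.fromkeys(universe, 0)
    for s in effective:
        for neighbor in network.graph.adj[s]:
            k_counts[neighbor] += 1
    degree = network.graph.degree
    return [(g, k_counts[g], degree(g)) for g in sorted(universe)]


def test_all_genes(network: CoexpressionNetwork, seed: SeedSet) -> list[SeedFriendResult]:
    """Hypergeometric seed-connectivity test for every gene in the universe.

    Non-seed genes are tested with K_eff = |seed ∩ universe| and seed genes
    with K_eff = |seed ∩ universe| - 1; both use N_eff = N - 1.  Results are
    sorted by ascending p-value, ties broken by gene id.
    """
    counts = seed_neighbor_counts(network, seed)
    universe = set(network.graph.nodes)
    effective = seed.effective(universe)
    K, N = len(effective), len(universe)
    results = []
    for gene, k, n in counts:
        K_eff = K - 1 if gene in effective else K
        logp = log_hypergeometric_upper_tail(k, n, K_eff, N - 1)
        p = math.exp(logp)
        results.append(
            SeedFriendResult(
                gene=gene, k=k, n=n, K_eff=K_eff, N_eff=N - 1,
                p_value=p if p > 0.0 else _TINY,
                log10_p=logp * LOG10E,
            )
        )
    results.sort(key=lambda r: (r.log10_p, r.gene))
    logger.info("test_all_genes: tested %d genes against %d seed genes", N, K)
    return results


def call_friends(
    results: list[SeedFriendResult],
    seed: SeedSet | None = None,
    alpha: float = 1e-8,
    exclude_seed: bool = True,
    condition_label: str = "condition",
) -> FriendSet:
    """Genes with p_value strictly below ``alpha``.

    Seed genes are excluded by default: friend lists report cellular genes,
    while seed self-connectivity is reported separately by
    :func:`seed_self_connectivity`.
    """
    if not results:
        raise EmptyResultError("no test results to call friends from")
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    excluded = seed.symbols if (exclude_seed and seed is not None) else frozenset()
    members = frozenset(
        r.gene for r in results if r.p_value < alpha and r.gene not in excluded
    )
    return FriendSet(
        condition_label=condition_label,
        alpha=alpha,
        members=members,
        seed_name=seed.name if seed is not None else "seed",
    )


def seed_self_connectivity(
    results: list[SeedFriendResult], seed: SeedSet, alpha: float = 1e-8
) -> frozenset:
    """Seed genes whose own connectivity to the other seed genes reaches
    significance (p < alpha) - the seed set's self-connection analysis."""
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    return frozenset(r.gene for r in results if r.gene in seed.symbols and r.p_value < alpha)


_FRIEND_COLUMNS = ["gene", "k", "n", "K_eff", "N_eff", "p_value", "log10_p", "q_value"]


def write_friend_table(results: list[SeedFriendResult], path) -> None:
    """Write the per-gene result table as TSV, sorted by ascending p.

    p-values are written in scientific notation with 9 significant digits;
    the log10_p column preserves magnitudes below the float underflow
    limit, and q_value is the Benjamini-Hochberg adjusted p-value (reported
    for reference; friend calling uses the raw fixed cutoff).
    """
    q = benjamini_hochberg([r.p_value for r in results])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_FRIEND_COLUMNS) + "\n")
        for r, qv in zip(results, q):
            fh.write(
                f"{r.gene}\t{r.k}\t{r.n}\t{r.K_eff}\t{r.N_eff}"
                f"\t{r.p_value:.8e}\t{r.log10_p:.10g}\t{qv:.8e}\n"
            )


def read_friend_table(path) -> list[SeedFriendResult]:
    """Read back a friend table written by :func:`write_friend_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FRIEND_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    return [
        SeedFriendResult(
            gene=str(row.gene), k=int(row.k), n=int(row.n),
            K_eff=int(row.K_eff), N_eff=int(row.N_eff),
            p_value=float(row.p_value), log10_p=float(row.log10_p),
        )
        for row in df.itertuples(index=False)
    ]
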