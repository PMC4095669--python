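"""Differential coexpression: partitioning friend sets between conditions.

The comparison is purely set-based on the called friends: a gene is
"shared" when it passes the friend criterion in both conditions, and
condition-specific when it passes in exactly one.  Genes present in one
condition's universe only cannot be assessed in the other and are flagged
``unassessable`` rather than silently categorised - absence of evidence is
not loss of coexpression.  A per-gene p-value change table is available as
supplementary output since the interesting biology is often a p-value that
collapses from e.g. 1e-54 to 0.2 after treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, DataFormatError
from .friends import FriendSet, SeedFriendResult, SeedSet

__all__ = [
    "FriendComparison",
    "compare_friend_sets",
    "compare_seed_self_connectivity",
    "pvalue_change_table",
    "write_comparison",
    "read_comparison",
]


@dataclass(frozen=True)
class FriendComparison:
    """Disjoint partition of two conditions' friend sets.

    ``in_both``/``only_a``/``only_b`` partition the assessable genes;
    ``unassessable_a`` (resp. ``_b``) holds friends of condition A (resp. B)
    absent from the other condition's universe.
    """

    label_a: str
    label_b: str
    in_both: frozenset
    only_a: frozenset
    only_b: frozenset
    unassessable_a: frozenset = frozenset()
    unassessable_b: frozenset = frozenset()

    def counts(self) -> dict[str, int]:
        return {
            "in_both": len(self.in_both),
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "unassessable_a": len(self.unassessable_a),
            "unassessable_b": len(self.unassessable_b),
        }


def compare_friend_sets(
    a: FriendSet,
    b: FriendSet,
    universe_a=None,
    universe_b=None,
) -> FriendComparison:
    """Partition two friend sets into shared and condition-specific genes.

    With universes supplied, a friend of one condition that is absent from
    the other condition's universe is flagged unassessable instead of being
    counted as condition-specific.
    """
    if a.seed_name != b.seed_name:
        warnings.warn(
            f"friend sets were called against different seeds"
            f" ({a.seed_name!r} vs {b.seed_name!r})",
            stacklevel=2,
        )
    set_a, set_b = set(a.members), set(b.members)
    una = frozenset(set_a - set(universe_b)) if universe_b is not None else frozenset()
    unb = frozenset(set_b - set(universe_a)) if universe_a is not None else frozenset()
    assess_a = set_a - una
    assess_b = set_b - unb
    return FriendComparison(
        label_a=a.condition_label,
        label_b=b.condition_label,
        in_both=frozenset(assess_a & assess_b),
        only_a=frozenset(assess_a - set_b),
        only_b=frozenset(assess_b - set_a),
        unassessable_a=una,
        unassessable_b=unb,
    )


def compare_seed_self_connectivity(a, b, seed: SeedSet, label_a="a", label_b="b") -> FriendComparison:
    """Same partition semantics restricted to seed genes: which seed genes
    stay self-connected across conditions."""
    a, b = frozenset(a), frozenset(b)
    if not a <= seed.symbols or not b <= seed.symbols:
        offenders = sorted((a | b) - seed.symbols)
        raise ConfigurationError(
            f"self-connectivity sets must be subsets of the seed; offenders: {offenders}"
        )
    return FriendComparison(
        label_a=label_a,
        label_b=label_b,
        in_both=a & b,
        only_a=a - b,
        only_b=b - a,
    )


def pvalue_change_table(
    results_a: list[SeedFriendResult],
    results_b: list[SeedFriendResult],
    genes=None,
) -> pd.DataFrame:
    """Per-gene p-values in both conditions, for genes tested in both.

    Sorted by the condition-A p-value so the largest collapses (tiny p in A,
    large p in B) surface first.
    """
    pa = {r.gene: r for r in results_a}
    pb = {r.gene: r for r in results_b}
    shared = set(pa) & set(pb)
    if genes is not None:
        shared &= set(genes)
    rows = [
        {
            "gene": g,
            "p_a": pa[g].p_value,
            "p_b": pb[g].p_value,
            "log10_p_a": pa[g].log10_p,
            "log10_p_b": pb[g].log10_p,
        }
        for g in sorted(shared)
    ]
    df = pd.DataFrame(rows, columns=["gene", "p_a", "p_b", "log10_p_a", "log10_p_b"])
    return df.sort_values(["log10_p_a", "gene"], kind="mergesort").reset_index(drop=True)


_CATEGORIES = ("both", "only_a", "only_b", "unassessable_a", "unassessable_b")


def write_comparison(cmp: FriendComparison, path) -> None:
    """TSV of (gene, category) plus a summary comment line of the counts."""
    c = cmp.counts()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# label_a={cmp.label_a} label_b={cmp.label_b}"
            f" in_both={c['in_both']} only_a={c['only_a']} only_b={c['only_b']}"
            f" unassessable_a={c['unassessable_a']} unassessable_b={c['unassessable_b']}\n"
        )
        fh.write("gene\tcategory\n")
        for category, members in (
            ("both", cmp.in_both),
            ("only_a", cmp.only_a),
            ("only_b", cmp.only_b),
            ("unassessable_a", cmp.unassessable_a),
            ("unassessable_b", cmp.unassessable_b),
        ):
            for gene in sorted(members):
                fh.write(f"{gene}\t{category}\n")


def read_comparison(path) -> FriendComparison:
    """Inverse of :func:`write_comparison`."""
    label_a, label_b = "a", "b"
    buckets: dict[str, set] = {c: set() for c in _CATEGORIES}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, val = token.partition("=")
                    if key == "label_a":
                        label_a = val
                    elif key == "label_b":
                        label_b = val
                continue
            parts = line.split("\t")
            if parts == ["gene", "category"]:
                continue
            if len(parts) != 2 or parts[1] not in _CATEGORIES:
                raise DataFormatError(f"{path}: line {lineno}: expected 'gene<TAB>category'")
            buckets[parts[1]].add(parts[0])
    return FriendComparison(
        label_a=label_a,
        label_b=label_b,
        in_both=frozenset(buckets["both"]),
        only_a=frozenset(buckets["only_a"]),
        only_b=frozenset(buckets["only_b"]),
        unassessable_a=frozenset(buckets["unassessable_a"]),
        unassessable_b=frozenset(buckets["unassessable_b"]),
    )
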