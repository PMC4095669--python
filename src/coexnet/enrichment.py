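"""Over-representation analysis of a gene list against GMT collections.

Each annotation term is tested with a one-sided exact test on the 2x2
overlap table, by default with the EASE modification (one observed success
removed, the conservative DAVID convention).  Term membership is restricted
to the supplied population before counting, so enrichment is conditional on
the genes actually assessed, and terms overlapping the query in fewer than
``min_count`` genes are dropped.  Reported rows carry Benjamini-Hochberg
adjusted p-values computed over the rows that survive filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DataFormatError
from .stats import benjamini_hochberg, fisher_onesided

__all__ = [
    "AnnotationCollection",
    "EnrichmentRow",
    "read_gmt",
    "write_gmt",
    "enrich",
    "write_enrichment",
    "read_enrichment",
]


@dataclass(frozen=True)
class AnnotationCollection:
    """Mapping term_id -> (term_name, gene set), with a source label."""

    terms: dict
    source_label: str = "annotations"

    def __post_init__(self):
        for term_id, (name, genes) in self.terms.items():
            if not genes:
                raise ConfigurationError(f"term {term_id!r} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: overlap count, population hits, exact p, BH q."""

    term_id: str
    term_name: str
    count: int
    pop_hits: int
    list_size: int
    pop_size: int
    p_value: float
    adjusted_p: float
    genes: tuple


def read_gmt(path) -> AnnotationCollection:
    """Read a standard GMT file: ``term_id<TAB>description<TAB>gene...``.

    Duplicate genes within a line are deduplicated; blank lines skipped;
    a line with fewer than 3 fields is a format error.
    """
    terms: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno}: expected term_id, description and"
                    " at least one gene"
                )
            term_id, name, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
            if term_id in terms:
                raise DataFormatError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            if not genes:
                raise DataFormatError(f"{path}: line {lineno}: term {term_id!r} has no genes")
            terms[term_id] = (name, genes)
    from pathlib import Path

    return AnnotationCollection(terms=terms, source_label=Path(path).stem)


def write_gmt(collection: AnnotationCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(collection.terms):
            name, genes = collection.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def enrich(
    query,
    population,
    annotations: AnnotationCollection,
    ease: bool = True,
    min_count: int = 2,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` within ``population`` for every term.

    pop_hits counts term members inside the population; terms whose overlap
    with the query is below ``min_count`` are dropped; rows are sorted by
    ascending p-value (ties by term id) and BH-adjusted over the reported
    rows.
    """
    query = frozenset(query)
    population = frozenset(population)
    if not population:
        raise ConfigurationError("population must be non-empty")
    offenders = sorted(query - population)
    if offenders:
        raise ConfigurationError(
            f"query genes outside the population: {offenders[:10]}"
        )
    rows = []
    for term_id in sorted(annotations.terms):
        name, genes = annotations.terms[term_id]
        hits = genes & population
        overlap = query & hits
        if len(overlap) < min_count:
            continue
        p = fisher_onesided(len(overlap), len(query), len(hits), len(population), ease=ease)
        rows.append(
            EnrichmentRow(
                term_id=term_id, term_name=name,
                count=len(overlap), pop_hits=len(hits),
                list_size=len(query), pop_size=len(population),
                p_value=p, adjusted_p=p, genes=tuple(sorted(overlap)),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    adjusted = benjamini_hochberg([r.p_value for r in rows])
    return [
        EnrichmentRow(**{**r.__dict__, "adjusted_p": float(q)})
        for r, q in zip(rows, adjusted)
    ]


_ENRICH_COLUMNS = [
    "term_id", "term_name", "count", "pop_hits", "list_size", "pop_size",
    "p_value", "adjusted_p", "genes",
]


def write_enrichment(rows: list[EnrichmentRow], path) -> None:
    """TSV report mirroring the Term / Count / Pop / P-value layout, with the
    overlapping genes comma-joined in the last column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ENRICH_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.count}\t{r.pop_hits}"
                f"\t{r.list_size}\t{r.pop_size}\t{r.p_value:.8e}"
                f"\t{r.adjusted_p:.8e}\t{','.join(r.genes)}\n"
            )


def read_enrichment(path) -> list[EnrichmentRow]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ENRICH_COLUMNS:
            raise DataFormatError(f"{path}: unexpected header {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_ENRICH_COLUMNS):
                raise DataFormatError(f"{path}: malformed row {parts!r}")
            rows.append(
                EnrichmentRow(
                    term_id=parts[0], term_name=parts[1],
                    count=int(parts[2]), pop_hits=int(parts[3]),
                    list_size=int(parts[4]), pop_size=int(parts[5]),
                    p_value=float(parts[6]), adjusted_p=float(parts[7]),
                    genes=tuple(g for g in parts[8].split(",") if g),
                )
            )
    return rows
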