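"""Table-driven yeast -> human ortholog mapping with multi-source consensus.

Orthology calls come from several curated resources that occasionally
disagree; rather than privileging one, each resource is loaded as an
:class:`OrthologTable` and a consensus policy combines them per gene:

* ``union`` (default) — every symbol any source reports; maximizes recall
  of the downstream human network.
* ``majority`` — symbols supported by more than half of the sources that
  mention the gene at all.

One-to-many mappings (a yeast gene with several human co-orthologs) are
first-class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "OrthologTable",
    "MappedHit",
    "read_ortholog_tables",
    "write_ortholog_tables",
    "consensus_map",
    "ortholog_fraction",
    "humanize",
]

POLICIES = ("union", "majority")


@dataclass
class OrthologTable:
    """One curated resource's yeast-ID -> human-symbol pairs."""

    source: str
    pairs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [g for g, syms in self.pairs.items() if not syms]
        if empty:
            raise ValueError(f"empty human-symbol sets for {empty[:5]}")


@dataclass
class MappedHit:
    """Consensus mapping of one yeast gene across the loaded sources."""

    gene_id: str
    human_symbols: set[str]
    supporting_sources: set[str]

    def __post_init__(self) -> None:
        if bool(self.human_symbols) != bool(self.supporting_sources):
            raise ValueError("symbols and supporting sources must be empty together")

    @property
    def mapped(self) -> bool:
        return bool(self.human_symbols)


def read_ortholog_tables(path: str | Path) -> list[OrthologTable]:
    """Read an ortholog TSV (source, yeast_id, human_symbol; one pair per line).

    Returns one table per distinct source label, in order of first
    appearance.
    """
    tables: dict[str, OrthologTable] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "yeast_id", "human_symbol"]:
            raise ValueError(f"{path}: expected header source\tyeast_id\thuman_symbol")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            source, yeast, human = parts
            table = tables.setdefault(source, OrthologTable(source))
            table.pairs.setdefault(yeast, set()).add(human)
    return list(tables.values())


def write_ortholog_tables(tables: Iterable[OrthologTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tyeast_id\thuman_symbol\n")
        for table in tables:
            for yeast in sorted(table.pairs):
                for human in sorted(table.pairs[yeast]):
                    fh.write(f"{table.source}\t{yeast}\t{human}\n")


def _check(tables: Sequence[OrthologTable], policy: str) -> None:
    if not tables:
        raise ValueError("at least one ortholog table must be loaded")
    labels = [t.source for t in tables]
    if len(labels) != len(set(labels)):
        raise ValueError("source labels must be unique within a collection")
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")


def consensus_map(
    gene_id: str, tables: Sequence[OrthologTable], policy: str = "union"
) -> MappedHit:
    """Combine the sources' calls for one gene under the chosen policy.

    The majority denominator is the number of sources that mention the gene
    at all, so a gene absent from two of four resources still gets its
    2-of-2 consensus.  An unmapped gene yields an empty mapping, never an
    error.
    """
    _check(tables, policy)
    mentioning = [t for t in tables if gene_id in t.pairs]
    if not mentioning:
        return MappedHit(gene_id, set(), set())
    if policy == "union":
        symbols = set().union(*(t.pairs[gene_id] for t in mentioning))
    else:
        counts: dict[str, int] = {}
        for t in mentioning:
            for sym in t.pairs[gene_id]:
                counts[sym] = counts.get(sym, 0) + 1
        symbols = {s for s, n in counts.items() if n > len(mentioning) / 2}
    if not symbols:
        return MappedHit(gene_id, set(), set())
    sources = {t.source for t in mentioning if t.pairs[gene_id] & symbols}
    return MappedHit(gene_id, symbols, sources)


def ortholog_fraction(
    modifiers: Iterable[str],
    tables: Sequence[OrthologTable],
    policy: str = "union",
) -> tuple[int, float]:
    """(count mapped, percent mapped to one decimal) over a modifier set."""
    modifiers = set(modifiers)
    if not modifiers:
        raise ValueError("modifier set is empty")
    count = sum(1 for g in modifiers if consensus_map(g, tables, policy).mapped)
    return count, round(100.0 * count / len(modifiers), 1)


def humanize(
    genes: Iterable[str], tables: Sequence[OrthologTable], policy: str = "union"
) -> set[str]:
    """Union of human symbols over a yeast gene set; one-to-many kept."""
    out: set[str] = set()
    for g in set(genes):
        out |= consensus_map(g, tables, policy).human_symbols
    return out
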