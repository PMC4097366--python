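"""Data model and readers/writers for colony-fitness screen artifacts.

The screen produces colony-size grids scanned from agar plates pinned in
1536 format (32 x 48), where every deletion strain occupies a quadruplicate
2 x 2 block.  This module defines the in-memory containers — :class:`ColonyGrid`,
:class:`StrainMap`, :class:`HitTable` — and the plain-text table dialects used
to move them on and off disk.

Coordinates are 1-based (row, col) in every file, matching plate-scanner
conventions; in memory they are 0-based numpy indices.  The two readers and
two writers in this module are the only places the offset appears.

Missing or dead colonies are encoded as size 0 and are excluded from
statistics downstream rather than imputed.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "PLATE_FORMATS",
    "ColonyGrid",
    "StrainMap",
    "HitRecord",
    "HitTable",
    "ColonyTableParseError",
    "read_colony_table",
    "write_colony_table",
    "read_strain_map",
    "write_strain_map",
    "read_hit_table",
    "write_hit_table",
    "read_table1_fixture",
]

#: Supported plate formats: total positions -> (n_rows, n_cols).
PLATE_FORMATS: dict[int, tuple[int, int]] = {1536: (32, 48), 384: (16, 24)}

CONDITIONS = ("inducing", "non_inducing")
SCREENS = ("wt", "mut")
CATEGORIES = ("SL", "SS")

_TABLE1_RESOURCE = "table1_hits.tsv"
_TABLE1_SHA256 = "f670aeb074db17258267d3b971125add59195e81521ae26370d3dbba5e9a4868"


class ColonyTableParseError(ValueError):
    """A colony-table or strain-map file violated its dialect."""


@dataclass
class ColonyGrid:
    """One plate x condition x day matrix of colony sizes.

    Sizes are non-negative reals in arbitrary area units; 0 means no growth
    or a missing colony.  ``sizes[r, c]`` is 0-based.
    """

    plate_id: str
    condition: str
    day: int
    sizes: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.day < 0:
            raise ValueError("day must be >= 0")
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 2:
            raise ValueError("sizes must be a 2-D matrix")
        n = self.sizes.size
        if n not in PLATE_FORMATS:
            raise ValueError(
                f"grid has {n} positions; expected one of {sorted(PLATE_FORMATS)}"
            )
        if self.sizes.shape != PLATE_FORMATS[n]:
            raise ValueError(
                f"{n}-format grid must be {PLATE_FORMATS[n]}, got {self.sizes.shape}"
            )
        if (self.sizes < 0).any():
            raise ValueError("colony sizes must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.sizes.shape[1]

    def key(self) -> tuple[str, str, int]:
        return (self.plate_id, self.condition, self.day)


@dataclass
class StrainMap:
    """Plate position -> deletion-gene systematic ID, for one query strain.

    ``entries`` maps 1-based ``(plate_id, row, col)`` to a gene ID.  Every
    gene occupies exactly four positions (the quadruplicate block pinned
    from the 384-format source plate).
    """

    entries: dict[tuple[str, int, int], str]
    query: str = "control"

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for gene in self.entries.values():
            counts[gene] = counts.get(gene, 0) + 1
        bad = {g: n for g, n in counts.items() if n != 4}
        if bad:
            some = ", ".join(f"{g} ({n})" for g, n in list(bad.items())[:5])
            raise ValueError(f"every gene needs exactly 4 positions; violated by {some}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries.values())

    def positions_of(self, gene_id: str) -> list[tuple[str, int, int]]:
        """The (plate_id, row, col) quadruplicate of one gene, sorted."""
        return sorted(k for k, g in self.entries.items() if g == gene_id)

    def by_gene(self) -> dict[str, list[tuple[str, int, int]]]:
        out: dict[str, list[tuple[str, int, int]]] = {}
        for pos in sorted(self.entries):
            out.setdefault(self.entries[pos], []).append(pos)
        return out


@dataclass(frozen=True)
class HitRecord:
    """One significant gene from one screen, with its statistic if known."""

    gene_id: str
    screen: str
    category: str
    rank: int
    statistic: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.screen not in SCREENS:
            raise ValueError(f"screen must be one of {SCREENS}")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if self.rank < 1:
            raise ValueError("rank is 1-based")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class HitTable:
    """The four ordered hit lists keyed by (screen, category).

    Keys are ``("wt", "SL")``, ``("wt", "SS")``, ``("mut", "SL")``,
    ``("mut", "SS")``; each list is sorted by rank and free of duplicate
    genes.
    """

    lists: dict[tuple[str, str], list[HitRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in list(self.lists):
            if key[0] not in SCREENS or key[1] not in CATEGORIES:
                raise ValueError(f"unknown hit-list key {key}")
            records = sorted(self.lists[key], key=lambda r: r.rank)
            genes = [r.gene_id for r in records]
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate gene within list {key}")
            self.lists[key] = records

    def genes(self, screen: str, category: str) -> list[str]:
        return [r.gene_id for r in self.lists.get((screen, category), [])]

    def all_genes(self) -> set[str]:
        return {r.gene_id for recs in self.lists.values() for r in recs}

    def __len__(self) -> int:
        return sum(len(v) for v in self.lists.values())


# ---------------------------------------------------------------------------
# colony CSV  (header: plate,condition,day,row,col,size)
# ---------------------------------------------------------------------------

_COLONY_HEADER = ["plate", "condition", "day", "row", "col", "size"]


def _infer_shape(max_row: int, max_col: int) -> tuple[int, int]:
    for total in sorted(PLATE_FORMATS):
        nr, nc = PLATE_FORMATS[total]
        if max_row <= nr and max_col <= nc:
            return nr, nc
    raise ColonyTableParseError(
        f"coordinates ({max_row}, {max_col}) exceed the largest supported format"
    )


def read_colony_table(path: str | Path) -> list[ColonyGrid]:
    """Read a colony CSV into one :class:`ColonyGrid` per (plate, condition, day).

    Positions absent from the file are size 0.  The grid format (384 or
    1536) is the smallest standard format containing every listed
    coordinate of that plate.  Raises :class:`ColonyTableParseError` naming
    the offending line for malformed rows, out-of-range coordinates or
    negative sizes.
    """
    cells: dict[tuple[str, str, int], list[tuple[int, int, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _COLONY_HEADER:
            raise ColonyTableParseError(
                f"{path}: expected header {','.join(_COLONY_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 6:
                raise ColonyTableParseError(f"{path}:{lineno}: expected 6 fields")
            plate, condition, day_s, row_s, col_s, size_s = (f.strip() for f in row)
            if condition not in CONDITIONS:
                raise ColonyTableParseError(
                    f"{path}:{lineno}: unknown condition {condition!r}"
                )
            try:
                day = int(day_s)
                r = int(row_s)
                c = int(col_s)
                size = float(size_s)
            except ValueError as exc:
                raise ColonyTableParseError(f"{path}:{lineno}: {exc}") from None
            if day < 0:
                raise ColonyTableParseError(f"{path}:{lineno}: negative day")
            if r < 1 or c < 1:
                raise ColonyTableParseError(
                    f"{path}:{lineno}: coordinates are 1-based, got ({r}, {c})"
                )
            max_nr, max_nc = PLATE_FORMATS[max(PLATE_FORMATS)]
            if r > max_nr or c > max_nc:
                raise ColonyTableParseError(
                    f"{path}:{lineno}: coordinate ({r}, {c}) out of range"
                )
            if size < 0:
                raise ColonyTableParseError(f"{path}:{lineno}: negative size {size}")
            cells.setdefault((plate, condition, day), []).append((r, c, size))

    grids = []
    for (plate, condition, day), entries in sorted(cells.items()):
        nr, nc = _infer_shape(
            max(r for r, _, _ in entries), max(c for _, c, _ in entries)
        )
        sizes = np.zeros((nr, nc))
        for r, c, size in entries:
            sizes[r - 1, c - 1] = size
        grids.append(ColonyGrid(plate, condition, day, sizes))
    return grids


def write_colony_table(grids: Iterable[ColonyGrid], path: str | Path) -> None:
    """Write grids to colony CSV, every position listed, deterministic order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLONY_HEADER)
        for grid in sorted(grids, key=ColonyGrid.key):
            for r in range(grid.n_rows):
                for c in range(grid.n_cols):
                    writer.writerow(
                        [grid.plate_id, grid.condition, grid.day,
                         r + 1, c + 1, repr(float(grid.sizes[r, c]))]
                    )


# ---------------------------------------------------------------------------
# strain-map TSV  (plate, row, col, gene_id)
# ---------------------------------------------------------------------------

def read_strain_map(path: str | Path, query: str = "control") -> StrainMap:
    entries: dict[tuple[str, int, int], str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["plate", "row", "col", "gene_id"]:
            raise ColonyTableParseError(f"{path}: expected header plate\trow\tcol\tgene_id")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ColonyTableParseError(f"{path}:{lineno}: expected 4 fields")
            plate, row_s, col_s, gene = parts
            try:
                pos = (plate, int(row_s), int(col_s))
            except ValueError as exc:
                raise ColonyTableParseError(f"{path}:{lineno}: {exc}") from None
            if pos in entries:
                raise ColonyTableParseError(f"{path}:{lineno}: duplicate position {pos}")
            entries[pos] = gene
    return StrainMap(entries, query=query)


def write_strain_map(strain_map: StrainMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("plate\trow\tcol\tgene_id\n")
        for (plate, r, c), gene in sorted(strain_map.entries.items()):
            fh.write(f"{plate}\t{r}\t{c}\t{gene}\n")


# ---------------------------------------------------------------------------
# hit-table TSV  (screen, category, rank, gene_id, statistic, p_value)
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> HitTable:
    lists: dict[tuple[str, str], list[HitRecord]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["screen", "category", "rank", "gene_id", "statistic", "p_value"]:
            raise ColonyTableParseError(f"{path}: bad hit-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ColonyTableParseError(f"{path}:{lineno}: expected 6 fields")
            screen, category, rank_s, gene, stat_s, p_s = parts
            record = HitRecord(
                gene_id=gene,
                screen=screen,
                category=category,
                rank=int(rank_s),
                statistic=float(stat_s) if stat_s else None,
                p_value=float(p_s) if p_s else None,
            )
            lists.setdefault((screen, category), []).append(record)
    return HitTable(lists)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    def fmt(x: float | None) -> str:
        return "" if x is None else repr(x)

    with open(path, "w") as fh:
        fh.write("screen\tcategory\trank\tgene_id\tstatistic\tp_value\n")
        for screen in SCREENS:
            for category in CATEGORIES:
                for rec in table.lists.get((screen, category), []):
                    fh.write(
                        f"{rec.screen}\t{rec.category}\t{rec.rank}\t{rec.gene_id}"
                        f"\t{fmt(rec.statistic)}\t{fmt(rec.p_value)}\n"
                    )


# ---------------------------------------------------------------------------
# published hit-list fixture
# ---------------------------------------------------------------------------

def read_table1_fixture() -> HitTable:
    """The published four top-hit lists of the UBA1 modifier screen.

    Transcribed once from the printed table (fission-yeast systematic IDs,
    in printed order; statistics and p-values were not printed and are
    absent).  The transcription is checksummed: any edit to the packaged
    file raises rather than silently changing the published lists.
    """
    ref = resources.files("yana.data").joinpath(_TABLE1_RESOURCE)
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise RuntimeError("packaged hit-list fixture is missing") from exc
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            "packaged hit-list fixture does not match its frozen checksum"
        )
    lists: dict[tuple[str, str], list[HitRecord]] = {}
    for line in text.splitlines()[1:]:
        screen, category, rank_s, gene, _, _ = line.split("\t")
        lists.setdefault((screen, category), []).append(
            HitRecord(gene_id=gene, screen=screen, category=category, rank=int(rank_s))
        )
    return HitTable(lists)
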