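"""Gene-age assignments and gene-class membership tables.

An :class:`AgeTable` maps gene identifiers to the 1-based taxon index of
their origin on a :class:`~geneage.timeline.Timeline` (their
phylostratum).  A :class:`GeneClassCatalog` holds named, possibly
overlapping sets of gene ids plus the universe of ids against which
overlap statistics are computed.  :func:`join_ages` joins the two,
producing per-class age vectors and a coverage report mirroring the
"listed vs detected" bookkeeping of phylostratigraphic studies.
"""

from __future__ import annotations

import csv
import difflib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .timeline import Timeline, ma_to_index

__all__ = [
    "AgeTable",
    "GeneClassCatalog",
    "JoinResult",
    "read_age_table",
    "read_class_lists",
    "join_ages",
]


@dataclass(frozen=True)
class AgeTable:
    """Mapping gene_id -> 1-based taxon index on ``timeline``."""

    records: Mapping[str, int]
    timeline: Timeline

    def __post_init__(self) -> None:
        for gene, idx in self.records.items():
            self.timeline.validate_index(idx)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def ages_of(self, genes: Iterable[str]) -> np.ndarray:
        """Taxon indices of the subset of ``genes`` present in the table."""
        return np.array(
            [self.records[g] for g in genes if g in self.records], dtype=np.int64
        )


@dataclass
class GeneClassCatalog:
    """Named, possibly overlapping gene-id sets over a universe.

    ``universe`` defaults to the union of all class members until the
    catalog is joined against an :class:`AgeTable`, at which point the
    detected genes of the age table are the natural universe.
    """

    classes: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.classes = {str(k): frozenset(v) for k, v in self.classes.items()}
        if not self.universe:
            u: set[str] = set()
            for members in self.classes.values():
                u |= members
            self.universe = frozenset(u)

    def __len__(self) -> int:
        return len(self.classes)

    def names(self) -> list[str]:
        return list(self.classes)

    def add_class(self, name: str, genes: Iterable[str]) -> None:
        if name in self.classes:
            raise ValidationError(f"class {name!r} already present in catalog")
        self.classes[name] = frozenset(genes)

    def __getitem__(self, name: str) -> frozenset[str]:
        try:
            return self.classes[name]
        except KeyError:
            raise ValidationError(
                f"unknown class {name!r}; known classes: {sorted(self.classes)}"
            ) from None


def read_age_table(path: str | Path, timeline: Timeline) -> AgeTable:
    """Read a gene-age TSV into an :class:`AgeTable`.

    Two dialects are auto-detected from the header: ``gene_id<TAB>taxon``
    (taxon names resolved against ``timeline``) and
    ``gene_id<TAB>age_ma`` (Ma values mapped to the oldest taxon with
    divergence time <= value, within a small tolerance).  Duplicate gene
    ids and unknown taxa are rejected; for a misspelt taxon the error
    suggests the nearest valid names.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"age table not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in rows_iter(reader)]
    if not rows:
        raise ValidationError(f"{path}: empty file")
    header = [c.strip().lower() for c in rows[0]]
    if len(header) < 2 or header[0] != "gene_id" or header[1] not in ("taxon", "age_ma"):
        raise ValidationError(
            f"{path}: header must be 'gene_id<TAB>taxon' or 'gene_id<TAB>age_ma', "
            f"got {rows[0]!r}"
        )
    by_ma = header[1] == "age_ma"
    records: dict[str, int] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {row!r}")
        gene = row[0].strip()
        if gene in records:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        if by_ma:
            try:
                idx = ma_to_index(timeline, float(row[1]))
            except ValueError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
        else:
            taxon = row[1].strip()
            if taxon not in timeline.taxa:
                near = difflib.get_close_matches(taxon, timeline.taxa, n=3)
                hint = f"; did you mean {near}?" if near else ""
                raise ValidationError(
                    f"{path}:{lineno}: unknown taxon {taxon!r}{hint}"
                )
            idx = timeline.index_of(taxon)
        records[gene] = idx
    if not records:
        raise ValidationError(f"{path}: no gene rows found")
    return AgeTable(records=records, timeline=timeline)


def rows_iter(reader):
    for row in reader:
        if not row or (row[0].lstrip().startswith("#")):
            continue
        yield row


def read_class_lists(paths: Sequence[str | Path] | str | Path) -> GeneClassCatalog:
    """Build a :class:`GeneClassCatalog` from class-membership files.

    Each path is either a plain list (one gene id per line, class named
    from the file stem) or a two-column CSV with header ``gene,class``
    (detected from the header line).  Ids are whitespace-trimmed with case
    preserved; duplicates within a class collapse.  An empty class file
    produces a warning but the empty class is retained.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    classes: dict[str, set[str]] = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"class file not found: {path}")
        with open(path, newline="") as fh:
            first = fh.readline()
            is_csv = [c.strip().lower() for c in first.split(",")[:2]] == ["gene", "class"]
            fh.seek(0)
            if is_csv:
                reader = csv.reader(fh)
                next(reader)  # header
                for lineno, row in enumerate(reader, start=2):
                    if not row or row[0].lstrip().startswith("#"):
                        continue
                    if len(row) < 2:
                        raise ValidationError(
                            f"{path}:{lineno}: expected 'gene,class', got {row!r}"
                        )
                    gene, cls = row[0].strip(), row[1].strip()
                    classes.setdefault(cls, set()).add(gene)
            else:
                name = path.stem
                members = classes.setdefault(name, set())
                for line in fh:
                    line = line.strip()
                    if line and not line.startswith("#"):
                        members.add(line)
                if not members:
                    warnings.warn(f"class file {path} is empty; retaining empty class")
    return GeneClassCatalog(classes={k: frozenset(v) for k, v in classes.items()})


@dataclass(frozen=True)
class JoinResult:
    """Per-class age vectors plus a listed/detected/missing coverage report.

    ``ages`` maps class name -> sorted array of 1-based taxon indices of
    its genes found in the age table; genes absent from the age table are
    excluded from the vectors but counted in ``coverage``.
    """

    ages: dict[str, np.ndarray]
    coverage: pd.DataFrame

    def detected(self, name: str) -> int:
        return int(self.coverage.set_index("class").loc[name, "detected"])


def join_ages(catalog: GeneClassCatalog, age_table: AgeTable) -> JoinResult:
    """Join class membership with gene ages.

    Returns per-class multisets of taxon indices (only genes present in
    the age table) and a coverage report with listed, detected and
    missing counts per class.  Classes with zero detected genes are kept
    in the report but flagged; downstream distribution builders refuse
    empty age vectors.
    """
    ages: dict[str, np.ndarray] = {}
    rows = []
    for name in catalog.names():
        members = catalog[name]
        vec = np.sort(age_table.ages_of(sorted(members)))
        ages[name] = vec
        listed = len(members)
        detected = len(vec)
        rows.append(
            {
                "class": name,
                "listed": listed,
                "detected": detected,
                "missing": listed - detected,
                "flagged_empty": detected == 0,
            }
        )
    coverage = pd.DataFrame(rows, columns=["class", "listed", "detected", "missing", "flagged_empty"])
    return JoinResult(ages=ages, coverage=coverage)
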