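"""The ordered species timeline on which every age distribution lives.

A timeline is a linear sequence of taxa along the human lineage, oldest
first, each carrying the divergence time (in millions of years ago, Ma)
of the corresponding branch point.  A gene assigned to taxon *s* is one
whose detectable homologs extend back to that branch point; the taxon's
divergence time is therefore a lower bound on the gene's age.

Every other module states ages in Ma only through a :class:`Timeline`.
Taxon indices are 1-based, oldest first, throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import LookupError_, ValidationError

__all__ = ["Timeline", "default_timeline", "load_timeline", "write_timeline"]

#: Divergence times (Ma) of the 16 human-lineage taxa used by default.
#: Opisthokonta, Bilateria, Chordata and Homininae carry fixed literature
#: values; the remaining entries are editable TimeTree-style defaults
#: (Deuterostomia is constrained to lie between its fixed neighbours).
_DEFAULT_TAXA: tuple[tuple[str, float], ...] = (
    ("Cellular Organisms", 4100.0),
    ("Eukaryota", 2100.0),
    ("Opisthokonta", 1368.0),
    ("Bilateria", 910.0),
    ("Deuterostomia", 850.0),
    ("Chordata", 797.0),
    ("Euteleostomi", 435.0),
    ("Tetrapoda", 352.0),
    ("Amniota", 312.0),
    ("Mammalia", 177.0),
    ("Theria", 159.0),
    ("Eutheria", 105.0),
    ("Euarchontoglires", 90.0),
    ("Catarrhini", 29.0),
    ("Homininae", 6.0),
    ("H. sapiens", 0.0),
)

#: Default Ma value assigned to the left anchor of the cumulative curve
#: (used for median interpolation when >= 50% of a class sits in the
#: oldest bucket).  A display/median convention, not a biological claim.
DEFAULT_ROOT_AGE = 4200.0


@dataclass(frozen=True)
class Timeline:
    """An ordered lineage of taxa with strictly decreasing divergence times.

    Parameters
    ----------
    taxa
        Taxon names, oldest first (index 1 = oldest in the package's
        1-based convention).
    ages
        Divergence times in Ma, same length as ``taxa``, strictly
        decreasing; the last entry must be >= 0.
    root_age
        Ma value anchoring the left end of cumulative curves;
        must be >= the first age.
    """

    taxa: tuple[str, ...]
    ages: tuple[float, ...]
    root_age: float = DEFAULT_ROOT_AGE
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxa)
        ages = tuple(float(a) for a in self.ages)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "ages", ages)
        if len(taxa) != len(ages):
            raise ValidationError(
                f"taxa ({len(taxa)}) and ages ({len(ages)}) differ in length"
            )
        if len(taxa) < 2:
            raise ValidationError("a timeline needs at least 2 taxa")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon names: {dupes}")
        for i in range(len(ages) - 1):
            if not ages[i] > ages[i + 1]:
                raise ValidationError(
                    "ages not strictly decreasing at "
                    f"{taxa[i]!r} ({ages[i]}) -> {taxa[i + 1]!r} ({ages[i + 1]})"
                )
        if ages[-1] < 0:
            raise ValidationError(f"last age must be >= 0, got {ages[-1]}")
        if self.root_age < ages[0]:
            raise ValidationError(
                f"root_age {self.root_age} < oldest taxon age {ages[0]}"
            )
        object.__setattr__(self, "_index", {t: i + 1 for i, t in enumerate(taxa)})

    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def k(self) -> int:
        """Number of taxa (breakpoints) on the timeline."""
        return len(self.taxa)

    def index_of(self, taxon: str) -> int:
        """1-based index of ``taxon`` (1 = oldest)."""
        try:
            return self._index[taxon]
        except KeyError:
            raise LookupError_(
                f"unknown taxon {taxon!r}; valid names: {list(self.taxa)}"
            ) from None

    def age_of(self, taxon: str) -> float:
        """Divergence time (Ma) of ``taxon``."""
        return self.ages[self.index_of(taxon) - 1]

    def taxon_at(self, index: int) -> str:
        """Taxon name at 1-based ``index``."""
        if not 1 <= index <= self.k:
            raise LookupError_(f"taxon index {index} outside 1..{self.k}")
        return self.taxa[index - 1]

    def validate_index(self, index: int) -> int:
        if not 1 <= int(index) == index <= self.k:
            raise ValidationError(f"taxon index {index} outside 1..{self.k}")
        return int(index)


def default_timeline() -> Timeline:
    """The 16-taxon human-lineage timeline used throughout.

    Cellular Organisms -> ... -> H. sapiens, with Opisthokonta at 1368 Ma,
    Bilateria at 910 Ma, Chordata at 797 Ma and Homininae at 6 Ma; the
    remaining divergence times are package defaults that can be replaced
    via a timeline CSV (:func:`load_timeline`).
    """
    taxa, ages = zip(*_DEFAULT_TAXA)
    return Timeline(taxa=taxa, ages=ages, root_age=DEFAULT_ROOT_AGE)


def age_of(timeline: Timeline, taxon: str) -> float:
    """Divergence time (Ma) of ``taxon`` on ``timeline``; free-function form."""
    return timeline.age_of(taxon)


def load_timeline(path: str | Path) -> Timeline:
    """Read a timeline from a CSV of ``taxon,age_ma`` rows, oldest first.

    Lines starting with ``#`` are comments; a comment of the form
    ``# root_age_ma: 4200`` overrides the default root age.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"timeline file not found: {path}")
    root_age: float | None = None
    rows: list[tuple[str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].lstrip().startswith("#"):
                text = ",".join(row).lstrip("# ").strip()
                if text.lower().startswith("root_age_ma"):
                    root_age = float(text.split(":", 1)[1])
                continue
            if not header_seen:
                if [c.strip().lower() for c in row[:2]] != ["taxon", "age_ma"]:
                    raise ValidationError(
                        f"{path}:{lineno}: expected header 'taxon,age_ma', got {row!r}"
                    )
                header_seen = True
                continue
            if len(row) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {row!r}")
            try:
                age = float(row[1])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: age {row[1]!r} is not a number"
                ) from None
            rows.append((row[0].strip(), age))
    if not rows:
        raise ValidationError(f"{path}: no taxon rows found")
    taxa, ages = zip(*rows)
    kwargs = {} if root_age is None else {"root_age": root_age}
    try:
        return Timeline(taxa=taxa, ages=ages, **kwargs)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_timeline(timeline: Timeline, path: str | Path) -> None:
    """Write ``timeline`` in the CSV dialect read by :func:`load_timeline`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# root_age_ma: {timeline.root_age:g}\n")
        writer = csv.writer(fh)
        writer.writerow(["taxon", "age_ma"])
        for taxon, age in zip(timeline.taxa, timeline.ages):
            writer.writerow([taxon, f"{age:g}"])


def ma_to_index(timeline: Timeline, age_ma: float, tol: float = 1e-6) -> int:
    """Map an age in Ma to the oldest taxon whose divergence time <= age + tol.

    Values at or above the oldest taxon's age map to index 1; values below
    the youngest taxon's age (minus ``tol``) are rejected.
    """
    if age_ma + tol < timeline.ages[-1]:
        raise ValidationError(
            f"age {age_ma} Ma below the youngest taxon age {timeline.ages[-1]}"
        )
    for i, a in enumerate(timeline.ages):
        if a <= age_ma + tol:
            return i + 1
    return timeline.k  # unreachable given the guard above
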