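"""Synthetic gene-age studies with the structure the analysis assumes.

Real inputs to this kind of study are database snapshots (gene-class
membership) joined to a family-based age assignment; neither ships with
the package.  The generator replaces them with a controlled model: each
class draws its genes' taxon-of-origin indices i.i.d. from a per-class
multinomial origination profile over the k timeline taxa, classes may
share genes (a shared gene keeps the single age it was first drawn
with), and all remaining genes of the universe follow a base profile.
This reproduces the statistical features the pipeline relies on —
per-class multinomial profiles, realistic class sizes, overlapping
membership, and exactly-null pairs for calibration — while making no
claim to reproduce any real database's curves.

Everything is a pure function of (specs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .tables import AgeTable, GeneClassCatalog
from .timeline import Timeline, default_timeline

__all__ = [
    "ClassSpec",
    "simulate_class",
    "simulate_study",
    "paper_like_spec",
    "planted_groups_spec",
    "OLD_PROFILE",
    "INTERMEDIATE_PROFILE",
    "YOUNG_PROFILE",
    "BASE_PROFILE",
]

# Stylized origination profiles over the 16 default taxa.  They echo the
# qualitative shapes of old / intermediate / young gene-class curves
# (early mass with a mid-timeline surge; a later surge; recent-heavy)
# and are NOT digitized from any published figure.
OLD_PROFILE = (
    0.10, 0.13, 0.06, 0.18, 0.03, 0.15, 0.12, 0.05,
    0.04, 0.04, 0.02, 0.02, 0.02, 0.02, 0.01, 0.01,
)
INTERMEDIATE_PROFILE = (
    0.04, 0.05, 0.05, 0.08, 0.04, 0.20, 0.12, 0.08,
    0.06, 0.08, 0.04, 0.05, 0.04, 0.03, 0.02, 0.02,
)
YOUNG_PROFILE = (
    0.02, 0.02, 0.02, 0.02, 0.02, 0.04, 0.05, 0.05,
    0.06, 0.08, 0.08, 0.10, 0.12, 0.12, 0.10, 0.10,
)
#: Background profile for universe genes outside every class (an
#: all-protein-coding-like mixture between old and intermediate).
BASE_PROFILE = (
    0.08, 0.08, 0.05, 0.12, 0.04, 0.14, 0.10, 0.06,
    0.05, 0.06, 0.04, 0.05, 0.04, 0.04, 0.03, 0.02,
)

#: Default universe size: the number of detected protein-coding genes in
#: a genome-wide scan of the human lineage used as the reference figure.
DEFAULT_UNIVERSE_SIZE = 19_911


@dataclass(frozen=True)
class ClassSpec:
    """Specification of one synthetic gene class.

    ``pi`` is the origination-probability vector over the k taxa;
    ``overlap_with`` optionally names an earlier class and the expected
    fraction of THIS class's genes shared with it.
    """

    name: str
    n: int
    pi: tuple[float, ...]
    overlap_with: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        pi = tuple(float(x) for x in self.pi)
        object.__setattr__(self, "pi", pi)
        if self.n < 1:
            raise ValidationError(f"class {self.name!r}: n must be >= 1")
        if any(x < 0 for x in pi):
            raise ValidationError(f"class {self.name!r}: pi must be nonnegative")
        if abs(sum(pi) - 1.0) > 1e-12:
            raise ValidationError(
                f"class {self.name!r}: pi sums to {sum(pi)!r}, not 1"
            )
        if self.overlap_with is not None:
            _, frac = self.overlap_with
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"class {self.name!r}: shared fraction {frac} outside [0, 1]"
                )


def _draw_ages(
    pi: Sequence[float], n: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.size != k:
        raise ValidationError(f"pi has length {pi.size}, timeline has {k} taxa")
    return rng.choice(np.arange(1, k + 1), size=n, p=pi / pi.sum())


def simulate_class(
    spec: ClassSpec, timeline: Timeline, seed: int | None = None
) -> tuple[list[str], np.ndarray]:
    """Draw one class: gene ids plus i.i.d. taxon indices from ``spec.pi``."""
    rng = np.random.default_rng(seed)
    ages = _draw_ages(spec.pi, spec.n, timeline.k, rng)
    ids = [f"{spec.name}_{i:05d}" for i in range(1, spec.n + 1)]
    return ids, ages


def simulate_study(
    specs: Sequence[ClassSpec],
    timeline: Timeline,
    seed: int | None = None,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    base_pi: Sequence[float] | None = None,
) -> tuple[AgeTable, GeneClassCatalog]:
    """Generate a full study: an age table over a gene universe plus classes.

    Classes are realized in order.  A class with ``overlap_with=(other,
    frac)`` takes ``round(frac * n)`` of its members (without
    replacement) from the already-realized ``other`` class — those genes
    keep the age they were first drawn with — and fills the rest with
    fresh universe genes aged from its own profile.  Genes belonging to
    no class follow ``base_pi``.  The output feeds
    :func:`geneage.tables.join_ages` directly.
    """
    if len({s.name for s in specs}) != len(specs):
        raise ValidationError("duplicate class names in specs")
    rng = np.random.default_rng(seed)
    k = timeline.k
    ids = [f"G{i:06d}" for i in range(1, universe_size + 1)]
    ages: dict[str, int] = {}
    classes: dict[str, frozenset[str]] = {}
    cursor = 0
    for spec in specs:
        shared: list[str] = []
        if spec.overlap_with is not None:
            other, frac = spec.overlap_with
            if other not in classes:
                raise ValidationError(
                    f"class {spec.name!r} overlaps with unknown/later class {other!r}"
                )
            n_shared = round(frac * spec.n)
            if n_shared > len(classes[other]):
                raise ValidationError(
                    f"class {spec.name!r}: overlap demands {n_shared} genes but "
                    f"{other!r} has only {len(classes[other])}"
                )
            shared = list(rng.choice(sorted(classes[other]), size=n_shared, replace=False))
        n_fresh = spec.n - len(shared)
        fresh = ids[cursor : cursor + n_fresh]
        if len(fresh) < n_fresh:
            raise ValidationError(
                f"universe of {universe_size} genes exhausted at class {spec.name!r}"
            )
        cursor += n_fresh
        for gene, age in zip(fresh, _draw_ages(spec.pi, n_fresh, k, rng)):
            ages[gene] = int(age)
        classes[spec.name] = frozenset(shared) | frozenset(fresh)
    rest = ids[cursor:]
    if base_pi is None:
        base_pi = BASE_PROFILE if k == 16 else tuple([1.0 / k] * k)
    for gene, age in zip(rest, _draw_ages(base_pi, len(rest), k, rng)):
        ages[gene] = int(age)
    age_table = AgeTable(records=ages, timeline=timeline)
    catalog = GeneClassCatalog(classes=dict(classes), universe=frozenset(ids))
    return age_table, catalog


def paper_like_spec() -> list[ClassSpec]:
    """Ten class specs with realistic detected sizes and three profile families.

    Sizes follow the detected counts of the curated human gene-class
    databases (housekeeping 6789, oncogenes 224, tumor suppressors 984,
    differentiation 3697, homeobox 231, apoptosis 53, autosomal CT 109,
    tumor-specific coding 60, CT-X 78, tumor-specific non-coding 121);
    the old / intermediate / young profiles plant three well-separated
    cluster families.  Illustrative study conditions — not a
    reconstruction of any real dataset.
    """
    return [
        ClassSpec("housekeeping", 6789, OLD_PROFILE),
        ClassSpec("differentiation", 3697, OLD_PROFILE),
        ClassSpec("oncogenes", 224, OLD_PROFILE, overlap_with=("differentiation", 0.25)),
        ClassSpec("tumor_suppressor", 984, OLD_PROFILE, overlap_with=("differentiation", 0.20)),
        ClassSpec("homeobox", 231, INTERMEDIATE_PROFILE),
        ClassSpec("apoptosis", 53, INTERMEDIATE_PROFILE),
        ClassSpec("ct_autosomal", 109, INTERMEDIATE_PROFILE),
        ClassSpec("gstse_coding", 60, INTERMEDIATE_PROFILE),
        ClassSpec("ct_x", 78, YOUNG_PROFILE),
        ClassSpec("gstse_noncoding", 121, YOUNG_PROFILE),
    ]


def planted_groups_spec(
    n_per_class: int = 300, classes_per_group: int = 3
) -> list[ClassSpec]:
    """Three well-separated profile groups for clustering-recovery studies."""
    profiles = {
        "old": OLD_PROFILE,
        "mid": INTERMEDIATE_PROFILE,
        "young": YOUNG_PROFILE,
    }
    return [
        ClassSpec(f"{family}_{i}", n_per_class, pi)
        for family, pi in profiles.items()
        for i in range(1, classes_per_group + 1)
    ]
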