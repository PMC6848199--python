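"""Per-class age distributions: origination counts, cumulative curves, medians.

The central object is the cumulative origination curve C of a gene
class: C(s) is the share of the class's genes whose origin lies at or
before taxon s (taxon indices are 1-based, oldest first).  Equivalently
1 - C(s-1) is the CDF-complement of gene age in Ma, so a class whose
age is stochastically smaller (a *younger* class) has an origination
curve that lies everywhere at or below the other's, while its age-CDF is
everywhere larger.  All downstream statistics (KS distances, clustering,
stochastic-order bands) operate on these curves.

The class median age in Ma is read off a piecewise-linear interpolation
of the curve over the time axis, anchored on the left at
``(root_age, 0)`` so that classes with half their mass in the oldest
bucket still receive a finite median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .timeline import Timeline

__all__ = [
    "AgeDistribution",
    "build_distribution",
    "from_counts",
    "median_age",
    "originated_between",
    "distribution_frame",
]


@dataclass(frozen=True)
class AgeDistribution:
    """Origination counts and cumulative curve of one gene class.

    Attributes
    ----------
    class_name
        Label of the class.
    n
        Number of genes (sum of counts).
    counts
        Per-taxon origination counts, length k.
    cum
        Cumulative origination proportions: ``cum[s-1]`` is the share of
        genes with taxon index <= s; nondecreasing with ``cum[-1] == 1``.
    """

    class_name: str
    n: int
    counts: np.ndarray
    cum: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 2:
            raise ValidationError("counts must be a 1-d vector over >= 2 taxa")
        if (counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        if counts.sum() != self.n or self.n <= 0:
            raise ValidationError(
                f"empty class or inconsistent n: sum(counts)={counts.sum()}, n={self.n}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "cum", np.cumsum(counts) / self.n)

    @property
    def k(self) -> int:
        return self.counts.size


def from_counts(class_name: str, counts: Sequence[int], timeline: Timeline) -> AgeDistribution:
    """Build an :class:`AgeDistribution` directly from per-taxon counts."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size != timeline.k:
        raise ValidationError(
            f"counts length {counts.size} != timeline size {timeline.k}"
        )
    n = int(counts.sum())
    if n == 0:
        raise ValidationError(f"empty class {class_name!r}")
    return AgeDistribution(class_name=class_name, n=n, counts=counts, cum=None)  # type: ignore[arg-type]


def build_distribution(
    class_name: str, age_vector: Sequence[int], timeline: Timeline
) -> AgeDistribution:
    """Distribution of a class from its vector of 1-based taxon indices."""
    ages = np.asarray(age_vector, dtype=np.int64)
    if ages.size == 0:
        raise ValidationError(f"empty class {class_name!r}")
    if ages.min() < 1 or ages.max() > timeline.k:
        raise ValidationError(
            f"class {class_name!r}: taxon indices outside 1..{timeline.k}"
        )
    counts = np.bincount(ages, minlength=timeline.k + 1)[1:]
    return from_counts(class_name, counts, timeline)


def median_age(dist: AgeDistribution, timeline: Timeline) -> float:
    """Median evolutionary age (Ma) of a class.

    The time point at which the piecewise-linear curve through
    ``(root_age, 0), (age_1, C(1)), ..., (age_k, C(k))`` equals 0.5.
    If the curve hits 0.5 exactly at a breakpoint, that taxon's age is
    returned; otherwise the crossing is linearly interpolated between the
    bracketing breakpoints on the Ma axis.
    """
    if dist.k != timeline.k:
        raise ValidationError("distribution and timeline sizes differ")
    cum = dist.cum
    xs = np.concatenate([[timeline.root_age], timeline.ages])  # decreasing
    ys = np.concatenate([[0.0], cum])
    s = int(np.argmax(ys >= 0.5))  # first index reaching 0.5
    if ys[s] == 0.5:
        return float(xs[s])
    x_hi, y_lo = xs[s - 1], ys[s - 1]
    x_lo, y_hi = xs[s], ys[s]
    return float(x_hi - (0.5 - y_lo) / (y_hi - y_lo) * (x_hi - x_lo))


def _resolve_index(timeline: Timeline, taxon: int | str) -> int:
    if isinstance(taxon, str):
        return timeline.index_of(taxon)
    return timeline.validate_index(taxon)


def originated_between(
    dist: AgeDistribution, taxon_a: int | str, taxon_b: int | str, timeline: Timeline
) -> float:
    """Share of a class's genes that originated in the interval (a, b].

    ``taxon_a`` must be older than or equal to ``taxon_b`` (taxa given by
    name or 1-based index).  For ``a < b`` this is ``C(b) - C(a)``, the
    share of genes strictly after taxon a and up to taxon b; for
    ``a == b`` it is the share that originated exactly at that taxon.
    """
    a = _resolve_index(timeline, taxon_a)
    b = _resolve_index(timeline, taxon_b)
    if a > b:
        raise ValidationError(
            f"taxon_a (index {a}) must be older than or equal to taxon_b (index {b})"
        )
    if a == b:
        return float(dist.counts[a - 1] / dist.n)
    return float(dist.cum[b - 1] - dist.cum[a - 1])


def distribution_frame(dist: AgeDistribution, timeline: Timeline) -> pd.DataFrame:
    """Export a distribution as a ``taxon,age_ma,count,cum`` table."""
    return pd.DataFrame(
        {
            "taxon": list(timeline.taxa),
            "age_ma": list(timeline.ages),
            "count": dist.counts,
            "cum": dist.cum,
        }
    )
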