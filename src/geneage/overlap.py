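"""Gene-class intersection analysis.

Gene classes drawn from curated databases overlap: a gene may carry
oncogene, tumor-suppressor and differentiation annotations at once.
This module quantifies pairwise overlaps against the independence
expectation |A||B|/N over a universe of N genes (2x2 contingency table,
chi-square and Fisher exact tests), enumerates triple/quadruple
intersections with per-class shares, and builds derived subclasses
(intersections ``A x B`` and differences ``A - B``) that feed back into
the age-distribution machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compare import chisq_homogeneity
from .errors import ValidationError
from .tables import GeneClassCatalog

__all__ = [
    "OverlapResult",
    "contingency_2x2",
    "fisher_exact_2x2",
    "class_algebra",
    "multiway_intersections",
    "pairwise_overlap_table",
]


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs expected overlap of two classes over a universe."""

    pair: tuple[str, str]
    n_a: int
    n_b: int
    observed: int
    expected: float
    table: np.ndarray  # [[both, A_only], [B_only, neither]]
    chi2_p: float
    fisher_p: float


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Two-sidedness by the point-probability method: the sum of
    hypergeometric probabilities of all tables (with the same margins)
    no more likely than the observed one.  A zero row or column margin
    leaves only one achievable table, so p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("need a 2x2 table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def contingency_2x2(
    class_a: Iterable[str],
    class_b: Iterable[str],
    universe: Iterable[str],
    names: tuple[str, str] = ("A", "B"),
) -> OverlapResult:
    """Overlap of two gene classes against the independence expectation.

    Builds the 2x2 membership table (in both / A only / B only /
    neither) over the universe, the expected overlap N |A|/N |B|/N under
    independent attendance, and chi-square (no continuity correction)
    plus Fisher exact p-values.  Degenerate tables (a class empty or
    equal to the universe) yield NaN for the chi-square p-value; Fisher
    falls back to its zero-margin convention.
    """
    a, b, u = set(class_a), set(class_b), set(universe)
    if not u:
        raise ValidationError("universe must be nonempty")
    stray = sorted((a | b) - u)
    if stray:
        raise ValidationError(f"classes not subsets of universe; offenders: {stray[:10]}")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(u) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]], dtype=np.int64)
    expected = len(u) * (len(a) / len(u)) * (len(b) / len(u))
    try:
        chi2_p = chisq_homogeneity(table).p_value
    except ValidationError:
        chi2_p = float("nan")
    return OverlapResult(
        pair=names,
        n_a=len(a),
        n_b=len(b),
        observed=both,
        expected=expected,
        table=table,
        chi2_p=chi2_p,
        fisher_p=fisher_exact_2x2(table),
    )


def class_algebra(catalog: GeneClassCatalog, expr: str) -> str:
    """Add a derived class to the catalog from ``"A x B"`` or ``"A - B"``.

    ``x`` is set intersection, ``-`` set difference (operators must be
    surrounded by spaces; operands are existing class names).  The new
    class is stored under the expression itself and is usable by every
    other module (age curves of ``diff x onco``-style subclasses etc.).
    Returns the new class name.
    """
    for op, fn in ((" x ", frozenset.intersection), (" - ", frozenset.difference)):
        if op in expr:
            left, right = (s.strip() for s in expr.split(op, 1))
            result = fn(catalog[left], catalog[right])
            name = f"{left}{op}{right}"
            catalog.add_class(name, result)
            return name
    raise ValidationError(
        f"cannot parse {expr!r}: expected 'A x B' (intersection) or 'A - B' (difference)"
    )


def multiway_intersections(
    catalog: GeneClassCatalog, max_order: int = 4
) -> pd.DataFrame:
    """Counts and per-class shares of triple/quadruple intersections.

    One row per (class combination, member class): the intersection
    count of the combination and the share ``count / |member|`` that the
    intersection occupies in that member class.  Orders 3 up to
    ``max_order`` (3 or 4) are enumerated.
    """
    if max_order not in (3, 4):
        raise ValidationError("max_order must be 3 or 4")
    names = catalog.names()
    rows = []
    for order in range(3, max_order + 1):
        for combo in combinations(names, order):
            inter = frozenset.intersection(*(catalog[c] for c in combo))
            for member in combo:
                size = len(catalog[member])
                rows.append(
                    {
                        "classes": " x ".join(combo),
                        "order": order,
                        "count": len(inter),
                        "member": member,
                        "member_share": len(inter) / size if size else float("nan"),
                    }
                )
    return pd.DataFrame(rows, columns=["classes", "order", "count", "member", "member_share"])


def pairwise_overlap_table(catalog: GeneClassCatalog) -> pd.DataFrame:
    """Observed/expected overlap and test p-values for every class pair."""
    names = catalog.names()
    rows = []
    for a, b in combinations(names, 2):
        res = contingency_2x2(catalog[a], catalog[b], catalog.universe, names=(a, b))
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "observed": res.observed,
                "expected": res.expected,
                "chi2_p": res.chi2_p,
                "fisher_p": res.fisher_p,
            }
        )
    return pd.DataFrame(rows)
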