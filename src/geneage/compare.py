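"""Pairwise distances and classical two-sample tests between age distributions.

The Kolmogorov-Smirnov (KS) distance between two classes is the maximum
absolute difference between their cumulative origination curves over the
taxon breakpoints; it drives both the pairwise significance tests and
the hierarchical clustering.  Gene ages are heavily tied (at most 16
support points), which makes the asymptotic two-sample KS p-value
conservative, so a label-permutation p-value is computed alongside it
and is the recommended headline number.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distributions import AgeDistribution, build_distribution
from .errors import ValidationError
from .timeline import Timeline

__all__ = [
    "DistanceMatrix",
    "KsTestResult",
    "ChisqResult",
    "ks_distance",
    "ks_two_sample_test",
    "chisq_homogeneity",
    "distance_matrix",
    "pairwise_matrix",
    "holm_adjust",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric KS-distance matrix over a set of class labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate labels in distance matrix")
        if np.any(np.isnan(d)):
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < 0) or np.any(d > 1):
            raise ValidationError("KS distances must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))


def ks_distance(dist_a: AgeDistribution, dist_b: AgeDistribution) -> float:
    """Maximum absolute difference of the two cumulative curves."""
    if dist_a.k != dist_b.k:
        raise ValidationError(
            f"distributions on different timelines (k={dist_a.k} vs {dist_b.k})"
        )
    return float(np.max(np.abs(dist_a.cum - dist_b.cum)))


class KsTestResult(NamedTuple):
    statistic: float
    p_asymptotic: float
    p_permutation: float
    n_permutations: int


def _cum_from_ages(ages: np.ndarray, k: int) -> np.ndarray:
    return np.cumsum(np.bincount(ages, minlength=k + 1)[1:]) / ages.size


def ks_two_sample_test(
    ages_a: Sequence[int],
    ages_b: Sequence[int],
    timeline: Timeline,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> KsTestResult:
    """Two-sample KS test on two taxon-index age vectors.

    The statistic is the KS distance between the empirical origination
    curves.  Two p-values are reported: the asymptotic two-sample
    Kolmogorov p-value, and a permutation p-value obtained by pooling
    the two samples and re-splitting labels ``n_permutations`` times
    (add-one rule).  The permutation value is exact-in-distribution
    under ties and is the recommended one for age data.
    """
    a = np.asarray(ages_a, dtype=np.int64)
    b = np.asarray(ages_b, dtype=np.int64)
    if a.size < 1 or b.size < 1:
        raise ValidationError("both samples must be nonempty")
    k = timeline.k
    for v, name in ((a, "A"), (b, "B")):
        if v.min() < 1 or v.max() > k:
            raise ValidationError(f"sample {name}: taxon indices outside 1..{k}")
    stat = float(np.max(np.abs(_cum_from_ages(a, k) - _cum_from_ages(b, k))))
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p_asym = float(np.clip(stats.kstwobign.sf(en * stat), 0.0, 1.0))

    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(pool)
        d = np.max(
            np.abs(_cum_from_ages(pool[: a.size], k) - _cum_from_ages(pool[a.size :], k))
        )
        if d >= stat - 1e-12:
            count += 1
    p_perm = (1 + count) / (1 + n_permutations)
    return KsTestResult(stat, p_asym, p_perm, n_permutations)


class ChisqResult(NamedTuple):
    chi2: float
    df: int
    p_value: float
    c_used: int


def chisq_homogeneity(count_matrix: Sequence[Sequence[int]]) -> ChisqResult:
    """Pearson chi-square homogeneity test on an r x c count table.

    All-zero columns are dropped before testing (they carry no
    information and would give zero expected counts); the number of
    columns actually used is reported as ``c_used`` and the degrees of
    freedom are ``(r - 1) * (c_used - 1)``.
    """
    table = np.asarray(count_matrix, dtype=float)
    if table.ndim != 2:
        raise ValidationError("count matrix must be 2-dimensional")
    if np.any(table < 0) or not np.all(table == np.floor(table)):
        raise ValidationError("counts must be nonnegative integers")
    if np.any(table.sum(axis=1) == 0):
        raise ValidationError("every row total must be > 0")
    used = table[:, table.sum(axis=0) > 0]
    r, c_used = used.shape
    if r < 2 or c_used < 2:
        raise ValidationError(
            f"degenerate table: {r} rows x {c_used} usable columns (need >= 2 each)"
        )
    row = used.sum(axis=1, keepdims=True)
    col = used.sum(axis=0, keepdims=True)
    expected = row @ col / used.sum()
    chi2 = float(np.sum((used - expected) ** 2 / expected))
    df = (r - 1) * (c_used - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ChisqResult(chi2, df, p, c_used)


def distance_matrix(dists: Sequence[AgeDistribution]) -> DistanceMatrix:
    """Full symmetric KS-distance matrix over a list of distributions."""
    labels = tuple(d.class_name for d in dists)
    m = len(dists)
    out = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        out[i, j] = out[j, i] = ks_distance(dists[i], dists[j])
    return DistanceMatrix(labels=labels, d=out)


def pairwise_matrix(
    class_ages: Mapping[str, np.ndarray],
    timeline: Timeline,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """KS-distance matrix plus a long-format pairwise test table.

    For every unordered class pair the table reports the KS statistic,
    its asymptotic and permutation p-values, the chi-square homogeneity
    test on the 2 x k count table (all-zero taxa dropped), and
    Holm-adjusted permutation p-values.  Self-pairs are excluded.
    """
    names = list(class_ages)
    if len(names) < 2:
        raise ValidationError("need at least 2 classes")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate class labels")
    dists = [build_distribution(n, class_ages[n], timeline) for n in names]
    dm = distance_matrix(dists)
    rng = np.random.default_rng(seed)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        ks = ks_two_sample_test(
            class_ages[a],
            class_ages[b],
            timeline,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        chis = chisq_homogeneity(np.vstack([dists[i].counts, dists[j].counts]))
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "n_a": dists[i].n,
                "n_b": dists[j].n,
                "ks_stat": ks.statistic,
                "ks_p_asym": ks.p_asymptotic,
                "ks_p_perm": ks.p_permutation,
                "chi2": chis.chi2,
                "df": chis.df,
                "chi2_p": chis.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["holm_p"] = holm_adjust(table["ks_p_perm"].to_numpy())
    return dm, table


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
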