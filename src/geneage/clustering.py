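"""Complete-linkage clustering of gene classes with bootstrap support.

Classes are clustered agglomeratively on the KS distance between their
cumulative origination curves, with inter-cluster distance the maximum
pairwise member distance (complete linkage; merge heights are therefore
nondecreasing).  Reliability is assessed by the nonparametric bootstrap:
each class's age vector is resampled with replacement at its original
size, the tree rebuilt, and each original clade's support reported as
the fraction of replicate trees containing the same leaf set.  The same
resampling drives per-curve exploratory statistics and the rates at
which one class's bootstrapped curve lies entirely below the other's
(stochastically younger without appeal to asymptotics).

Resampling a multiset of taxon indices with replacement is equivalent to
a multinomial draw over the empirical per-taxon proportions, which is
how the replicates are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import DistanceMatrix
from .distributions import build_distribution
from .errors import ValidationError
from .timeline import Timeline

__all__ = [
    "ClusterNode",
    "BootstrapTrees",
    "complete_linkage",
    "to_newick",
    "cut_tree",
    "bootstrap_trees",
    "bootstrap_order_rates",
    "bootstrap_curve_stats",
]


@dataclass(frozen=True)
class ClusterNode:
    """Node of a dendrogram; leaves have height 0 and no children."""

    height: float
    children: tuple["ClusterNode", ...]
    leaves: frozenset[str]
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def internal_nodes(self) -> list["ClusterNode"]:
        """All internal nodes (root included), pre-order."""
        out: list[ClusterNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes."""
        return {n.leaves for n in self.internal_nodes()}


def _min_leaf(node: ClusterNode) -> str:
    return min(node.leaves)


def complete_linkage(dm: DistanceMatrix) -> ClusterNode:
    """Agglomerative complete-linkage dendrogram from a distance matrix.

    At each step the pair of clusters at minimum distance is merged;
    the distance between clusters is the maximum pairwise distance of
    their members.  Ties are broken deterministically by the
    lexicographically smallest pair of cluster representatives (each
    cluster represented by its smallest leaf label).
    """
    if np.any(np.isnan(dm.d)):
        raise ValidationError("distance matrix contains NaN")
    if len(dm.labels) < 2:
        raise ValidationError("need at least 2 labels to cluster")
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, children=(), leaves=frozenset([lab]), label=lab)
        for i, lab in enumerate(dm.labels)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.d[i, j]) for i, j in combinations(range(len(dm.labels)), 2)
    }
    next_id = len(dm.labels)
    while len(nodes) > 1:
        best_key = min(
            dist,
            key=lambda ij: (
                dist[ij],
                tuple(sorted((_min_leaf(nodes[ij[0]]), _min_leaf(nodes[ij[1]])))),
            ),
        )
        i, j = best_key
        h = dist[best_key]
        a, b = nodes.pop(i), nodes.pop(j)
        children = tuple(sorted((a, b), key=_min_leaf))
        merged = ClusterNode(height=h, children=children, leaves=a.leaves | b.leaves)
        # complete linkage: distance to the merge is the max of the two
        new_dist: dict[tuple[int, int], float] = {}
        for (x, y), d in dist.items():
            if i in (x, y) or j in (x, y):
                continue
            new_dist[(x, y)] = d
        for m in nodes:
            da = dist[(min(i, m), max(i, m))]
            db = dist[(min(j, m), max(j, m))]
            new_dist[(min(m, next_id), max(m, next_id))] = max(da, db)
        nodes[next_id] = merged
        dist = new_dist
        next_id += 1
    return next(iter(nodes.values()))


def _fmt(x: float) -> str:
    return f"{x:g}"


def to_newick(node: ClusterNode) -> str:
    """Ultrametric Newick string; branch length = parent - child height."""

    def render(n: ClusterNode, parent_height: float) -> str:
        bl = _fmt(parent_height - n.height)
        if n.is_leaf:
            return f"{n.label}:{bl}"
        inner = ",".join(render(c, n.height) for c in n.children)
        return f"({inner}):{bl}"

    if node.is_leaf:
        return f"{node.label};"
    inner = ",".join(render(c, node.height) for c in node.children)
    return f"({inner});"


def cut_tree(node: ClusterNode, n_clusters: int) -> list[frozenset[str]]:
    """Cut the dendrogram into ``n_clusters`` groups at the highest merges."""
    if n_clusters < 1 or n_clusters > len(node.leaves):
        raise ValidationError(f"cannot cut into {n_clusters} clusters")
    groups: list[ClusterNode] = [node]
    while len(groups) < n_clusters:
        tallest = max(
            (g for g in groups if not g.is_leaf), key=lambda g: g.height, default=None
        )
        if tallest is None:
            break
        groups.remove(tallest)
        groups.extend(tallest.children)
    return sorted((g.leaves for g in groups), key=min)


@dataclass(frozen=True)
class BootstrapTrees:
    """Original tree plus bootstrap clade-support rates.

    ``node_support`` maps each original internal node's leaf set to the
    fraction of replicate trees containing it as a clade (the root is
    always 1).  ``class_support`` gives, for each class, the support of
    the clade formed at that leaf's first merge in the original tree.
    """

    tree: ClusterNode
    node_support: dict[frozenset[str], float]
    class_support: dict[str, float]
    n_boot: int
    seed: int | None

    def support_frame(self) -> pd.DataFrame:
        rows = [
            {"leaf_set": "|".join(sorted(ls)), "size": len(ls), "support": s}
            for ls, s in sorted(
                self.node_support.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows)


def _boot_cums(
    counts: np.ndarray, n: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_boot, k) bootstrap cumulative curves for one class."""
    draws = rng.multinomial(n, counts / n, size=n_boot)
    return np.cumsum(draws, axis=1) / n


def _tree_from_cums(labels: Sequence[str], cums: np.ndarray) -> ClusterNode:
    m = len(labels)
    d = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        d[i, j] = d[j, i] = np.max(np.abs(cums[i] - cums[j]))
    return complete_linkage(DistanceMatrix(labels=tuple(labels), d=d))


def bootstrap_trees(
    class_ages: Mapping[str, np.ndarray],
    timeline: Timeline,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> BootstrapTrees:
    """Complete-linkage tree with bootstrap clade support.

    Each replicate independently resamples every class at its original
    size, rebuilds the KS-distance matrix and the tree, and records
    which original clades reappear.  Classes sharing genes are
    resampled independently all the same (the resampling is of each
    class's own age vector).
    """
    labels = list(class_ages)
    if len(labels) < 2:
        raise ValidationError("need at least 2 classes")
    dists = [build_distribution(lab, class_ages[lab], timeline) for lab in labels]
    orig_cums = np.vstack([d.cum for d in dists])
    tree = _tree_from_cums(labels, orig_cums)
    clades = tree.clades()
    hits = {ls: 0 for ls in clades}
    rng = np.random.default_rng(seed)
    all_boot = [
        _boot_cums(d.counts, d.n, n_boot, rng) for d in dists
    ]  # list of (n_boot, k)
    for r in range(n_boot):
        rep_tree = _tree_from_cums(labels, np.vstack([b[r] for b in all_boot]))
        rep_clades = rep_tree.clades()
        for ls in clades:
            if ls in rep_clades:
                hits[ls] += 1
    node_support = {ls: hits[ls] / n_boot for ls in clades}
    class_support: dict[str, float] = {}
    for lab in labels:
        parents = [ls for ls in clades if lab in ls]
        first_merge = min(parents, key=len)
        class_support[lab] = node_support[first_merge]
    return BootstrapTrees(
        tree=tree,
        node_support=node_support,
        class_support=class_support,
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_order_rates(
    ages_a: np.ndarray,
    ages_b: np.ndarray,
    timeline: Timeline,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Bootstrap rates of strict curve ordering between two classes.

    Per replicate both classes are resampled and the curves compared at
    every breakpoint: ``A_lower`` when A's curve is everywhere <= B's
    with strict inequality somewhere (A stochastically younger in the
    replicate), ``B_lower`` symmetrically, ``no_strict_order`` otherwise
    (crossing curves, or curves tied everywhere).  The three rates
    partition the replicates and sum to 1.
    """
    da = build_distribution("A", ages_a, timeline)
    db = build_distribution("B", ages_b, timeline)
    rng = np.random.default_rng(seed)
    ca = _boot_cums(da.counts, da.n, n_boot, rng)
    cb = _boot_cums(db.counts, db.n, n_boot, rng)
    diff = ca - cb
    eps = 1e-12
    a_lower = np.all(diff <= eps, axis=1) & np.any(diff < -eps, axis=1)
    b_lower = np.all(diff >= -eps, axis=1) & np.any(diff > eps, axis=1)
    return {
        "A_lower": float(np.mean(a_lower)),
        "B_lower": float(np.mean(b_lower)),
        "no_strict_order": float(np.mean(~a_lower & ~b_lower)),
    }


def bootstrap_curve_stats(
    ages: np.ndarray,
    timeline: Timeline,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exploratory bootstrap statistics of one cumulative curve.

    Per taxon breakpoint: the original cumulative proportion, the
    bootstrap mean, the mean squared deviation from the original curve
    (MSE), and the bootstrap quartiles/median.
    """
    dist = build_distribution("class", ages, timeline)
    rng = np.random.default_rng(seed)
    cums = _boot_cums(dist.counts, dist.n, n_boot, rng)
    q25, q50, q75 = np.quantile(cums, [0.25, 0.5, 0.75], axis=0)
    return pd.DataFrame(
        {
            "taxon": list(timeline.taxa),
            "age_ma": list(timeline.ages),
            "original": dist.cum,
            "boot_mean": cums.mean(axis=0),
            "mse": np.mean((cums - dist.cum) ** 2, axis=0),
            "q25": q25,
            "median": q50,
            "q75": q75,
        }
    )
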