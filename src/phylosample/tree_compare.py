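"""Bipartition-based tree distances.

Robinson–Foulds (RF) distance counts the non-trivial bipartitions (splits)
present in one tree but not the other; it is normalized by 2(n−3), the
maximum for binary trees on n shared leaves.  Two weighted flavours sum
|branch length differences| over the union of splits, an absent split
contributing its full weight, optionally normalized by the total internal
branch length of both trees.  Trees with unequal leaf sets are pruned to the
intersection before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .tree import PhyloTree, prune_to_taxa


@dataclass
class BipartitionSet:
    """Non-trivial splits of an unrooted tree, canonicalized and weighted.

    Each split is stored as the frozenset of leaf names on the side NOT
    containing the lexicographically smallest leaf (the fixed reference
    taxon), so a split has one canonical representation regardless of tree
    orientation.  Weights are the branch lengths of the internal edges
    inducing the splits (summed if several edges of a multifurcating tree
    induce the same split after rooting artifacts).
    """

    leaf_set: frozenset[str]
    splits: frozenset[frozenset[str]]
    weights: dict[frozenset[str], float] = field(default_factory=dict)


def bipartition_set(tree: PhyloTree, restrict_to: Iterable[str] = ()) -> BipartitionSet:
    """Canonical non-trivial splits of `tree`, with branch-length weights.

    If `restrict_to` is nonempty the tree is pruned to those taxa first
    (suppressing unary nodes and summing lengths).  Trees with fewer than 4
    leaves have no non-trivial splits.
    """
    work = tree
    restrict = frozenset(restrict_to)
    if restrict:
        work = prune_to_taxa(tree, restrict)
    leaves = work.leaf_set()
    if len(leaves) < 4:
        return BipartitionSet(leaves, frozenset(), {})
    ref = min(leaves)
    n = len(leaves)
    weights: dict[frozenset[str], float] = {}
    below: dict[int, frozenset[str]] = {}
    for node in work.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        side = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = side
        if node is work.root or node.parent is None:
            continue
        if len(side) < 2 or len(side) > n - 2:
            continue  # trivial split
        canonical = leaves - side if ref in side else side
        weights[canonical] = weights.get(canonical, 0.0) + (node.length or 0.0)
    # a rooted tree's two basal edges induce the same split once; drop the
    # duplicate contribution by re-deriving splits from the canonical keys
    return BipartitionSet(leaves, frozenset(weights), weights)


def _shared_pruned(t1: PhyloTree, t2: PhyloTree) -> tuple[BipartitionSet, BipartitionSet, int]:
    shared = t1.leaf_set() & t2.leaf_set()
    if len(shared) < 4:
        raise ValueError(f"trees share only {len(shared)} taxa; need at least 4")
    return bipartition_set(t1, shared), bipartition_set(t2, shared), len(shared)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Plain and normalized Robinson–Foulds distance on the shared leaf set.

    rf = |S1 Δ S2|; normalized by 2(n−3) where n is the shared leaf count
    (even for multifurcating trees, whose maximum may not be attainable).
    """
    b1, b2, n = _shared_pruned(t1, t2)
    rf = len(b1.splits ^ b2.splits)
    return rf, rf / (2.0 * (n - 3))


def weighted_rf_distance(t1: PhyloTree, t2: PhyloTree, flavour: str = "sum_abs") -> float:
    """Branch-length-weighted RF distance.

    sum_abs: Σ over the union of splits of |w1(s) − w2(s)|, an absent split
    weighing 0.  normalized_sum_abs divides by the summed internal branch
    length of both trees (0 if both trees are internal-edge-free).
    """
    if flavour not in ("sum_abs", "normalized_sum_abs"):
        raise ValueError(f"unknown flavour {flavour!r}")
    b1, b2, _n = _shared_pruned(t1, t2)
    total = 0.0
    for s in b1.splits | b2.splits:
        total += abs(b1.weights.get(s, 0.0) - b2.weights.get(s, 0.0))
    if flavour == "sum_abs":
        return total
    denom = sum(b1.weights.values()) + sum(b2.weights.values())
    return total / denom if denom > 0 else 0.0


def pairwise_distance_table(
    trees: Sequence[PhyloTree],
    metric: Callable[[PhyloTree, PhyloTree], float] | str = "nrf",
) -> np.ndarray:
    """Symmetric matrix of a tree distance over all unordered pairs.

    `metric` is a callable (t1, t2) → float or one of "rf", "nrf", "wrf",
    "nwrf".  Metric errors are re-raised with the offending pair identified.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    fn = _metric_fn(metric)
    n = len(trees)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = fn(trees[i], trees[j])
            except ValueError as exc:
                raise ValueError(f"metric failed on tree pair ({i}, {j}): {exc}") from exc
    return out


def _metric_fn(metric) -> Callable[[PhyloTree, PhyloTree], float]:
    if callable(metric):
        return metric
    table = {
        "rf": lambda a, b: float(rf_distance(a, b)[0]),
        "nrf": lambda a, b: rf_distance(a, b)[1],
        "wrf": lambda a, b: weighted_rf_distance(a, b, "sum_abs"),
        "nwrf": lambda a, b: weighted_rf_distance(a, b, "normalized_sum_abs"),
    }
    try:
        return table[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None


def trees_isomorphic(t1: PhyloTree, t2: PhyloTree, length_tol: float | None = None) -> bool:
    """Topological identity on the full leaf sets (optionally checking lengths)."""
    if t1.leaf_set() != t2.leaf_set():
        return False
    if len(t1.leaf_set()) < 4:
        return True
    b1 = bipartition_set(t1)
    b2 = bipartition_set(t2)
    if b1.splits != b2.splits:
        return False
    if length_tol is not None:
        for s in b1.splits:
            if abs(b1.weights[s] - b2.weights[s]) > length_tol:
                return False
    return True
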