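"""Independent brute-force oracles used to validate the library.

Everything here is deliberately naive (enumeration, double loops, explicit
recursions) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from phylosample.tree import Node, PhyloTree


# ---------------------------------------------------------------------------
# topology enumeration
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(labels: list[str]) -> list[PhyloTree]:
    """All unrooted binary topologies by sequential leaf insertion.

    Yields (2n−5)!! trees for n labels (n ≥ 3): 3 labels → 1, 6 labels → 105.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")

    def star(a: str, b: str, c: str) -> Node:
        root = Node()
        for name in (a, b, c):
            root.add_child(Node(name, 1.0))
        return root

    def clone(node: Node) -> Node:
        new = Node(node.name, node.length)
        for c in node.children:
            new.add_child(clone(c))
        return new

    def attachment_points(root: Node) -> list[Node]:
        out = []
        stack = [root]
        while stack:
            n = stack.pop()
            if n.parent is not None:
                out.append(n)
            stack.extend(n.children)
        return out

    trees = [star(*labels[:3])]
    for label in labels[3:]:
        grown = []
        for t in trees:
            for i in range(len(attachment_points(t))):
                c = clone(t)
                edge_child = attachment_points(c)[i]
                parent = edge_child.parent
                mid = Node(None, 1.0)
                parent.children[parent.children.index(edge_child)] = mid
                mid.parent = parent
                mid.add_child(edge_child)
                mid.add_child(Node(label, 1.0))
                grown.append(c)
        trees = grown
    return [PhyloTree(t) for t in trees]


# ---------------------------------------------------------------------------
# naive splits and RF
# ---------------------------------------------------------------------------


def naive_splits(tree: PhyloTree) -> list[tuple[frozenset, frozenset]]:
    """Non-trivial splits as unordered (side, other-side) pairs."""
    all_leaves = frozenset(tree.leaf_names())

    def below(node: Node) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        return frozenset().union(*(below(c) for c in node.children))

    splits = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        stack.extend(n.children)
        if n.parent is None or not n.children:
            continue
        side = below(n)
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.append((side, all_leaves - side))
    # deduplicate (a rooted tree's two basal edges induce one split)
    unique = []
    for s in splits:
        if not any(s[0] in pair for pair in unique):
            unique.append(s)
    return unique


def naive_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count by explicit double loop over split pairs."""
    s1, s2 = naive_splits(t1), naive_splits(t2)
    only_1 = sum(1 for a in s1 if not any(a[0] in b for b in s2))
    only_2 = sum(1 for b in s2 if not any(b[0] in a for a in s1))
    return only_1 + only_2


# ---------------------------------------------------------------------------
# path-length (additive) distances
# ---------------------------------------------------------------------------


def path_length_matrix(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths by explicit root-path comparison."""

    paths: dict[str, list[tuple[int, float]]] = {}

    def walk(node: Node, acc: list[tuple[int, float]]):
        acc = acc + [(id(node), node.length or 0.0)]
        if not node.children:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            pa, pb = paths[a], paths[b]
            shared = 0
            for (na, _), (nb, _) in zip(pa, pb):
                if na == nb:
                    shared += 1
                else:
                    break
            dist = sum(l for _, l in pa[shared:]) + sum(l for _, l in pb[shared:])
            d[i, j] = d[j, i] = dist
    return labels, d


# ---------------------------------------------------------------------------
# likelihood enumeration oracles
# ---------------------------------------------------------------------------


def _internal_nodes(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder() if n.children]


def enum_loglik_jc(tree: PhyloTree, seqs: dict[str, str]) -> float:
    """JC log-likelihood by summing over all internal-node state assignments."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    length = len(next(iter(seqs.values())))

    def P(t: float) -> np.ndarray:
        e = np.exp(-4.0 / 3.0 * t)
        M = np.full((4, 4), 0.25 * (1 - e))
        np.fill_diagonal(M, 0.25 + 0.75 * e)
        return M

    internals = _internal_nodes(tree)
    total = 0.0
    for site in range(length):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            for leaf in tree.leaves():
                state[id(leaf)] = code[seqs[leaf.name][site]]
            lik = 0.25  # uniform root prior
            for node in tree.postorder():
                if node is tree.root:
                    continue
                lik *= P(node.length or 0.0)[state[id(node.parent)], state[id(node)]]
            site_lik += lik
        total += np.log(site_lik)
    return total


def enum_mk1_root_logliks(tree: PhyloTree, states: dict[str, int], k: float, beta: float) -> np.ndarray:
    """Per-root-state conditional log-likelihood by full enumeration."""

    def P(t: float) -> np.ndarray:
        e = np.exp(-k * beta * t)
        M = np.full((k, k), (1 - e) / k)
        np.fill_diagonal(M, 1 / k + (k - 1) / k * e)
        return M

    internals = [n for n in _internal_nodes(tree) if n is not tree.root]
    out = np.zeros(k)
    for root_state in range(k):
        total = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            st = {id(n): s for n, s in zip(internals, assign)}
            st[id(tree.root)] = root_state
            for leaf in tree.leaves():
                st[id(leaf)] = states[leaf.name]
            lik = 1.0
            for node in tree.postorder():
                if node is tree.root:
                    continue
                lik *= P(node.length or 0.0)[st[id(node.parent)], st[id(node)]]
            total += lik
        with np.errstate(divide="ignore"):
            out[root_state] = np.log(total)
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony (independent of the Sankoff implementation)
# ---------------------------------------------------------------------------


def fitch_score(tree: PhyloTree, states: dict[str, int]) -> int:
    """Classic Fitch count on a (possibly multifurcating) rooted tree.

    For binary trees this equals the unit-cost Sankoff minimum.
    """
    changes = 0

    def down(node: Node) -> set[int]:
        nonlocal changes
        if not node.children:
            return {states[node.name]}
        sets = [down(c) for c in node.children]
        inter = set.intersection(*sets)
        if inter:
            return inter
        changes += len(sets) - 1  # binary: one change per empty intersection
        return set.union(*sets)

    down(tree.root)
    return changes
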