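"""Self-contained tree inference: JC distances + neighbor joining, and an
optional ML hill-climb over nearest-neighbor interchanges.

The built-in engines keep the pipeline free of external programs.  The
distance engine ("nj") is fully deterministic: Jukes–Cantor corrected
pairwise distances followed by Saitou–Nei neighbor joining with ties broken
by taxon label.  The "ml-nni" engine refines the NJ tree by NNI hill
climbing under a Jukes–Cantor likelihood with per-branch Brent length
optimization.  Externally inferred trees can be supplied anywhere a tree is
an input (newick), so results from dedicated ML software can be re-analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment_io import GeneAlignment
from .tree import (  # noqa: F401  (re-exported: this module owns tree I/O)
    NewickError,
    Node,
    PhyloTree,
    parse_newick,
    prune_to_taxa,
    root_at_outgroup,
    write_newick,
)

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def jc_distance_matrix(aln: GeneAlignment, max_distance: float = 5.0) -> DistanceMatrix:
    """Jukes–Cantor corrected pairwise distances.

    p is computed over columns where both taxa have an unambiguous base;
    d = −(3/4)·ln(1 − (4/3)p).  Saturated pairs (p ≥ 3/4) and pairs with no
    shared sites get `max_distance`.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    valid = (aln.codes < 4).astype(np.float32)
    shared = valid @ valid.T
    matches = np.zeros_like(shared)
    for b in range(4):
        hit = (aln.codes == b).astype(np.float32)
        matches += hit @ hit.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - matches / shared
    d = np.full_like(p, max_distance)
    ok = (shared > 0) & (p < 0.75 - 1e-12)
    d[ok] = -0.75 * np.log1p(-(4.0 / 3.0) * p[ok])
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(aln.taxa), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei agglomeration with the Q-criterion.

    Deterministic: among minimal-Q pairs the one with lexicographically
    smallest (sorted) pair of cluster labels is joined, a cluster's label
    being its smallest leaf label.  Negative branch lengths are clamped to 0.
    The returned tree is unrooted (basal trifurcation).
    """
    m = len(D.labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=lab) for lab in D.labels]
    labels = list(D.labels)  # tie-break key per active cluster
    d = D.d.astype(float).copy()
    active = list(range(m))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-9 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((labels[active[a]], labels[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (k - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row[None, :]])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    root = Node()
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        root.add_child(nodes[idx])
    tree = PhyloTree(root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Jukes-Cantor likelihood (Felsenstein pruning)
# ---------------------------------------------------------------------------


def _jc_transition(t: float) -> np.ndarray:
    e = np.exp(-4.0 / 3.0 * max(t, 0.0))
    P = np.full((4, 4), 0.25 * (1.0 - e))
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def _leaf_conditionals(codes_row: np.ndarray) -> np.ndarray:
    L = codes_row.shape[0]
    cond = np.ones((L, 4))
    known = codes_row < 4
    cond[known] = 0.0
    cond[np.flatnonzero(known), codes_row[known]] = 1.0
    return cond


def tree_log_likelihood(tree: PhyloTree, aln: GeneAlignment) -> float:
    """Log-likelihood of the alignment on the tree under Jukes–Cantor.

    Uniform base frequencies; gap/N/? cells contribute an all-ones
    conditional vector.  Works for rooted and unrooted (basal polytomy)
    trees alike — JC is reversible, so the root placement is immaterial.
    """
    if aln.length == 0:
        raise ValueError("zero-length alignment")
    row_of = {t: i for i, t in enumerate(aln.taxa)}
    missing = [n.name for n in tree.leaves() if n.name not in row_of]
    if missing:
        raise ValueError(f"taxa missing from alignment: {missing}")

    log_scale = np.zeros(aln.length)
    cond: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = _leaf_conditionals(aln.codes[row_of[node.name]])
        else:
            c = np.ones((aln.length, 4))
            for child in node.children:
                P = _jc_transition(child.length or 0.0)
                c *= cond.pop(id(child)) @ P.T
            top = c.max(axis=1)
            top[top == 0] = 1.0
            c /= top[:, None]
            log_scale += np.log(top)
        cond[id(node)] = c
    site = cond[id(tree.root)] @ np.full(4, 0.25)
    with np.errstate(divide="ignore"):  # impossible sites legitimately -> -inf
        return float(np.sum(np.log(site) + log_scale))


def optimize_branch_lengths(tree: PhyloTree, aln: GeneAlignment, sweeps: int = 2) -> float:
    """In-place coordinate-wise Brent optimization of every branch length."""
    ll = tree_log_likelihood(tree, aln)
    for _ in range(max(sweeps, 1)):
        for node in tree.postorder():
            if node is tree.root:
                continue

            def neg(t: float, node=node) -> float:
                node.length = t
                return -tree_log_likelihood(tree, aln)

            res = minimize_scalar(neg, bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
                                  options={"xatol": 1e-6})
            node.length = float(res.x)
        new_ll = tree_log_likelihood(tree, aln)
        if new_ll - ll < 1e-8:
            ll = new_ll
            break
        ll = new_ll
    return ll


# ---------------------------------------------------------------------------
# NNI hill climbing
# ---------------------------------------------------------------------------


def _unrooted_canonical(tree: PhyloTree) -> PhyloTree:
    """Re-express a binary rooted tree as rooted at a basal trifurcation."""
    work = tree.copy()
    root = work.root
    if len(root.children) != 2:
        return work
    a, b = root.children
    keep, move = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        return work  # two-leaf tree: nothing to do
    move.length = (move.length or 0.0) + (keep.length or 0.0)
    keep.length = None
    keep.parent = None
    keep.add_child(move)
    return PhyloTree(keep)


def _nni_candidates(tree: PhyloTree):
    """Yield (edge_key, candidate_tree) for both NNI moves on each internal edge.

    Candidates are produced in a deterministic order keyed by the sorted leaf
    set below the edge's child node.
    """
    base = _unrooted_canonical(tree)
    below: dict[Node, frozenset[str]] = {}
    edges = []
    for node in base.postorder():
        below[node] = (
            frozenset([node.name]) if node.is_leaf
            else frozenset().union(*(below[c] for c in node.children))
        )
        if not node.is_leaf and node.parent is not None:
            edges.append(tuple(sorted(below[node])))
    for edge_key in sorted(edges):
        v_set = frozenset(edge_key)
        # root the tree at the parent side of the edge, then swap subtrees
        rerooted = _reroot_parent_of(base, v_set)
        if rerooted is None:
            continue
        root = rerooted.root
        v = next(c for c in root.children if _leafset(c) == v_set)
        siblings = sorted((c for c in root.children if c is not v),
                          key=lambda c: min(_leafset(c)))
        s = siblings[0]
        for swap_idx in (0, 1):
            cand = rerooted.copy()
            croot = cand.root
            cv = next(c for c in croot.children if _leafset(c) == v_set)
            cs = next(c for c in croot.children if _leafset(c) == _leafset(s))
            child = sorted(cv.children, key=lambda c: min(_leafset(c)))[swap_idx]
            # swap `child` (under cv) with sibling subtree `cs` (under root)
            cv.children[cv.children.index(child)] = cs
            cs.parent = cv
            croot.children[croot.children.index(cs)] = child
            child.parent = croot
            yield edge_key, cand


def _leafset(node: Node) -> frozenset[str]:
    if node.is_leaf:
        return frozenset([node.name])
    return frozenset().union(*(_leafset(c) for c in node.children))


def _reroot_parent_of(base: PhyloTree, v_set: frozenset[str]) -> PhyloTree | None:
    from .tree import _adjacency, _build_rooted

    work = base.copy()
    below: dict[Node, frozenset[str]] = {}
    parent = None
    for node in work.postorder():
        below[node] = (
            frozenset([node.name]) if node.is_leaf
            else frozenset().union(*(below[c] for c in node.children))
        )
        if not node.is_leaf and below[node] == v_set and node.parent is not None:
            parent = node.parent
    if parent is None:
        return None
    adj = _adjacency(work)
    return _build_rooted(adj, parent, {})


def nni_ml_search(start: PhyloTree, aln: GeneAlignment, max_rounds: int = 20) -> PhyloTree:
    """Greedy NNI hill climbing under the JC likelihood.

    Each round scans all NNI neighbors in deterministic order, re-optimizes
    branch lengths of a candidate, and accepts the first move improving the
    log-likelihood by more than 1e-6; stops when a full scan yields no
    improvement or after `max_rounds` rounds.  With max_rounds=0 only the
    branch lengths of the start tree are optimized.
    """
    tree = start.copy()
    current = optimize_branch_lengths(tree, aln)
    for _ in range(max_rounds):
        improved = False
        for _key, cand in _nni_candidates(tree):
            ll = optimize_branch_lengths(cand, aln, sweeps=1)
            if ll > current + 1e-6:
                tree, current = cand, ll
                improved = True
                break
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# engine front door
# ---------------------------------------------------------------------------

ENGINES = ("nj", "ml-nni")


def infer_tree(aln: GeneAlignment, engine: str = "nj", max_distance: float = 5.0,
               max_rounds: int = 20) -> PhyloTree:
    """Infer a tree from an alignment with a built-in engine."""
    if engine == "nj":
        return neighbor_joining(jc_distance_matrix(aln, max_distance=max_distance))
    if engine == "ml-nni":
        start = neighbor_joining(jc_distance_matrix(aln, max_distance=max_distance))
        return nni_ml_search(start, aln, max_rounds=max_rounds)
    raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
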