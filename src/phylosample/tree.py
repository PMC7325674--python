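"""Phylogenetic tree container and newick I/O.

Trees are node-linked structures over uniquely labelled leaves with
non-negative branch lengths in substitutions/site.  A tree whose root has
two children is treated as rooted; a basal polytomy (three or more
children at the root) is the usual representation of an unrooted tree.
"""

from __future__ import annotations

from typing import Iterable, Iterator


class NewickError(ValueError):
    """Malformed newick text; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class PhyloTree:
    """Rooted or unrooted phylogeny with named leaves and branch lengths."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_names())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf labels")
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.name or 'internal node'}")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree({self.n_leaves()} leaves)"


# ---------------------------------------------------------------------------
# newick parsing / writing
# ---------------------------------------------------------------------------

_TOKEN_ENDERS = set("(),:;")


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree; branch lengths optional.

    Raises :class:`NewickError` with the character offset on malformed input.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty newick string", 0)
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_label() -> str | None:
        nonlocal pos
        if pos < len(s) and s[pos] in ("'", '"'):
            quote = s[pos]
            end = s.find(quote, pos + 1)
            if end < 0:
                raise error("unterminated quoted label")
            label = s[pos + 1 : end]
            pos = end + 1
            return label
        start = pos
        while pos < len(s) and s[pos] not in _TOKEN_ENDERS and not s[pos].isspace():
            pos += 1
        return s[start:pos] if pos > start else None

    def parse_length() -> float | None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos] in "+-eE." or s[pos].isdigit()):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error("invalid branch length") from None
        return None

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                if pos >= len(s):
                    raise error("unexpected end of input inside clade")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"expected ',' or ')', found {s[pos]!r}")
        node.name = parse_label()
        node.length = parse_length()
        return node

    root = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';'")
    tree = PhyloTree(root)
    tree.validate()
    return tree


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                out += node.name
        if lengths and node.length is not None and node is not tree.root:
            out += ":" + _format_length(node.length)
        return out

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# re-rooting and pruning
# ---------------------------------------------------------------------------


def _adjacency(tree: PhyloTree):
    """Undirected edge map {node: [(neighbor, length), ...]} of a node-linked tree."""
    adj: dict[Node, list[tuple[Node, float]]] = {}
    for node in tree.postorder():
        adj.setdefault(node, [])
        if node.parent is not None:
            length = node.length if node.length is not None else 0.0
            adj[node].append((node.parent, length))
            adj.setdefault(node.parent, []).append((node, length))
    return adj


def _build_rooted(adj, root: Node, length_of: dict[Node, float | None]) -> PhyloTree:
    """Rebuild a Node tree from adjacency, rooted at `root` (a fresh Node map)."""
    new_nodes: dict[Node, Node] = {}

    def build(old: Node, parent_old: Node | None, length: float | None) -> Node:
        new = Node(old.name if old.is_leaf or old.name else None, length)
        new_nodes[old] = new
        for nbr, edge_len in adj[old]:
            if nbr is parent_old:
                continue
            new.add_child(build(nbr, old, edge_len))
        return new

    return PhyloTree(build(root, None, None))


def _suppress_unary(tree: PhyloTree) -> PhyloTree:
    """Remove degree-2 internal nodes, summing the two branch lengths."""

    def simplify(node: Node) -> Node:
        node.children = [simplify(c) for c in node.children]
        for i, child in enumerate(node.children):
            if len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                node.children[i] = grand
                grand.parent = node
        return node

    root = simplify(tree.root)
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return PhyloTree(root)


def root_at_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root on the edge separating `outgroup` from the remaining taxa.

    The outgroup must be monophyletic in the unrooted sense (some edge of the
    tree must split it exactly from the ingroup); the subtended branch length
    is split equally between the two sides of the new root.
    """
    og = frozenset(outgroup)
    all_taxa = tree.leaf_set()
    if not og:
        raise ValueError("empty outgroup")
    missing = og - all_taxa
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")
    if og == all_taxa:
        raise ValueError("outgroup contains every leaf")

    work = tree.copy()
    below: dict[Node, frozenset[str]] = {}
    target: Node | None = None
    for node in work.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.name])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is not None and (below[node] == og or below[node] == all_taxa - og):
            # prefer the edge whose below-set IS the outgroup; either side of
            # the same split works, keep the first found
            target = node if below[node] == og or target is None else target
    if target is None:
        raise ValueError("outgroup is not monophyletic (no edge splits it from the ingroup)")

    parent = target.parent
    edge_len = target.length if target.length is not None else 0.0
    adj = _adjacency(work)
    # sever target--parent, insert the new root midway
    adj[target] = [(n, l) for n, l in adj[target] if n is not parent]
    adj[parent] = [(n, l) for n, l in adj[parent] if n is not target]
    new_root = Node()
    adj[new_root] = [(target, edge_len / 2.0), (parent, edge_len / 2.0)]
    adj[target].append((new_root, edge_len / 2.0))
    adj[parent].append((new_root, edge_len / 2.0))

    rooted = _build_rooted(adj, new_root, {})
    rooted = _suppress_unary(rooted)
    rooted.validate()
    return rooted


def prune_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Restrict the tree to `taxa`, suppressing unary nodes and summing lengths."""
    keep = frozenset(taxa)
    present = tree.leaf_set()
    if not keep <= present:
        raise ValueError(f"taxa absent from tree: {sorted(keep - present)}")
    work = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.name in keep else None
        node.children = [c for c in (prune(c) for c in node.children) if c is not None]
        for c in node.children:
            c.parent = node
        return node if node.children else None

    root = prune(work.root)
    if root is None:
        raise ValueError("no taxa left after pruning")
    return _suppress_unary(PhyloTree(root))
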