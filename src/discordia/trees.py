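"""Light-weight phylogenetic trees for five-taxon genome scans.

Trees are small here (five tips), so we use a minimal :class:`Clade`
container plus an explicit enumeration of the 15 unrooted five-taxon
topologies instead of a general tree library.  Every unrooted binary tree
on five tips has the same shape: two cherries joined through a central
internal node that also carries the fifth tip.  A topology is therefore
identified by an unordered pair of disjoint tip pairs ("cherry pairs"),
which makes enumeration, indexing and hashing trivial.
"""

from __future__ import annotations

from typing import Iterable, Sequence

DEFAULT_TAXA = ("YP", "H1706", "GAL", "PIM", "TUB")
OUTGROUP = "TUB"


class Clade:
    """A rooted (sub)tree node with an optional label and branch length.

    ``length`` is the length of the branch leading to this node, in
    expected substitutions per site (or generations, for time trees —
    callers keep track of units).
    """

    __slots__ = ("label", "length", "children")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 children: list["Clade"] | None = None):
        self.label = label
        self.length = float(length)
        self.children = list(children) if children else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out: list[Clade] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal (non-root, non-leaf) node and the root."""
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                out.append(n.leaf_names())
                stack.extend(n.children)
        return out

    def total_length(self) -> float:
        tot = 0.0
        stack = list(self.children)
        while stack:
            n = stack.pop()
            tot += n.length
            stack.extend(n.children)
        return tot

    def copy(self) -> "Clade":
        return Clade(self.label, self.length, [c.copy() for c in self.children])

    def newick(self, lengths: bool = True) -> str:
        return _newick(self, lengths) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clade({self.newick()})"


def _newick(node: Clade, lengths: bool) -> str:
    if node.is_leaf:
        s = node.label or ""
    else:
        s = "(" + ",".join(_newick(c, lengths) for c in node.children) + ")"
        if node.label:
            s += node.label
    if lengths:
        s += f":{node.length:.10g}"
    return s


def parse_newick(text: str) -> Clade:
    """Parse a newick string (names, branch lengths; no comments/quoting)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Clade:
        nonlocal pos
        node = Clade()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if s[pos] != ")":
                raise ValueError(f"unbalanced newick at position {pos}")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            node.label = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick string")
    return root


def tree_from_tuples(spec, length: float = 0.0) -> Clade:
    """Build a Clade from nested tuples of tip labels, e.g. ``(("YP","H1706"),"GAL")``."""
    if isinstance(spec, str):
        return Clade(spec, length)
    return Clade(None, length, [tree_from_tuples(c, length) for c in spec])


# ---------------------------------------------------------------------------
# Unrooted 5-taxon topologies


def enumerate_topologies(taxa: Sequence[str] = DEFAULT_TAXA) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """All 15 unrooted binary topologies on five tips.

    Each topology is a canonical pair of disjoint cherry pairs; the fifth
    taxon sits on the central node.  Order is deterministic in the given
    taxon order, with the pair containing the first taxon listed first.
    """
    if len(set(taxa)) != 5:
        raise ValueError("exactly five distinct taxa required")
    idx = {t: i for i, t in enumerate(taxa)}
    out = []
    seen = set()
    for i in range(5):
        for j in range(i + 1, 5):
            rest = [t for t in taxa if t not in (taxa[i], taxa[j])]
            for k in range(3):
                for l in range(k + 1, 3):
                    p1 = tuple(sorted((taxa[i], taxa[j]), key=idx.get))
                    p2 = tuple(sorted((rest[k], rest[l]), key=idx.get))
                    key = frozenset((p1, p2))
                    if key in seen:
                        continue
                    seen.add(key)
                    pair = tuple(sorted((p1, p2), key=lambda p: idx[p[0]]))
                    out.append(pair)
    assert len(out) == 15
    return out


def topology_of_tree(tree: Clade, taxa: Sequence[str] | None = None
                     ) -> tuple[tuple[str, str], tuple[str, str]]:
    """Canonical unrooted topology of any binary tree on five tips."""
    names = tree.leaf_names()
    if taxa is None:
        taxa = DEFAULT_TAXA if names == frozenset(DEFAULT_TAXA) else sorted(names)
    if len(names) != 5 or set(taxa) != set(names):
        raise ValueError("five-tip tree required")
    full = frozenset(taxa)
    pairs = set()
    for cl in tree.clades():
        side = cl if len(cl) <= 2 else full - cl
        if len(side) == 2:
            pairs.add(tuple(sorted(side)))
    # The root of a rooted binary 5-taxon tree induces a redundant split; the
    # two cherry pairs of the unrooted shape are the disjoint ones.
    pairs = sorted(pairs)
    for a in pairs:
        for b in pairs:
            if a < b and not set(a) & set(b):
                return _canonical_pair(a, b, taxa)
    raise ValueError("tree is not a binary five-taxon tree")


def _canonical_pair(p1, p2, taxa):
    idx = {t: i for i, t in enumerate(taxa)}
    p1 = tuple(sorted(p1, key=idx.get))
    p2 = tuple(sorted(p2, key=idx.get))
    return tuple(sorted((p1, p2), key=lambda p: idx[p[0]]))


def center_taxon(pairs, taxa: Iterable[str]) -> str:
    """The tip attached to the central node of an unrooted topology."""
    used = set(pairs[0]) | set(pairs[1])
    (w,) = [t for t in taxa if t not in used]
    return w


def topology_tree(pairs, taxa: Sequence[str] = DEFAULT_TAXA,
                  branch_lengths: Sequence[float] | None = None) -> Clade:
    """Materialize an unrooted topology as a Clade rooted at the central node.

    Branch length order: the four cherry tips (pair 1 then pair 2, in
    canonical order), the central tip, then the two internal edges
    (pair-1 stem, pair-2 stem).
    """
    (x, y), (u, v) = pairs
    w = center_taxon(pairs, taxa)
    b = list(branch_lengths) if branch_lengths is not None else [0.0] * 7
    n1 = Clade(None, b[5], [Clade(x, b[0]), Clade(y, b[1])])
    n2 = Clade(None, b[6], [Clade(u, b[2]), Clade(v, b[3])])
    return Clade(None, 0.0, [n1, n2, Clade(w, b[4])])


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: Clade, outgroup: str = OUTGROUP) -> Clade:
    """Root on the outgroup's pendant edge and return the ingroup subtree.

    The root is placed at the node where the outgroup branch attaches, so
    all branch lengths of the ingroup are preserved exactly.
    """
    names = tree.leaf_names()
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not present in tree")
    nodes, edges = _adjacency(tree)
    og = next(i for i, n in enumerate(nodes) if n.is_leaf and n.label == outgroup)
    (attach,) = [j for j in edges[og]]
    sub = _build_rooted(attach, og, nodes, edges)
    if len(sub.children) == 1:
        sub = sub.children[0]
    sub.length = 0.0
    return sub


def _adjacency(tree: Clade):
    """Undirected adjacency (node index -> {neighbor: edge length})."""
    nodes: list[Clade] = []
    edges: list[dict[int, float]] = []

    def visit(n: Clade) -> int:
        i = len(nodes)
        nodes.append(n)
        edges.append({})
        for c in n.children:
            j = visit(c)
            edges[i][j] = c.length
            edges[j][i] = c.length
        return i

    visit(tree)
    # suppress a degree-2 root (rooted input): merge its two edges
    if len(edges[0]) == 2:
        (a, la), (b, lb) = edges[0].items()
        del edges[a][0], edges[b][0]
        edges[a][b] = la + lb
        edges[b][a] = la + lb
        edges[0] = {}
    return nodes, edges


def _build_rooted(i: int, parent: int, nodes, edges) -> Clade:
    n = nodes[i]
    node = Clade(n.label if n.is_leaf else None)
    for j, length in edges[i].items():
        if j == parent:
            continue
        child = _build_rooted(j, i, nodes, edges)
        child.length = length
        node.children.append(child)
    return node
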