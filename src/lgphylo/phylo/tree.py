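"""Minimal rooted-representation tree for unrooted ML inference.

Trees are stored with an arbitrary internal root (a trifurcation for a fully
unrooted binary tree); the likelihood of a reversible model is invariant to
this choice.  Newick parsing goes through dendropy; writing is native.
"""

from __future__ import annotations

import dendropy


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add(self, child: "Node"):
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

        def conv(dn) -> Node:
            node = Node(
                name=dn.taxon.label if dn.taxon else None,
                length=dn.edge.length if dn.edge.length is not None else 0.0,
            )
            if dn.label is not None and dn.taxon is None:
                try:
                    node.support = float(dn.label)
                except ValueError:
                    node.name = dn.label if dn.is_leaf() else node.name
            for c in dn.child_nodes():
                node.add(conv(c))
            return node

        root = conv(dt.seed_node)
        root.length = 0.0
        return cls(root)

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root))

    # -- traversal --------------------------------------------------------

    def postorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out[::-1]

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def taxa(self) -> list[str]:
        return sorted(n.name for n in self.leaves())

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"taxon {name!r} not in tree")

    # -- shape edits ------------------------------------------------------

    def suppress_unifurcations(self):
        changed = True
        while changed:
            changed = False
            for n in self.postorder():
                if not n.is_leaf and len(n.children) == 1 and n.parent is not None:
                    child = n.children[0]
                    child.length += n.length
                    sibs = n.parent.children
                    sibs[sibs.index(n)] = child
                    child.parent = n.parent
                    changed = True
        while len(self.root.children) == 1 and not self.root.children[0].is_leaf:
            old = self.root
            self.root = old.children[0]
            self.root.parent = None
            self.root.length = 0.0

    def unroot(self):
        """Collapse a degree-2 root into a trifurcation."""
        if len(self.root.children) == 2:
            a, b = self.root.children
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                return  # two-taxon tree stays rooted
            move.length += keep.length
            keep.length = 0.0
            self.root.children = list(keep.children) + [move]
            for c in self.root.children:
                c.parent = self.root
            self.root.name = keep.name

    def root_with_outgroup(self, outgroup: str) -> "Tree":
        """New tree rooted on the outgroup's pendant edge (split in half)."""
        t = self.copy()
        leaf = t.find_leaf(outgroup)
        if leaf.parent is t.root and len(t.root.children) == 2:
            return t
        u = leaf.parent
        u.children.remove(leaf)
        # reverse parent pointers along the path u -> old root
        path = []
        n = u
        while n is not None:
            path.append(n)
            n = n.parent
        lengths = [n.length for n in path]
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        for i in range(len(path) - 1):
            path[i].add(path[i + 1])
            path[i + 1].length = lengths[i]
        u.parent = None
        half = leaf.length / 2.0
        new_root = Node(None, 0.0)
        leaf.length = half
        u.length = half
        new_root.add(leaf)
        new_root.add(u)
        t2 = Tree(new_root)
        t2.suppress_unifurcations()
        return t2

    # -- bipartitions -----------------------------------------------------

    def leaf_sets(self) -> dict[int, frozenset]:
        """Postorder-index -> frozenset of leaf names below each node."""
        nodes = self.postorder()
        sets: dict[int, frozenset] = {}
        memo: dict[int, frozenset] = {}
        for i, n in enumerate(nodes):
            if n.is_leaf:
                memo[id(n)] = frozenset([n.name])
            else:
                memo[id(n)] = frozenset().union(*(memo[id(c)] for c in n.children))
            sets[i] = memo[id(n)]
        return sets

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the smaller-or-lexes side set."""
        all_taxa = frozenset(self.taxa())
        out = set()
        for i, s in self.leaf_sets().items():
            if 1 < len(s) < len(all_taxa) - 1:
                comp = all_taxa - s
                out.add(min((s, comp), key=lambda x: (len(x), sorted(x))))
        return out

    def has_clade(self, taxa: frozenset) -> bool:
        """Does some edge split exactly these taxa from the rest?"""
        all_taxa = frozenset(self.taxa())
        if len(taxa) <= 1 or taxa == all_taxa:
            return True
        for s in self.leaf_sets().values():
            if s == taxa or (all_taxa - s) == taxa:
                return True
        return False

    def is_compatible(self, clades) -> bool:
        sets = set(self.leaf_sets().values())
        all_taxa = frozenset(self.taxa())
        for c in clades:
            c = frozenset(c)
            if len(c) <= 1 or c == all_taxa:
                continue
            if c not in sets and (all_taxa - c) not in sets:
                return False
        return True

    # -- newick -----------------------------------------------------------

    def to_newick(self, lengths: bool = True, supports: bool = False,
                  min_support: float | None = None) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if supports and n.support is not None and (
                    min_support is None or n.support >= min_support
                ):
                    s += f"{n.support:g}"
            if lengths and n.parent is not None:
                s += f":{n.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def __repr__(self):
        return f"Tree({self.to_newick(lengths=False)})"


# --------------------------------------------------------------------------
# NNI machinery
# --------------------------------------------------------------------------


def internal_edges(tree: Tree) -> list[int]:
    """Postorder indices of nodes whose parent edge is internal."""
    nodes = tree.postorder()
    out = []
    for i, v in enumerate(nodes):
        if v.parent is None or v.is_leaf:
            continue
        u = v.parent
        # the parent must offer at least one sibling subtree to swap with
        if len(u.children) >= 2:
            out.append(i)
    return out


def nni_candidates(tree: Tree, edge_index: int) -> list[tuple[int, int]]:
    """The two NNI swaps around an internal edge.

    Returned as (sibling_child_index_in_parent, child_index_in_v).
    """
    nodes = tree.postorder()
    v = nodes[edge_index]
    u = v.parent
    sib_idx = next(k for k, c in enumerate(u.children) if c is not v)
    return [(sib_idx, 0), (sib_idx, 1)]


def apply_nni(tree: Tree, edge_index: int, swap: tuple[int, int]) -> Tree:
    """Return a new tree with one NNI applied around the given edge."""
    t = tree.copy()
    nodes = t.postorder()
    v = nodes[edge_index]
    u = v.parent
    sib_idx, child_idx = swap
    b = u.children[sib_idx]
    c = v.children[child_idx]
    u.children[sib_idx] = c
    c.parent = u
    v.children[child_idx] = b
    b.parent = v
    return t
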