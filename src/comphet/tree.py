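"""Phylogenetic tree structure with per-node composition attachments.

Trees are stored rooted (the root is usually a trifurcation, so the shape
corresponds to an unrooted topology); every non-root node carries the
length of the branch leading into it.  Composition vectors live in
``Tree.comp_vectors`` and nodes point into that list via ``Node.comp``:

* CV1 — one shared vector, every node points at index 0;
* NDCH-k — k shared vectors, node assignment sampled;
* NDCH2 — one vector per node (``comp`` indices are distinct).

The branch into node ``v`` evolves under the rate matrix built from ``v``'s
composition; the root's vector is the state distribution at the root.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

CV1 = "cv1"
NDCH = "ndch"
NDCH2 = "ndch2"


class Node:
    __slots__ = ("name", "length", "children", "parent", "comp")

    def __init__(self, name=None, length=None, comp=0):
        self.name = name
        self.length = length
        self.children: list = []
        self.parent = None
        self.comp = comp

    def add_child(self, child: "Node"):
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or 'internal'}>"


class Tree:
    """Rooted tree over named leaves with composition-vector attachments."""

    def __init__(self, root: Node, comp_mode: str = CV1, comp_vectors=None):
        self.root = root
        self.comp_mode = comp_mode
        self.comp_vectors = list(comp_vectors) if comp_vectors is not None else []

    # -- traversal ------------------------------------------------------
    def postorder(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def nodes(self) -> list:
        return self.postorder()

    def leaves(self) -> list:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list:
        return [n.name for n in self.leaves()]

    def internal_nodes(self, exclude_root=False) -> list:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(name)

    # -- copy -----------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(node):
            c = Node(node.name, node.length, node.comp)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return Tree(clone(self.root), self.comp_mode,
                    [np.array(v, dtype=float) for v in self.comp_vectors])

    # -- splits ---------------------------------------------------------
    def splits(self, taxa=None) -> frozenset:
        """Nontrivial unrooted splits as canonical frozensets of leaf names.

        The canonical side of a split is the one NOT containing the
        reference taxon (first of ``taxa`` or the alphabetically first
        leaf), so identical splits compare equal across rootings.
        """
        names = sorted(self.leaf_names()) if taxa is None else list(taxa)
        ref = names[0]
        full = frozenset(names)
        out = set()
        below: dict = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
        for node in self.postorder():
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = full - side
            if 2 <= len(side) <= len(names) - 2:
                out.add(side)
        return frozenset(out)

    # -- newick ---------------------------------------------------------
    def newick(self, support=None, precision=6) -> str:
        """Newick string; ``support`` maps canonical splits to a label."""
        names = sorted(self.leaf_names())
        ref = names[0]
        full = frozenset(names)

        def fmt(node):
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if support is not None and node is not self.root:
                    side = frozenset(n.name for n in _leaves_under(node))
                    if ref in side:
                        side = full - side
                    if side in support:
                        label = f"{support[side]:.4g}"
                s = f"({inner}){label}"
            if node.length is not None and node is not self.root:
                s += f":{node.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    # -- surgery ---------------------------------------------------------
    def prune_leaf(self, name: str) -> "Tree":
        """Return a copy with the named leaf removed (degree-2 nodes sutured)."""
        t = self.copy()
        leaf = t.find_leaf(name)
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(leaf)
        while parent is not None and len(parent.children) == 1 and parent is not t.root:
            child = parent.children[0]
            child.length = (child.length or 0.0) + (parent.length or 0.0)
            grand = parent.parent
            grand.children[grand.children.index(parent)] = child
            child.parent = grand
            parent = grand
        if parent is t.root and len(t.root.children) == 1:
            t.root = t.root.children[0]
            t.root.parent = None
            t.root.length = None
        return t


def _leaves_under(node: Node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def random_topology(taxa, rng, branch_length=0.1) -> Tree:
    """Uniform-ish random unrooted binary topology (trifurcating root) built
    by sequential random attachment."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    order = list(taxa)
    rng.shuffle(order)
    root = Node()
    for name in order[:3]:
        root.add_child(Node(name, branch_length))
    tree = Tree(root)
    for name in order[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[rng.integers(len(edges))]
        attach_on_edge(tree, target, Node(name, branch_length), branch_length)
    return tree


def attach_on_edge(tree: Tree, target: Node, new_leaf: Node, branch_length=0.1):
    """Insert ``new_leaf`` in the middle of the branch leading into ``target``."""
    parent = target.parent
    mid = Node(length=(target.length or branch_length) / 2.0)
    target.length = (target.length or branch_length) / 2.0
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add_child(target)
    mid.add_child(new_leaf)
    new_leaf.length = new_leaf.length or branch_length
    return mid


def build_from_splits(taxa, split_freqs: dict) -> tuple:
    """Build the majority-rule tree from compatible canonical splits.

    ``split_freqs`` maps canonical split sides (frozensets excluding the
    reference taxon) to frequencies; the sides must form a laminar family.
    Returns ``(Tree, support)`` where support maps splits to frequency.
    """
    taxa = sorted(taxa)
    sides = sorted(split_freqs, key=len, reverse=True)
    root = Node()
    node_for: dict = {}
    # parent of a side = the smallest strict superset (or the root)
    for side in sides:
        node_for[side] = Node()
    for side in sides:
        best = None
        for other in sides:
            if other is not side and side < other:
                if best is None or len(other) < len(best):
                    best = other
        parent = node_for[best] if best is not None else root
        parent.add_child(node_for[side])
        node_for[side].length = 1.0
    for taxon in taxa:
        best = None
        for side in sides:
            if taxon in side and (best is None or len(side) < len(best)):
                best = side
        parent = node_for[best] if best is not None else root
        parent.add_child(Node(taxon, 1.0))
    tree = Tree(root)
    return tree, dict(split_freqs)


# ---------------------------------------------------------------------------
# newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True)
    return _from_dendropy(dtree)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_list(path) -> list:
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    return [_from_dendropy(t) for t in trees]


def _from_dendropy(dtree) -> Tree:
    def convert(dnode):
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(name=name, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return Tree(root)


def write_newick(tree: Tree, path, support=None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(support=support) + "\n")


def same_unrooted_topology(a: Tree, b: Tree) -> bool:
    return a.splits() == b.splits()
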