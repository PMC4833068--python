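"""Phylogenetic tree data model, newick I/O, and generic tree surgery.

Trees are stored rooted.  An unrooted tree is represented as a rooted tree
with ``rooted=False``; operations documented as unrooted-safe first collapse
a degree-2 root so their result cannot depend on where the arbitrary root
was placed.

Branch lengths are in expected substitutions per site; supports are bootstrap
percentages in [0, 100] stored on internal nodes (interpreted as a property
of the edge above the node).
"""

from __future__ import annotations

import random
from typing import Callable, Iterable, Iterator

import dendropy


class NewickError(ValueError):
    """Raised for malformed newick input (names the offending token)."""


class Node:
    """One node of a :class:`PhyloTree`.

    ``length`` is the length of the edge above this node (``None`` at the
    root or when unknown); ``support`` is the bootstrap percentage of that
    edge; ``label`` is the tip name (tips only).
    """

    __slots__ = ("parent", "children", "length", "support", "label")

    def __init__(self, label=None, length=None, support=None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length: float | None = length
        self.support: float | None = support
        self.label: str | None = label

    # -- structure ---------------------------------------------------------
    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def iter_preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator["Node"]:
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list["Node"]:
        return [n for n in self.iter_preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def __repr__(self):  # pragma: no cover - debugging aid
        if self.is_tip:
            return f"<tip {self.label!r}>"
        return f"<node {len(self.tips())} tips>"


class PhyloTree:
    """A rooted (or arbitrarily rooted unrooted) phylogenetic tree."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._check_unique_tips()

    def _check_unique_tips(self):
        seen = set()
        for lab in self.root.tip_labels():
            if lab is None:
                continue  # childless internal stub, cleaned up by suppression
            if lab in seen:
                raise NewickError(f"duplicate tip label: {lab!r}")
            seen.add(lab)

    # -- basic queries -----------------------------------------------------
    def tips(self) -> list[Node]:
        return self.root.tips()

    def tip_labels(self) -> list[str]:
        return self.root.tip_labels()

    def nodes(self) -> list[Node]:
        return list(self.root.iter_preorder())

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.root.iter_preorder() if not n.is_tip]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.iter_preorder()
                   if n is not self.root)

    def find_tip(self, label: str) -> Node:
        for n in self.tips():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    def has_node(self, node: Node) -> bool:
        n = node
        while n.parent is not None:
            n = n.parent
        return n is self.root

    # -- copying -----------------------------------------------------------
    def copy(self, with_map: bool = False):
        mapping: dict[int, Node] = {}

        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            mapping[id(node)] = new
            for c in node.children:
                new.add_child(_copy(c))
            return new

        new_tree = PhyloTree(_copy(self.root), rooted=self.rooted)
        if with_map:
            return new_tree, mapping
        return new_tree

    # -- surgery -----------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Remove nodes with a single child, merging branch lengths additively.

        Also removes childless internal nodes left by tip pruning.  The root
        is replaced by its single child (the child keeps no stem length).
        """
        changed = True
        while changed:
            changed = False
            for node in list(self.root.iter_postorder()):
                if node.is_tip and node.label is None and node is not self.root:
                    node.parent.remove_child(node)  # dead internal stub
                    changed = True
                elif len(node.children) == 1 and node is not self.root:
                    (child,) = node.children
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    # support of the merged edge: keep the child's if present
                    if child.support is None:
                        child.support = node.support
                    changed = True
            while len(self.root.children) == 1 and not self.root.is_tip:
                self.root = self.root.children[0]
                self.root.parent = None
                self.root.length = None
                changed = True

    def collapse_root_edge(self) -> None:
        """Merge the two root-adjacent edges of a bifurcating root.

        Makes edge-based operations independent of where an arbitrary root
        split a single underlying edge: the root becomes trifurcating (or the
        tree a cherry stays as-is if both children are tips).
        """
        if len(self.root.children) != 2:
            return
        a, b = self.root.children
        target = b if not b.is_tip else (a if not a.is_tip else None)
        if target is None:
            return
        other = a if target is b else b
        # re-hang: root adopts target's children, other absorbs both edges
        self.root.children = []
        for c in list(target.children):
            target.remove_child(c)
            self.root.add_child(c)
        other.length = (other.length or 0.0) + (target.length or 0.0)
        if other.support is None:
            other.support = target.support
        self.root.add_child(other)
        self.root.support = None

    def prune_tip(self, tip: Node) -> None:
        """Remove one tip and suppress the unary node this creates."""
        if tip is self.root:
            raise ValueError("cannot prune the root")
        tip.parent.remove_child(tip)
        self.suppress_unifurcations()


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _num_or_none(text):
    if text is None or text == "":
        return None
    try:
        return float(text)
    except ValueError:
        return None


def read_newick(text: str, support_in: str = "label") -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Internal-node labels are interpreted as bootstrap support values when
    numeric (``support_in="label"``, the usual ML-tree dialect); pass
    ``support_in="comment"`` for trees that carry supports in square-bracket
    comments instead.  Trees whose top-level node has three or more children
    are flagged unrooted.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=(support_in == "comment"),
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse failure: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            if support_in == "label":
                node.support = _num_or_none(dnode.label)
            else:
                node.support = _num_or_none(
                    dnode.annotations.get_value("support", None))
            for c in dnode.child_nodes():
                node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    tree = PhyloTree(root, rooted=len(root.children) <= 2)
    return tree


def write_newick(tree: PhyloTree, support_as_label: bool = True,
                 fmt: str = "%.6g") -> str:
    """Serialize a tree to newick (supports as internal-node labels)."""

    def render(node: Node) -> str:
        if node.is_tip:
            out = node.label or ""
        else:
            out = "(" + ",".join(render(c) for c in node.children) + ")"
            if support_as_label and node.support is not None:
                sup = node.support
                out += fmt % sup if sup != int(sup) else str(int(sup))
        if node.length is not None:
            out += ":" + fmt % node.length
        return out

    return render(tree.root) + ";"


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# generic operations
# ---------------------------------------------------------------------------

def extract_subtree(tree: PhyloTree, node: Node) -> PhyloTree:
    """Deep copy of the clade rooted at ``node``; stem length kept as root length."""
    if not tree.has_node(node):
        raise ValueError("node not in tree")

    def _copy(n: Node) -> Node:
        new = Node(n.label, n.length, n.support)
        for c in n.children:
            new.add_child(_copy(c))
        return new

    return PhyloTree(_copy(node), rooted=True)


def mrca(tree: PhyloTree, labels: Iterable[str]) -> Node:
    """Most recent common ancestor of a set of tip labels.

    Returns the deepest node whose tip set contains every given label.
    """
    labels = set(labels)
    if not labels:
        raise ValueError("mrca of an empty set")
    tips = {t.label: t for t in tree.tips()}
    missing = labels - tips.keys()
    if missing:
        raise KeyError(f"labels absent from tree: {sorted(missing)}")
    it = iter(labels)
    node = tips[next(it)]
    on_path = set()
    n = node
    while n is not None:
        on_path.add(id(n))
        n = n.parent
    for lab in it:
        n = tips[lab]
        while id(n) not in on_path:
            n = n.parent
        node = n
        # trim on_path to ancestors of the new candidate
        on_path = set()
        m = node
        while m is not None:
            on_path.add(id(m))
            m = m.parent
    return node


def mrca_taxa(tree: PhyloTree, taxa: Iterable[str],
              taxon_of: Callable[[str], str]) -> Node:
    """MRCA of all tips whose taxon (via ``taxon_of``) is in ``taxa``."""
    taxa = set(taxa)
    labels = [t.label for t in tree.tips() if taxon_of(t.label) in taxa]
    if not labels:
        raise KeyError(f"no tips for taxa {sorted(taxa)}")
    return mrca(tree, labels)


def reroot(tree: PhyloTree, node: Node) -> PhyloTree:
    """Return a copy of ``tree`` rerooted so that ``node`` becomes a child
    of the new root, placed on the edge above ``node``.

    The edge above ``node`` is kept intact (its full length becomes the new
    root-to-node edge, the old parent side gets length 0), so total tree
    length is preserved.  Rerooting at the current root returns a plain copy.
    """
    new_tree, mapping = tree.copy(with_map=True)
    target = mapping[id(node)]
    if target is new_tree.root:
        return new_tree

    # reverse parent pointers along the path target -> old root
    path = []
    n = target
    while n is not None:
        path.append(n)
        n = n.parent
    new_root = Node()
    parent = path[1]
    parent.remove_child(target)
    new_root.add_child(target)
    # target keeps its own length/support on the new root edge
    prev = new_root
    prev_len, prev_sup = 0.0, None
    for i in range(1, len(path)):
        n = path[i]
        nxt = path[i + 1] if i + 1 < len(path) else None
        if nxt is not None:
            nxt.remove_child(n)
        length, support = n.length, n.support
        n.length, n.support = prev_len, prev_sup
        prev.add_child(n)
        prev, prev_len, prev_sup = n, length, support
    out = PhyloTree(new_root, rooted=False)
    out.suppress_unifurcations()
    return out


def random_reroot(tree: PhyloTree, rng: random.Random) -> PhyloTree:
    """Reroot on the edge above a uniformly chosen non-root node."""
    candidates = [n for n in tree.nodes() if n.parent is not None]
    return reroot(tree, rng.choice(candidates))
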