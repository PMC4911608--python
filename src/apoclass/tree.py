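"""Rooted reference trees.

The topology is an input fixed by a prior phylogenomic study; this package
never infers or rearranges it.  Newick parsing and outgroup rerooting are
delegated to DendroPy, after which the tree is converted into a light
parent/children structure with integer node ids, cached leaf sets, and the
designated outgroup leaves.  Polytomies are accepted and kept as hard
polytomies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import dendropy


class Node:
    __slots__ = ("id", "label", "name", "parent", "children")

    def __init__(self, id: int, label: Optional[str] = None,
                 name: Optional[str] = None):
        self.id = id
        self.label = label          # leaf taxon label (None for internal)
        self.name = name            # optional clade name on internal nodes
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:
        what = self.label or self.name or "internal"
        return f"Node({self.id}, {what})"


class RootedTree:
    """Fixed reference topology with a designated outgroup leaf set."""

    def __init__(self, root: Node, outgroup: Iterable[str] = ()):
        self.root = root
        self.outgroup = frozenset(outgroup)
        self._reindex()
        unknown = self.outgroup - set(self.leaf_labels)
        if unknown:
            raise ValueError(f"outgroup taxa not in tree: {sorted(unknown)}")

    # -- construction helpers -------------------------------------------------

    def _reindex(self) -> None:
        self.nodes: dict[int, Node] = {}
        self._preorder: list[Node] = []
        counter = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.id = counter
            counter += 1
            self.nodes[node.id] = node
            self._preorder.append(node)
            stack.extend(reversed(node.children))
        labels = [n.label for n in self._preorder if n.is_leaf]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        self.leaf_labels: list[str] = labels
        self._leafsets: dict[int, frozenset[str]] = {}
        for node in reversed(self._preorder):
            if node.is_leaf:
                self._leafsets[node.id] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= self._leafsets[c.id]
                self._leafsets[node.id] = frozenset(acc)

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[Node]:
        return reversed(self._preorder)

    def leaves(self) -> list[Node]:
        return [n for n in self._preorder if n.is_leaf]

    def leafset(self, node: Node) -> frozenset[str]:
        return self._leafsets[node.id]

    def depth(self, node: Node) -> int:
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    @property
    def ingroup_leaves(self) -> list[str]:
        return [t for t in self.leaf_labels if t not in self.outgroup]

    def is_ingroup_node(self, node: Node) -> bool:
        """True when no outgroup taxon is below the node."""
        return not (self._leafsets[node.id] & self.outgroup)

    def mrca(self, taxa: Iterable[str]) -> Node:
        taxa = frozenset(taxa)
        for node in reversed(self._preorder):  # postorder: smallest first
            if taxa <= self._leafsets[node.id]:
                return node
        raise ValueError(f"taxa not in tree: {sorted(taxa)}")

    # -- editing --------------------------------------------------------------

    def prune_to(self, keep: Iterable[str]) -> "RootedTree":
        """Return a copy restricted to ``keep`` leaves, suppressing unifurcations."""
        keep = frozenset(keep)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    return Node(0, label=node.label)
                return None
            kids = [k for k in (build(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = Node(0, name=node.name)
            for k in kids:
                k.parent = new
                new.children.append(k)
            return new

        root = build(self.root)
        if root is None:
            raise ValueError("pruning removed every leaf")
        return RootedTree(root, self.outgroup & keep)

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.label
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.name or ''}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, outgroup: Iterable[str] = ()) -> "RootedTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return _from_dendropy(dt, outgroup)

    def __repr__(self) -> str:
        return f"RootedTree({len(self.leaf_labels)} leaves)"


def _from_dendropy(dt: dendropy.Tree, outgroup: Iterable[str]) -> RootedTree:
    outgroup = frozenset(outgroup)
    labels = {lf.taxon.label for lf in dt.leaf_node_iter()}
    unknown = outgroup - labels
    if unknown:
        raise ValueError(f"outgroup taxa not in tree: {sorted(unknown)}")

    if outgroup and outgroup != labels:
        _reroot_on_outgroup(dt, outgroup)

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(0, label=dnode.taxon.label)
        node = Node(0, name=dnode.label)
        for child in dnode.child_nodes():
            c = convert(child)
            c.parent = node
            node.children.append(c)
        return node

    root = convert(dt.seed_node)
    # a rooting artifact can leave a unifurcate root; collapse it
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
    return RootedTree(root, outgroup)


def _reroot_on_outgroup(dt: dendropy.Tree, outgroup: frozenset[str]) -> None:
    """Root the tree on the stem edge of the outgroup if not already so."""
    for child in dt.seed_node.child_nodes():
        below = {lf.taxon.label for lf in child.leaf_iter()}
        if below == outgroup:
            return  # already separates outgroup from ingroup
    taxa = [t for t in dt.taxon_namespace if t.label in outgroup]
    mrca = dt.mrca(taxa=taxa) if len(taxa) > 1 else dt.find_node_with_taxon_label(
        next(iter(outgroup))
    )
    if mrca is dt.seed_node:
        # outgroup is paraphyletic at the current root; reroot on the
        # complement (the ingroup stem), which realizes the same split
        ingroup = {t for t in (x.label for x in dt.taxon_namespace)} - outgroup
        taxa = [t for t in dt.taxon_namespace if t.label in ingroup]
        mrca = dt.mrca(taxa=taxa)
        if mrca is dt.seed_node:
            raise ValueError("cannot root tree on the requested outgroup")
    dt.reroot_at_edge(mrca.edge, update_bipartitions=False)


def read_tree(
    path: str | Path,
    outgroup: Iterable[str] = (),
    matrix_taxa: Optional[Sequence[str]] = None,
    extra_taxa: str = "prune",
) -> RootedTree:
    """Read a Newick tree, root it on the outgroup stem if needed, and check
    its leaves against the matrix taxa.

    ``extra_taxa`` controls taxa present in the tree but absent from the
    matrix: ``"prune"`` (default) removes them, ``"error"`` raises.  Taxa in
    the matrix but absent from the tree always raise.
    """
    text = Path(path).read_text()
    tree = RootedTree.from_newick(text, outgroup)
    if matrix_taxa is not None:
        matrix_set = set(matrix_taxa)
        tree_set = set(tree.leaf_labels)
        missing_from_tree = sorted(matrix_set - tree_set)
        if missing_from_tree:
            raise ValueError(
                f"matrix taxa absent from tree: {missing_from_tree}"
            )
        extra = sorted(tree_set - matrix_set)
        if extra:
            if extra_taxa == "error":
                raise ValueError(f"tree taxa absent from matrix: {extra}")
            tree = tree.prune_to(matrix_set)
    return tree
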