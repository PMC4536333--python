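"""Rooted phylogenies with branch lengths and foreground branch labels.

Newick text is parsed with dendropy.  Branch-site analyses mark one or more
branches as "foreground" (the lineage tested for positive selection); the
conventional ``#1`` mark is not part of Newick, so marks are extracted before
parsing and re-attached on rendering.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

import dendropy

_FG_TAG = "@@FG@@"
# move a mark that trails a branch length in front of the colon: "x:0.1#1" -> "x#1:0.1"
_MARK_AFTER_LENGTH = re.compile(r":([^,():;#\s]+)\s*#\s*(\d+)")
_MARK = re.compile(r"\s*#\s*\d+")


class TreeNode:
    __slots__ = ("name", "length", "foreground", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        foreground: bool = False,
    ):
        self.name = name
        self.length = length
        self.foreground = foreground
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, length={self.length}, fg={self.foreground})"


class PhyloTree:
    """A rooted tree; leaf labels are species or gene ids and must be unique."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = self.leaf_names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node in root.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length at {node.name!r}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip()
        if not text:
            raise ValueError("empty Newick string")
        if text.count("(") != text.count(")"):
            raise ValueError("unbalanced parentheses in Newick string")
        if not text.endswith(";"):
            text += ";"
        text = _MARK_AFTER_LENGTH.sub(r"#\2:\1", text)
        text = _MARK.sub(_FG_TAG, text)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "Duplicate taxon labels" in str(exc) or "duplicate" in str(exc).lower():
                raise ValueError(f"duplicate leaf labels: {exc}") from exc
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.foreground)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- queries ------------------------------------------------------

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    def mrca(self, names: set[str]) -> TreeNode:
        """Most recent common ancestor of the named leaves."""
        if not names:
            raise ValueError("mrca of empty leaf set")
        node = self.root
        while True:
            covering = [
                c
                for c in node.children
                if names <= {l.name for l in c.leaves()}
            ]
            if not covering:
                return node
            node = covering[0]

    def branches(self) -> list[TreeNode]:
        """Non-root nodes; each represents the branch above it."""
        return [n for n in self.postorder() if n.parent is not None]

    def pruned_to(self, names: set[str]) -> "PhyloTree":
        """Restriction of the tree to a leaf subset.

        Unary internal nodes created by pruning are collapsed, summing
        branch lengths; foreground marks on collapsed paths are preserved
        (a branch is foreground if any merged segment was).
        """
        missing = set(names) - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.name in names:
                    return TreeNode(node.name, node.length, node.foreground)
                return None
            kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                child.foreground = child.foreground or node.foreground
                return child
            new = TreeNode(node.name, node.length, node.foreground)
            for c in kept:
                new.add_child(c)
            return new

        root = prune(self.root)
        if root is None or root.is_leaf:
            raise ValueError("pruning leaves fewer than two taxa")
        root.length = None
        root.foreground = False
        return PhyloTree(root)

    # -- foreground labelling -----------------------------------------

    def set_foreground(self, taxa: str | set[str], clade: bool = False) -> None:
        """Mark the branch above a leaf (or above the MRCA of several leaves).

        With ``clade=True`` every branch inside the clade is marked too.
        """
        names = {taxa} if isinstance(taxa, str) else set(taxa)
        missing = names - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        node = self.find_leaf(next(iter(names))) if len(names) == 1 else self.mrca(names)
        node.foreground = True
        if clade:
            for desc in node.preorder():
                desc.foreground = True

    def clear_foreground(self) -> None:
        for node in self.postorder():
            node.foreground = False

    def foreground_branches(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.foreground]

    # -- rendering ----------------------------------------------------

    def to_newick(self, include_lengths: bool = True, include_marks: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if include_marks and node.foreground:
                s += " #1"
            if include_lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return render(self.root) + ";"

    def write(self, path: str | Path, **kwargs) -> None:
        Path(path).write_text(self.to_newick(**kwargs) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick(include_lengths=False)})"


def _from_dendropy(dnode) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
    else:
        label = dnode.label
    foreground = False
    if label and label.endswith(_FG_TAG):
        label = label[: -len(_FG_TAG)] or None
        foreground = True
    node = TreeNode(name=label, length=dnode.edge.length, foreground=foreground)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def render_newick(tree: PhyloTree, **kwargs) -> str:
    return tree.to_newick(**kwargs)


def species_tree_path() -> Path:
    """Path to the bundled 8-taxon mammal species tree."""
    return Path(__file__).parent / "data" / "species_tree_8taxa.nwk"


def load_species_tree() -> PhyloTree:
    return PhyloTree.from_file(species_tree_path())
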