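"""Rooted host-family phylogenies with branch lengths (Newick / NEXUS input)."""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy

__all__ = ["Phylogeny", "TreeFormatError", "DuplicateTipError", "read_tree"]


class TreeFormatError(ValueError):
    """The tree file could not be parsed."""


class DuplicateTipError(ValueError):
    """Two tips carry the same label."""


class Phylogeny:
    """Rooted tree whose tips are host-family identifiers.

    Branch lengths are non-negative reals in arbitrary units (the tree may be
    non-ultrametric).  Missing branch lengths are replaced by a configurable
    default (0 by default, so diversity sums never silently inflate).
    """

    def __init__(self, tree: dendropy.Tree, missing_length: float = 0.0):
        self._tree = tree
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge carries no information
            if edge.length is None:
                edge.length = missing_length
                n_missing += 1
            elif edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        if n_missing:
            warnings.warn(
                f"{n_missing} branch(es) lacked a length; defaulted to "
                f"{missing_length}",
                stacklevel=2,
            )
        self._leaves: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if label is None:
                raise TreeFormatError("unlabelled tip")
            label = str(label).strip()
            if label in self._leaves:
                raise DuplicateTipError(f"duplicate tip label {label!r}")
            self._leaves[label] = leaf

    @property
    def tip_labels(self) -> set[str]:
        return set(self._leaves)

    @property
    def n_tips(self) -> int:
        return len(self._leaves)

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths."""
        return float(
            sum(
                e.length or 0.0
                for e in self._tree.preorder_edge_iter()
                if e.head_node is not self._tree.seed_node
            )
        )

    def leaf(self, label: str) -> dendropy.Node:
        return self._leaves[label]

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, total_length={self.total_length:g})"


def read_tree(
    path: str | Path, format: str = "newick", missing_length: float = 0.0
) -> Phylogeny:
    """Read a rooted tree from a Newick or NEXUS file.

    Raises :class:`TreeFormatError` on unparseable input and
    :class:`DuplicateTipError` when two tips share a label.
    """
    schema = format.lower()
    if schema not in {"newick", "nexus"}:
        raise ValueError(f"unsupported tree format {format!r}")
    try:
        tree = dendropy.Tree.get(path=str(path), schema=schema)
    except Exception as exc:
        message = str(exc)
        if "Multiple occurrences" in message or "duplicate" in message.lower():
            raise DuplicateTipError(f"{path}: {message}") from exc
        raise TreeFormatError(f"{path}: cannot parse as {schema}: {exc}") from exc
    return Phylogeny(tree, missing_length=missing_length)


def tree_from_string(
    text: str, format: str = "newick", missing_length: float = 0.0
) -> Phylogeny:
    """Parse a tree from an in-memory string (mainly for tests and examples)."""
    try:
        tree = dendropy.Tree.get(data=text, schema=format.lower())
    except Exception as exc:
        raise TreeFormatError(f"cannot parse tree string: {exc}") from exc
    return Phylogeny(tree, missing_length=missing_length)
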