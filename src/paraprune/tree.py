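"""Unrooted support trees.

Wraps :mod:`dendropy` trees and exposes exactly what the screening pipeline
needs: bipartitions of internal edges with their bootstrap supports and
branch lengths, and terminal branch lengths.  Bootstrap supports are read
from internal node labels (the RAxML convention); a second dialect with the
support in a bracketed branch comment (``):0.5[100]``) is accepted behind a
flag.  Supports that are absent stay absent — they are never defaulted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

import dendropy

_COMMENT_SUPPORT = re.compile(r"\)\s*:\s*([0-9eE.+-]+)\s*\[\s*(\d+)\s*\]")


@dataclass(frozen=True)
class InternalEdge:
    """One internal edge, described by one side of its bipartition."""

    side: frozenset[str]
    support: Optional[int]
    length: float


class SupportTree:
    """Unrooted tree with branch lengths and optional integer supports.

    Parameters
    ----------
    tree:
        A dendropy tree.  It is derooted in place; supports must already be
        attached to nodes as the ``support`` attribute (use :meth:`parse`).
    partition_id:
        Stable identifier of the gene partition the tree belongs to.
    """

    def __init__(self, tree: dendropy.Tree, partition_id: str):
        self.partition_id = partition_id
        tree.is_rooted = False
        if len(tree.seed_node.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
            tree.deroot()
        self._tree = tree
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise ValueError(f"tree {partition_id!r}: unlabeled leaf")
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        if len(names) != len(set(names)):
            raise ValueError(f"tree {partition_id!r}: duplicate leaf names")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(
                    f"tree {partition_id!r}: negative branch length {edge.length}"
                )

    # -- construction ---------------------------------------------------

    @classmethod
    def parse(
        cls,
        newick_text: str,
        partition_id: str,
        support_style: str = "node_label",
    ) -> "SupportTree":
        """Parse a newick string into a :class:`SupportTree`.

        ``support_style`` is ``"node_label"`` (internal node labels hold the
        bootstrap percentages) or ``"branch_comment"`` (``):0.5[95]``).
        """
        if support_style == "branch_comment":
            newick_text = _COMMENT_SUPPORT.sub(r")\2:\1", newick_text)
        elif support_style != "node_label":
            raise ValueError(f"unknown support style {support_style!r}")
        try:
            tree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            offset = getattr(exc, "col_num", None)
            raise ValueError(
                f"unparseable newick for partition {partition_id!r}"
                + (f" at character {offset}" if offset is not None else "")
                + f": {exc}"
            ) from exc
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            if label is None or label == "":
                node.support = None
            else:
                try:
                    value = int(label)
                except ValueError as exc:
                    raise ValueError(
                        f"tree {partition_id!r}: internal node label {label!r} "
                        "is not an integer bootstrap support"
                    ) from exc
                if not 0 <= value <= 100:
                    raise ValueError(
                        f"tree {partition_id!r}: support {value} outside [0, 100]"
                    )
                node.support = value
        return cls(tree, partition_id)

    # -- basic queries --------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    def _leafset_below(self, node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def internal_edges(self) -> list[InternalEdge]:
        """All internal edges as (side, support, length) triples.

        The reported ``side`` is the leaf set below the edge's child node;
        the complementary side is ``self.taxa - side``.  The seed edge is
        not an edge of the unrooted tree and is skipped.
        """
        edges = []
        all_taxa = self.taxa
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = self._leafset_below(node)
            if len(side) < 2 or len(all_taxa - side) < 2:
                continue
            length = node.edge.length if node.edge.length is not None else 0.0
            edges.append(InternalEdge(side, getattr(node, "support", None), length))
        return edges

    def terminal_branch_length(self, taxon: str) -> float:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == taxon:
                return leaf.edge.length if leaf.edge.length is not None else 0.0
        raise KeyError(f"taxon {taxon!r} not in tree {self.partition_id!r}")

    def internal_branch_lengths(self) -> list[float]:
        return [e.length for e in self.internal_edges()]

    def find_edge(self, taxa: frozenset[str]) -> InternalEdge:
        """The internal edge whose bipartition is {taxa | complement}."""
        complement = self.taxa - taxa
        for edge in self.internal_edges():
            if edge.side == taxa or edge.side == complement:
                return edge
        raise KeyError(
            f"clade {sorted(taxa)} is not an internal edge of tree "
            f"{self.partition_id!r}"
        )

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Set of unordered bipartitions (each a frozenset of two leaf sets)."""
        out = set()
        for edge in self.internal_edges():
            out.add(frozenset({edge.side, self.taxa - edge.side}))
        return out

    # -- output ---------------------------------------------------------

    def to_newick(self) -> str:
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf():
                support = getattr(node, "support", None)
                node.label = str(support) if support is not None else None
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return text

    def __repr__(self) -> str:  # pragma: no cover
        return f"SupportTree({self.partition_id!r}, {self.n_leaves} leaves)"
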