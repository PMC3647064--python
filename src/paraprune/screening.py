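"""Bootstrap screening of single-gene trees.

Single-gene bootstrap support for deep relationships is usually low, so a
clade with very high support in one gene is suspicious: it may reflect
cross-contamination or a misassigned paralog rather than phylogenetic
signal.  This module extracts every internal edge whose support reaches a
threshold (default 95) and discards candidates whose taxon set falls
entirely inside an a-priori accepted monophyletic group, for which strong
support is expected and uninformative.

Trees are unrooted, so a "clade" is implemented as either side of a
bipartition: both sides of a qualifying edge are emitted, sharing the
edge's support and length.  The a-priori filter and the later assessments
operate per side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .tree import SupportTree
from .types import AprioriGroupSet, FlaggedClade

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT_THRESHOLD = 95

__all__ = [
    "DEFAULT_SUPPORT_THRESHOLD",
    "extract_supported_clades",
    "filter_apriori",
    "screen",
    "ScreenReport",
]


def extract_supported_clades(
    tree: SupportTree, threshold: int = DEFAULT_SUPPORT_THRESHOLD
) -> list[FlaggedClade]:
    """Both sides of every internal edge with support >= ``threshold``.

    Edges with absent support never qualify.  Sides must contain between 2
    and N-2 taxa (both hold automatically for internal edges).  Output is
    deterministic: sorted by partition, then by the lexicographically
    smallest member, then by size.
    """
    if not 0 <= threshold <= 100:
        raise ValueError(f"threshold {threshold} outside [0, 100]")
    if tree.n_leaves < 4:
        logger.info(
            "tree %r has %d leaves, no internal edges", tree.partition_id, tree.n_leaves
        )
        return []
    all_taxa = tree.taxa
    clades = []
    for edge in tree.internal_edges():
        if edge.support is None or edge.support < threshold:
            continue
        for side in (edge.side, all_taxa - edge.side):
            clades.append(
                FlaggedClade(
                    partition_id=tree.partition_id,
                    taxa=side,
                    support=edge.support,
                    leading_branch_length=edge.length,
                )
            )
    clades.sort(key=FlaggedClade.sort_key)
    return clades


def filter_apriori(
    clades: list[FlaggedClade], groups: AprioriGroupSet
) -> list[FlaggedClade]:
    """Drop clades whose taxon set is a subset of an a-priori group.

    All other clades are retained in input order.  The filter is idempotent.
    """
    return [c for c in clades if not groups.covers(c.taxa)]


@dataclass
class ScreenReport:
    """Flagged clades surviving the screen, with bookkeeping counts."""

    clades: list[FlaggedClade]
    per_partition: dict[str, int]
    n_unfiltered: int
    n_filtered: int
    threshold: int = DEFAULT_SUPPORT_THRESHOLD

    def by_partition(self) -> dict[str, list[FlaggedClade]]:
        out: dict[str, list[FlaggedClade]] = {}
        for clade in self.clades:
            out.setdefault(clade.partition_id, []).append(clade)
        return out


def screen(
    trees: list[SupportTree],
    threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    groups: AprioriGroupSet | None = None,
) -> ScreenReport:
    """Extract and a-priori-filter high-support clades over all partitions."""
    if not trees:
        raise ValueError("screen requires at least one tree")
    if groups is None:
        groups = AprioriGroupSet({})
    unfiltered: list[FlaggedClade] = []
    for tree in trees:
        unfiltered.extend(extract_supported_clades(tree, threshold))
    kept = filter_apriori(unfiltered, groups)
    per_partition: dict[str, int] = {}
    for clade in kept:
        per_partition[clade.partition_id] = per_partition.get(clade.partition_id, 0) + 1
    return ScreenReport(
        clades=kept,
        per_partition=per_partition,
        n_unfiltered=len(unfiltered),
        n_filtered=len(kept),
        threshold=threshold,
    )
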