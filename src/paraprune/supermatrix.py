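"""Redundant-partition detection, prune-action application, and
supermatrix concatenation.

Sequence-level pruning removes a taxon's row from a partition; the columns
stay, so the concatenated length is invariant under sequence pruning (the
pruned cells become gaps).  Partition-level exclusion removes the columns.
This matches the bookkeeping convention in which the all-data and the
contamination-pruned matrices have identical lengths, and keeps coordinate
charts stable across dataset variants.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .types import (
    ACTION_EXCLUDE_PARTITION,
    ACTION_PRUNE_SEQUENCES,
    PartitionAlignment,
    PruneAction,
    SupermatrixSpec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "detect_redundant_partitions",
    "apply_actions",
    "concatenate",
    "empty_row_taxa",
]


def detect_redundant_partitions(
    partitions: Sequence[PartitionAlignment],
) -> list[tuple[str, str]]:
    """Find byte-identical partition pairs; keep the lexicographically first.

    Partitions are first grouped by identical taxon set; within a group,
    two partitions are redundant when every taxon's sequence is exactly
    identical.  Returns (kept_id, dropped_id) pairs, one per dropped
    partition (all members of an identical group map to the group's first
    ID in lexicographic order).
    """
    by_taxa: dict[frozenset[str], list[PartitionAlignment]] = {}
    for part in partitions:
        by_taxa.setdefault(frozenset(part.taxa), []).append(part)
    drops: list[tuple[str, str]] = []
    for group in by_taxa.values():
        if len(group) < 2:
            continue
        # group identical members: content key = the sequence dict itself
        clusters: list[list[PartitionAlignment]] = []
        for part in group:
            for cluster in clusters:
                if dict(cluster[0].sequences) == dict(part.sequences):
                    cluster.append(part)
                    break
            else:
                clusters.append([part])
        for cluster in clusters:
            if len(cluster) < 2:
                continue
            ids = sorted(p.partition_id for p in cluster)
            kept = ids[0]
            drops.extend((kept, dropped) for dropped in ids[1:])
    return sorted(drops)


def apply_actions(
    partitions: Sequence[PartitionAlignment],
    actions: Iterable[PruneAction],
) -> list[PartitionAlignment]:
    """Apply prune/exclude actions, order-insensitively and idempotently.

    Unknown partition IDs are hard errors; pruning a taxon absent from its
    partition logs a warning and is a no-op.
    """
    by_id = {p.partition_id: p for p in partitions}
    excluded: set[str] = set()
    prune: dict[str, set[str]] = {}
    for action in actions:
        if action.partition_id not in by_id:
            raise KeyError(f"action names unknown partition {action.partition_id!r}")
        if action.kind == ACTION_EXCLUDE_PARTITION:
            excluded.add(action.partition_id)
        elif action.kind == ACTION_PRUNE_SEQUENCES:
            prune.setdefault(action.partition_id, set()).update(action.target_taxa)
    out = []
    for part in partitions:
        pid = part.partition_id
        if pid in excluded:
            continue
        targets = prune.get(pid, set())
        if targets:
            absent = targets - set(part.taxa)
            for taxon in sorted(absent):
                logger.warning(
                    "prune target %r absent from partition %r — no-op", taxon, pid
                )
            part = part.without_taxa(targets & set(part.taxa))
        out.append(part)
    return out


def concatenate(
    partitions: Sequence[PartitionAlignment],
    taxa_order: Sequence[str] | None = None,
) -> SupermatrixSpec:
    """Concatenate partitions into a supermatrix with a coordinate chart.

    Rows follow ``taxa_order`` (default: sorted union of all partition
    taxa); a taxon missing from a partition gets gaps across that
    partition's columns.  Total length equals the sum of partition lengths.
    """
    if not partitions:
        raise ValueError("concatenate requires at least one partition")
    if taxa_order is None:
        taxa_order = sorted({t for p in partitions for t in p.taxa})
    chart: list[tuple[str, int, int]] = []
    pos = 0
    pieces: dict[str, list[str]] = {t: [] for t in taxa_order}
    for part in partitions:
        chart.append((part.partition_id, pos, pos + part.length))
        pos += part.length
        gap_row = "-" * part.length
        for taxon in taxa_order:
            pieces[taxon].append(part.sequences.get(taxon, gap_row))
    matrix = {t: "".join(chunks) for t, chunks in pieces.items()}
    return SupermatrixSpec(matrix=matrix, chart=chart)


def empty_row_taxa(spec: SupermatrixSpec) -> list[str]:
    """Taxa whose supermatrix row carries no data at all (flagged, kept)."""
    return sorted(
        t for t, row in spec.matrix.items()
        if all(c in "-X" for c in row)
    )
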