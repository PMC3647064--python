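"""Cross-contamination assessment of flagged clades.

A flagged clade is classified as cross-contamination between sequencing
libraries when two criteria hold jointly: (1) at least one clade member has
a (near-)zero terminal branch in the gene tree, and (2) some pair of clade
members is identical or nearly identical over the alignment columns both
actually share.  The verdict records the extremal evidence used, so the
thresholds are auditable in reports.

Contaminant transfer cannot be attributed to a donor computationally, so
the downstream action is always to prune *both* members of the affected
pair from the partition.
"""

from __future__ import annotations

import logging

from .tree import SupportTree
from .types import (
    MISSING_CHARS,
    ContaminationVerdict,
    FlaggedClade,
    PartitionAlignment,
)

logger = logging.getLogger(__name__)

#: Default thresholds: a terminal branch is "very short" below EPS
#: substitutions/site; sequences are "nearly identical" at or above THETA
#: over at least MIN_OVERLAP shared columns.
DEFAULT_EPS = 1e-6
DEFAULT_THETA = 0.99
DEFAULT_MIN_OVERLAP = 20

__all__ = [
    "DEFAULT_EPS",
    "DEFAULT_THETA",
    "DEFAULT_MIN_OVERLAP",
    "pairwise_identity",
    "assess_contamination",
]


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[int, float]:
    """Overlap columns and fractional identity of two aligned sequences.

    Overlap counts the columns where neither sequence is a gap or ``X``;
    identity is matches/overlap.  With zero overlap the identity is
    undefined and reported as 0.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    overlap = 0
    matches = 0
    for a, b in zip(seq_a, seq_b):
        if a in MISSING_CHARS or b in MISSING_CHARS:
            continue
        overlap += 1
        if a == b:
            matches += 1
    return overlap, (matches / overlap if overlap else 0.0)


def assess_contamination(
    clade: FlaggedClade,
    alignment: PartitionAlignment,
    tree: SupportTree,
    eps: float = DEFAULT_EPS,
    theta: float = DEFAULT_THETA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ContaminationVerdict:
    """Apply the two contamination criteria to one flagged clade.

    ``is_contamination`` is true iff some clade member's terminal branch is
    <= ``eps`` AND some pair of clade members reaches identity >= ``theta``
    over >= ``min_overlap`` shared columns.
    """
    members = sorted(clade.taxa)
    for taxon in members:
        if taxon not in alignment.sequences:
            raise KeyError(
                f"clade member {taxon!r} missing from alignment "
                f"{alignment.partition_id!r}"
            )
    min_terminal = min(tree.terminal_branch_length(t) for t in members)

    best_identity = 0.0
    best_overlap = 0
    best_pair: tuple[str, str] | None = None
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            overlap, identity = pairwise_identity(
                alignment.sequences[a], alignment.sequences[b]
            )
            if overlap < min_overlap:
                continue
            if identity > best_identity or (
                identity == best_identity and overlap > best_overlap
            ):
                best_identity, best_overlap, best_pair = identity, overlap, (a, b)

    short_branch = min_terminal <= eps
    near_identical = best_identity >= theta and best_overlap >= min_overlap
    verdict = short_branch and near_identical
    if near_identical and not short_branch:
        logger.warning(
            "partition %s: pair %s nearly identical (%.4f) but no short terminal "
            "branch (min %.4g) — not flagged as contamination",
            clade.partition_id, best_pair, best_identity, min_terminal,
        )
    return ContaminationVerdict(
        clade=clade,
        is_contamination=verdict,
        min_terminal_branch=min_terminal,
        best_pair_identity=best_identity,
        overlap_columns=best_overlap,
        best_pair=best_pair,
    )
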