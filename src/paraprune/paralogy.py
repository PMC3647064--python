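"""Paralogy assessment by best-hit gene-label comparison, and the
prune-versus-exclude decision rule.

The flagged clade's members and the primer taxa (the curated reference
species that seeded the orthology search) are each represented by the gene
label of their best hit against an outgroup reference transcriptome.  If
every available label agrees, the clade's support cannot be attributed to
paralogy ("no paralog").  If the clade's labels differ from the primer
consensus, or the primer taxa disagree among themselves, the clade is a
potential paralog.  The consequence depends on whether the core ortholog
set itself is compromised: a clean primer consensus means only the
deviating sequences are pruned; an inconsistent primer set, or a primer
taxon inside the flagged clade, means the whole partition is excluded.

The module also computes the per-clade branch diagnostics tabulated for
each detected clade: the length of the internal branch leading to the
clade and its ratio to the mean of all internal branch lengths.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .tree import SupportTree
from .types import (
    ACTION_EXCLUDE_PARTITION,
    ACTION_NONE,
    ACTION_PRUNE_SEQUENCES,
    CATEGORY_INDETERMINATE,
    CATEGORY_NO_PARALOG,
    CATEGORY_POTENTIAL_PARALOG,
    AssessmentRecord,
    BestHitTable,
    BranchDiagnostics,
    FlaggedClade,
    PruneAction,
    normalize_gene_label,
)

__all__ = [
    "best_hit_label",
    "assess_paralogy",
    "assess_paralogy_multi",
    "decide_prune_action",
    "branch_diagnostics",
]

#: Sentinel-free representation: a taxon with no hit carries label ``None``.
NoHit = None


def best_hit_label(
    table: BestHitTable, taxon: str, partition_id: str
) -> tuple[Optional[str], Optional[float], Optional[float]]:
    """Gene label, e-value and bitscore of the best hit for one query.

    The best hit minimizes the e-value; ties are broken by maximal
    bitscore, then by lexicographically smallest gene label, so the result
    is deterministic.  With no rows at all the distinguished no-hit result
    ``(None, None, None)`` is returned.
    """
    rows = table.for_query(taxon, partition_id)
    if not rows:
        return (None, None, None)
    best = min(rows, key=lambda r: (r.evalue, -r.bitscore, normalize_gene_label(r.gene_label)))
    return (best.gene_label, best.evalue, best.bitscore)


def _consensus(labels: Mapping[str, Optional[str]]) -> tuple[set[str], bool]:
    """Distinct normalized labels among available entries, and availability."""
    seen = {normalize_gene_label(v) for v in labels.values() if v is not None}
    return seen, bool(seen)


def assess_paralogy(
    clade: FlaggedClade,
    clade_labels: Mapping[str, Optional[str]],
    primer_labels: Mapping[str, Optional[str]],
) -> AssessmentRecord:
    """Classify one clade from its label evidence against one reference.

    ``no_paralog`` iff every available clade label equals every available
    primer label.  ``potential_paralog`` if the primer labels are
    internally inconsistent or the clade labels deviate from the primer
    consensus.  A member with no hit is ignored in the comparison (absence
    of a hit is not evidence of a different gene) and noted.  If no label
    at all is available the record is ``indeterminate`` and triggers no
    action.
    """
    clade_seen, clade_avail = _consensus(clade_labels)
    primer_seen, primer_avail = _consensus(primer_labels)
    notes = []
    missing = [t for t, v in {**clade_labels, **primer_labels}.items() if v is None]
    if missing:
        notes.append("no-hit: " + ", ".join(sorted(missing)))

    if not clade_avail and not primer_avail:
        notes.append("no labels available; treated as no action")
        category = CATEGORY_INDETERMINATE
    elif len(primer_seen) > 1:
        notes.append("primer labels internally inconsistent")
        category = CATEGORY_POTENTIAL_PARALOG
    elif len(clade_seen | primer_seen) > 1:
        category = CATEGORY_POTENTIAL_PARALOG
    elif not clade_avail or not primer_avail:
        notes.append("one side entirely no-hit; comparison indeterminate")
        category = CATEGORY_INDETERMINATE
    else:
        category = CATEGORY_NO_PARALOG
    return AssessmentRecord(
        clade=clade,
        category=category,
        clade_labels=dict(clade_labels),
        primer_labels=dict(primer_labels),
        notes="; ".join(notes),
    )


def assess_paralogy_multi(
    clade: FlaggedClade,
    per_reference: Mapping[str, tuple[Mapping[str, Optional[str]], Mapping[str, Optional[str]]]],
) -> AssessmentRecord:
    """Assess against several reference transcriptomes in turn.

    A single reference can miss a paralogy case (both paralogs may hit the
    same reference gene), so labels are compared per reference and the
    clade is a potential paralog if *any* reference yields a label split.
    The returned record carries the evidence of the deciding reference, or
    of the first informative one if all agree.
    """
    if not per_reference:
        raise ValueError("at least one reference required")
    records = {
        ref: assess_paralogy(clade, cl, pl)
        for ref, (cl, pl) in per_reference.items()
    }
    for ref, rec in records.items():
        if rec.category == CATEGORY_POTENTIAL_PARALOG:
            rec.notes = (f"reference {ref}: " + rec.notes).rstrip(": ")
            return rec
    for ref, rec in records.items():
        if rec.category == CATEGORY_NO_PARALOG:
            return rec
    return next(iter(records.values()))


def decide_prune_action(
    record: AssessmentRecord, primer_taxa: frozenset[str] | set[str]
) -> PruneAction:
    """Turn an assessment into the supermatrix edit it implies.

    No paralogy (or indeterminate evidence) means no action.  A potential
    paralog with a clean primer consensus prunes exactly the clade members
    whose label deviates from that consensus.  If the primer labels are
    inconsistent, or a primer taxon sits inside the flagged clade, the core
    ortholog set itself is suspect and the entire partition is excluded.
    """
    pid = record.clade.partition_id
    if record.category != CATEGORY_POTENTIAL_PARALOG:
        return PruneAction(ACTION_NONE, pid)

    # A primer taxon may sit inside the flagged clade; its label then lives
    # in the clade map.  Pool every available primer label before judging
    # whether the core ortholog set itself is compromised.
    def label_of(taxon: str) -> Optional[str]:
        return record.primer_labels.get(taxon) or record.clade_labels.get(taxon)

    primer_seen = {
        normalize_gene_label(v)
        for v in (label_of(t) for t in primer_taxa)
        if v is not None
    }
    if len(primer_seen) != 1:
        return PruneAction(ACTION_EXCLUDE_PARTITION, pid)
    consensus = next(iter(primer_seen))
    affected = frozenset(
        t
        for t, v in record.clade_labels.items()
        if v is not None and normalize_gene_label(v) != consensus and t in record.clade.taxa
    )
    if affected & set(primer_taxa):
        # a primer taxon is itself among the affected sequences
        return PruneAction(ACTION_EXCLUDE_PARTITION, pid)
    targets = affected
    if not targets:
        # Deviation was driven by labels of taxa outside the clade map; no
        # clade member deviates individually, nothing to prune.
        return PruneAction(ACTION_NONE, pid)
    return PruneAction(ACTION_PRUNE_SEQUENCES, pid, targets)


def branch_diagnostics(tree: SupportTree, clade: FlaggedClade) -> BranchDiagnostics:
    """Leading branch length, mean internal branch length, and their ratio.

    The mean averages *all* internal branches, including the leading one,
    so a tree with a single internal edge has ratio exactly 1.  The clade
    must correspond to an internal edge of the tree.
    """
    edge = tree.find_edge(clade.taxa)  # KeyError if not an edge
    internal = tree.internal_branch_lengths()
    mean = sum(internal) / len(internal)
    if mean > 0:
        ratio = edge.length / mean
    else:
        ratio = 1.0 if edge.length == 0 else float("inf")
    return BranchDiagnostics(
        leading_branch_length=edge.length,
        mean_internal_branch=mean,
        branch_ratio=ratio,
    )
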