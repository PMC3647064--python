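"""End-to-end orchestration: screen → contamination → paralogy → prune →
concatenate, with paper-style reports and dataset variants.

The pipeline produces the standard family of supermatrix variants: the
all-data matrix (AD), the contamination-pruned matrix (CPr), one variant
per paralogy case applied on top of CPr (CPr<partition>), and the fully
pruned matrix (CPPr).  Every decision is traceable: each stage's records
are kept on the report and written as sorted TSVs, so re-running on
identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as pio
from .contamination import (
    DEFAULT_EPS,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_THETA,
    assess_contamination,
)
from .paralogy import assess_paralogy, best_hit_label, decide_prune_action
from .screening import DEFAULT_SUPPORT_THRESHOLD, ScreenReport, screen
from .supermatrix import apply_actions, concatenate, empty_row_taxa
from .tree import SupportTree
from .types import (
    ACTION_NONE,
    ACTION_PRUNE_SEQUENCES,
    CATEGORY_CONTAMINATION,
    CATEGORY_POTENTIAL_PARALOG,
    AprioriGroupSet,
    AssessmentRecord,
    BestHitTable,
    ContaminationVerdict,
    FlaggedClade,
    PartitionAlignment,
    PruneAction,
    SupermatrixSpec,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineSettings", "PipelineReport", "run_screen_pipeline"]


@dataclass(frozen=True)
class PipelineSettings:
    """All thresholds in one auditable place (echoed into reports)."""

    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD
    eps: float = DEFAULT_EPS
    theta: float = DEFAULT_THETA
    min_overlap: int = DEFAULT_MIN_OVERLAP
    primer_taxa: frozenset[str] = frozenset()


@dataclass
class PipelineReport:
    settings: PipelineSettings
    screen: ScreenReport
    contamination: list[ContaminationVerdict]
    assessments: list[AssessmentRecord]
    actions: list[PruneAction]
    variants: dict[str, SupermatrixSpec] = field(default_factory=dict)

    @property
    def n_contamination(self) -> int:
        return sum(1 for v in self.contamination if v.is_contamination)

    @property
    def n_potential_paralog(self) -> int:
        return sum(
            1 for a in self.assessments if a.category == CATEGORY_POTENTIAL_PARALOG
        )

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.contamination:
            if v.is_contamination:
                counts[CATEGORY_CONTAMINATION] = counts.get(CATEGORY_CONTAMINATION, 0) + 1
        for a in self.assessments:
            counts[a.category] = counts.get(a.category, 0) + 1
        return counts


def _labels_for(
    best_hits: BestHitTable, taxa: Sequence[str], partition_id: str
) -> dict[str, str | None]:
    return {
        t: best_hit_label(best_hits, t, partition_id)[0] for t in sorted(taxa)
    }


def run_screen_pipeline(
    partitions: Sequence[PartitionAlignment],
    trees: Sequence[SupportTree],
    best_hits: BestHitTable,
    groups: AprioriGroupSet | None = None,
    settings: PipelineSettings = PipelineSettings(),
    out_dir: str | Path | None = None,
    build_variants: bool = True,
) -> PipelineReport:
    """Run the full detection-and-pruning workflow over a dataset.

    Each flagged clade is first tested for cross-contamination; clades not
    explained by contamination are assessed for paralogy by best-hit label
    comparison against the primer taxa.  The resulting actions are applied
    to build the AD / CPr / CPr<id> / CPPr supermatrix variants.
    """
    by_id = {p.partition_id: p for p in partitions}
    tree_by_id = {t.partition_id: t for t in trees}

    report_screen = screen(list(trees), settings.support_threshold, groups)

    verdicts: list[ContaminationVerdict] = []
    assessments: list[AssessmentRecord] = []
    contamination_actions: dict[tuple, PruneAction] = {}
    paralogy_actions: dict[tuple, PruneAction] = {}

    for clade in report_screen.clades:
        pid = clade.partition_id
        if pid not in by_id:
            raise KeyError(f"screen flagged unknown partition {pid!r}")
        alignment, tree = by_id[pid], tree_by_id[pid]
        verdict = assess_contamination(
            clade, alignment, tree,
            eps=settings.eps, theta=settings.theta,
            min_overlap=settings.min_overlap,
        )
        verdicts.append(verdict)
        if verdict.is_contamination:
            # donor cannot be decided computationally: prune the whole pair
            targets = frozenset(verdict.best_pair or clade.taxa)
            action = PruneAction(ACTION_PRUNE_SEQUENCES, pid, targets)
            contamination_actions[(pid, targets)] = action
            continue
        record = assess_paralogy(
            clade,
            _labels_for(best_hits, sorted(clade.taxa), pid),
            _labels_for(best_hits, sorted(settings.primer_taxa), pid),
        )
        assessments.append(record)
        action = decide_prune_action(record, settings.primer_taxa)
        if action.kind != ACTION_NONE:
            paralogy_actions[(pid, action.target_taxa)] = action

    contam = sorted(contamination_actions.values(),
                    key=lambda a: (a.partition_id, sorted(a.target_taxa)))
    paralog = sorted(paralogy_actions.values(),
                     key=lambda a: (a.partition_id, sorted(a.target_taxa)))
    actions = contam + paralog

    report = PipelineReport(
        settings=settings,
        screen=report_screen,
        contamination=verdicts,
        assessments=assessments,
        actions=actions,
    )

    if build_variants:
        taxa_order = sorted({t for p in partitions for t in p.taxa})
        report.variants["AD"] = concatenate(partitions, taxa_order)
        cpr_parts = apply_actions(partitions, contam)
        report.variants["CPr"] = concatenate(cpr_parts, taxa_order)
        for pid in sorted({a.partition_id for a in paralog}):
            case_actions = [a for a in paralog if a.partition_id == pid]
            report.variants[f"CPr{pid}"] = concatenate(
                apply_actions(cpr_parts, case_actions), taxa_order
            )
        report.variants["CPPr"] = concatenate(
            apply_actions(cpr_parts, paralog), taxa_order
        )

    if out_dir is not None:
        _write_reports(report, Path(out_dir))
    return report


def _write_reports(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "partition": c.partition_id,
                "members": ",".join(sorted(c.taxa)),
                "support": c.support,
                "leading_branch_length": c.leading_branch_length,
            }
            for c in report.screen.clades
        ]
    ).to_csv(out_dir / "screen.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "partition": v.clade.partition_id,
                "members": ",".join(sorted(v.clade.taxa)),
                "pair": ",".join(v.best_pair) if v.best_pair else "",
                "identity": round(v.best_pair_identity, 6),
                "overlap": v.overlap_columns,
                "min_terminal_branch": v.min_terminal_branch,
                "verdict": "contamination" if v.is_contamination else "clean",
            }
            for v in report.contamination
        ]
    ).to_csv(out_dir / "contamination.tsv", sep="\t", index=False)

    rows = []
    for a in report.assessments:
        for taxon in sorted(a.clade_labels) + sorted(a.primer_labels):
            labels = a.clade_labels if taxon in a.clade_labels else a.primer_labels
            rows.append(
                {
                    "partition": a.clade.partition_id,
                    "clade": ",".join(sorted(a.clade.taxa)),
                    "role": "clade" if taxon in a.clade_labels else "primer",
                    "species": taxon,
                    "gene_name": labels[taxon] or "no-hit",
                    "assessment": a.category,
                    "notes": a.notes,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "assessment.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "partition": a.partition_id,
                "action": a.kind,
                "targets": ",".join(sorted(a.target_taxa)),
            }
            for a in report.actions
        ]
    ).to_csv(out_dir / "actions.tsv", sep="\t", index=False)

    matrices = out_dir / "matrices"
    matrices.mkdir(exist_ok=True)
    for name, spec in report.variants.items():
        pio.write_fasta(spec.matrix, matrices / f"{name}.fasta")
        pio.write_phylip(spec, matrices / f"{name}.phy")
        pio.write_partition_file(spec, matrices / f"{name}.partitions")
        empties = empty_row_taxa(spec)
        if empties:
            logger.warning("variant %s: all-gap rows kept for %s", name, empties)
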