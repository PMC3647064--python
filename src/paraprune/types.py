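"""Core domain types shared across the screening pipeline.

The pipeline operates on per-gene ("partition") amino-acid alignments and
their single-gene maximum-likelihood trees, flags suspiciously well-supported
clades, classifies them (cross-contamination vs. misassigned paralogs vs.
clean), and edits the concatenated supermatrix accordingly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

MISSING_CHARS = frozenset("-X")

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Assessment categories for a flagged clade.
CATEGORY_CONTAMINATION = "contamination"
CATEGORY_POTENTIAL_PARALOG = "potential_paralog"
CATEGORY_NO_PARALOG = "no_paralog"
CATEGORY_INDETERMINATE = "indeterminate"

#: Prune action kinds.
ACTION_NONE = "none"
ACTION_PRUNE_SEQUENCES = "prune_sequences"
ACTION_EXCLUDE_PARTITION = "exclude_partition"


@dataclass(frozen=True)
class PartitionAlignment:
    """One gene's masked amino-acid alignment with a stable partition ID.

    ``sequences`` maps taxon name to an aligned amino-acid string using the
    20 one-letter codes, ``X`` for ambiguity and ``-`` for gaps.  All rows
    have identical length and taxon names are unique.
    """

    partition_id: str
    sequences: Mapping[str, str]
    length: int = field(default=-1)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"partition {self.partition_id!r}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            offender = next(
                t for t, s in self.sequences.items()
                if len(s) != len(next(iter(self.sequences.values())))
            )
            raise ValueError(
                f"ragged alignment in partition {self.partition_id!r}: "
                f"taxon {offender!r} has deviating length"
            )
        (width,) = lengths
        if width < 1:
            raise ValueError(f"partition {self.partition_id!r}: zero-length alignment")
        if self.length == -1:
            object.__setattr__(self, "length", width)
        elif self.length != width:
            raise ValueError(
                f"partition {self.partition_id!r}: declared length {self.length} "
                f"!= actual {width}"
            )

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def non_gap_count(self, taxon: str) -> int:
        return sum(1 for c in self.sequences[taxon] if c not in MISSING_CHARS)

    def without_taxa(self, taxa: Iterable[str]) -> "PartitionAlignment":
        drop = set(taxa)
        kept = {t: s for t, s in self.sequences.items() if t not in drop}
        return PartitionAlignment(self.partition_id, kept)


@dataclass(frozen=True)
class FlaggedClade:
    """One side of a well-supported bipartition in a single-gene tree."""

    partition_id: str
    taxa: frozenset[str]
    support: int
    leading_branch_length: float

    def sort_key(self) -> tuple:
        return (self.partition_id, min(self.taxa), len(self.taxa), sorted(self.taxa))


@dataclass(frozen=True)
class AprioriGroupSet:
    """Named taxon groups whose monophyly is accepted on prior evidence.

    Clades falling entirely inside one group are not pursued further.
    """

    groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if len(members) < 2:
                raise ValueError(f"a-priori group {name!r} has fewer than 2 members")

    def covers(self, taxa: frozenset[str]) -> bool:
        return any(taxa <= members for members in self.groups.values())


@dataclass(frozen=True)
class BestHitRow:
    query_taxon: str
    partition_id: str
    subject_accession: str
    gene_label: str
    evalue: float
    bitscore: float


@dataclass
class BestHitTable:
    """Tabular best-hit evidence (BLAST outfmt 6 style) with mapped gene labels."""

    rows: list[BestHitRow] = field(default_factory=list)

    def for_query(self, taxon: str, partition_id: str) -> list[BestHitRow]:
        return [
            r for r in self.rows
            if r.query_taxon == taxon and r.partition_id == partition_id
        ]


@dataclass(frozen=True)
class ContaminationVerdict:
    clade: FlaggedClade
    is_contamination: bool
    min_terminal_branch: float
    best_pair_identity: float
    overlap_columns: int
    best_pair: tuple[str, str] | None = None


@dataclass
class AssessmentRecord:
    """Classification of a flagged clade with the label evidence that drove it."""

    clade: FlaggedClade
    category: str
    clade_labels: dict[str, Optional[str]]
    primer_labels: dict[str, Optional[str]]
    notes: str = ""


@dataclass(frozen=True)
class PruneAction:
    kind: str
    partition_id: str
    target_taxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in (ACTION_NONE, ACTION_PRUNE_SEQUENCES, ACTION_EXCLUDE_PARTITION):
            raise ValueError(f"unknown action kind {self.kind!r}")
        if self.kind == ACTION_PRUNE_SEQUENCES and not self.target_taxa:
            raise ValueError("prune_sequences requires non-empty target_taxa")
        if self.kind != ACTION_PRUNE_SEQUENCES and self.target_taxa:
            raise ValueError(f"action {self.kind!r} takes no target taxa")


@dataclass(frozen=True)
class BranchDiagnostics:
    """Branch-length evidence for a flagged clade (as tabulated per clade)."""

    leading_branch_length: float
    mean_internal_branch: float
    branch_ratio: float


@dataclass
class SupermatrixSpec:
    """Concatenated matrix plus the coordinate chart locating each partition.

    Chart segments are 0-based half-open internally; writers emit the
    conventional 1-based inclusive coordinates.
    """

    matrix: dict[str, str]
    chart: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        total = self.chart[-1][2] if self.chart else 0
        pos = 0
        for pid, start, end in self.chart:
            if start != pos or end <= start:
                raise ValueError(f"chart segment {pid!r} not contiguous at {pos}")
            pos = end
        for taxon, row in self.matrix.items():
            if len(row) != total:
                raise ValueError(
                    f"supermatrix row {taxon!r} length {len(row)} != chart total {total}"
                )

    @property
    def length(self) -> int:
        return self.chart[-1][2] if self.chart else 0

    def segment(self, partition_id: str) -> tuple[int, int]:
        for pid, start, end in self.chart:
            if pid == partition_id:
                return start, end
        raise KeyError(partition_id)

    def partition_of_site(self, site: int) -> str:
        for pid, start, end in self.chart:
            if start <= site < end:
                return pid
        raise IndexError(site)


def normalize_gene_label(label: str) -> str:
    """Canonical form for gene-label equality: whitespace collapsed, case-folded."""
    return " ".join(label.split()).casefold()
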