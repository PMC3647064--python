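"""Readers and writers for the standard flat formats the pipeline touches.

FASTA alignments and supermatrices (via Biopython), newick trees and
one-tree-per-line tree sets, BLAST tabular output (``-outfmt 6``) with an
accession-to-gene-label map, tab-separated a-priori group definitions, and
RAxML-style partition files.  Internal coordinates are 0-based half-open;
partition files are emitted 1-based inclusive as the format demands.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .tree import SupportTree
from .types import (
    AprioriGroupSet,
    BestHitRow,
    BestHitTable,
    PartitionAlignment,
    SupermatrixSpec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_partition_alignment",
    "write_fasta",
    "parse_support_tree",
    "read_support_tree",
    "read_tree_set",
    "read_blast_table",
    "read_accession_map",
    "read_groups",
    "write_phylip",
    "write_partition_file",
    "read_partition_file",
]


def read_partition_alignment(path, partition_id: str) -> PartitionAlignment:
    """Read one aligned amino-acid FASTA file as a partition.

    Sequences are uppercased; input taxon order is preserved.  Ragged rows
    and duplicate taxon names are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(
                f"duplicate taxon {name!r} in partition {partition_id!r} ({path})"
            )
        sequences[name] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    widths = {len(s) for s in sequences.values()}
    if len(widths) != 1:
        mode = max(widths, key=lambda w: sum(1 for s in sequences.values() if len(s) == w))
        offender = next(t for t, s in sequences.items() if len(s) != mode)
        raise ValueError(
            f"ragged alignment in partition {partition_id!r}: taxon {offender!r} "
            f"has length {len(sequences[offender])}, expected {mode}"
        )
    return PartitionAlignment(partition_id, sequences)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def parse_support_tree(
    newick_text: str, partition_id: str, support_style: str = "node_label"
) -> SupportTree:
    """Parse a newick string with branch lengths and bootstrap supports."""
    return SupportTree.parse(newick_text, partition_id, support_style=support_style)


def read_support_tree(path, partition_id: str | None = None, **kwargs) -> SupportTree:
    path = Path(path)
    if partition_id is None:
        partition_id = path.stem
    return parse_support_tree(path.read_text(), partition_id, **kwargs)


def read_tree_set(path, label: str = "") -> list[SupportTree]:
    """Read a one-newick-per-line tree set (e.g. bootstrap replicates)."""
    trees = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        trees.append(parse_support_tree(line, f"{label or Path(path).stem}:{i}"))
    return trees


def read_accession_map(path) -> dict[str, str]:
    """Two-column TSV mapping subject accession to curated gene label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


#: outfmt 6 column order.
_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore"
).split()


def read_blast_table(
    path,
    accession_label_map: Mapping[str, str],
    partition_id: str | None = None,
    query_splitter=None,
) -> BestHitTable:
    """Parse BLAST tabular output (``-outfmt 6``) into a best-hit table.

    ``qseqid`` is interpreted as ``taxon|partition`` when it contains a pipe
    and no explicit ``partition_id`` is given; a custom ``query_splitter``
    callable may override that convention.  Subject accessions are resolved
    to gene labels through ``accession_label_map``; unmapped accessions keep
    the accession as label and a warning is logged.  Malformed rows are hard
    errors with their line number.
    """
    table = BestHitTable()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(_BLAST_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_BLAST_COLUMNS)} "
                    f"tab-separated fields, found {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}")
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative e-value {evalue}")
            if query_splitter is not None:
                taxon, pid = query_splitter(qseqid)
            elif partition_id is not None:
                taxon, pid = qseqid, partition_id
            elif "|" in qseqid:
                taxon, pid = qseqid.split("|", 1)
            else:
                taxon, pid = qseqid, ""
            label = accession_label_map.get(sseqid)
            if label is None:
                logger.warning(
                    "%s:%d: unmapped subject accession %r kept as label",
                    path, lineno, sseqid,
                )
                label = sseqid
            table.rows.append(
                BestHitRow(taxon, pid, sseqid, label, evalue, bitscore)
            )
    return table


def read_groups(path) -> AprioriGroupSet:
    """Groups file: ``group-name<TAB>comma-separated taxa`` per line."""
    groups: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>taxa")
            name = row[0].strip()
            members = frozenset(t.strip() for t in row[1].split(",") if t.strip())
            groups[name] = members
    return AprioriGroupSet(groups)


def write_phylip(spec: SupermatrixSpec, path) -> None:
    """Sequential PHYLIP (relaxed names) for the concatenated matrix."""
    with open(path, "w") as fh:
        fh.write(f" {len(spec.matrix)} {spec.length}\n")
        for taxon, row in spec.matrix.items():
            fh.write(f"{taxon.replace(' ', '_')}  {row}\n")


def write_partition_file(spec: SupermatrixSpec, path, model: str = "LG") -> None:
    """RAxML-style partition file, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for pid, start, end in spec.chart:
            fh.write(f"{model}, {pid} = {start + 1}-{end}\n")


_PARTITION_LINE = re.compile(
    r"^\s*(?P<model>[^,]+)\s*,\s*(?P<pid>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$"
)


def read_partition_file(path) -> list[tuple[str, int, int]]:
    """Read a RAxML partition file into 0-based half-open chart segments."""
    chart = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _PARTITION_LINE.match(line)
            if not m:
                raise ValueError(f"{path}:{lineno}: cannot parse partition line")
            chart.append((m.group("pid"), int(m.group("start")) - 1, int(m.group("end"))))
    return chart
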