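"""Synthetic data with the statistical structure the screening assumes.

The generator emulates the mechanism by which reciprocal-best-hit
orthology prediction misassigns paralogs.  A gene family carries two
paralogs, A and B, from a duplication predating the speciation of the
study taxa; each paralog copy mirrors the species tree and the two copies
are separated by an extra stretch of branch length (the inter-paralog
divergence).  Paralogs are lost along branches, and a taxon's sequencing
library then samples each surviving transcript with a per-taxon detection
probability — small, shallow libraries miss genes.  When a query taxon's
library holds only B while every reference taxon's library holds only A,
the forward search finds B, the back-check returns A, reciprocity appears
satisfied, and B is silently filed under A: the reciprocal-lack
misassignment.  Ground truth is tracked throughout so the emulated
assignment can be scored exactly.

Cross-contamination between two libraries (a small fraction of one
library's transcripts copied verbatim into another) and neighbor-joining
trees with bootstrap supports on simulated partitions complete the inputs
the screening pipeline consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np

from .substitution_models import SubstitutionModel, lg_model
from .tree import SupportTree
from .types import AMINO_ACIDS, BestHitRow, BestHitTable, PartitionAlignment

__all__ = [
    "SimConfig",
    "SimTruth",
    "GeneFamily",
    "simulate_gene_family",
    "sample_est_library",
    "inject_contamination",
    "make_alignment_scorer",
    "validate_score_separation",
    "emulate_orthology_assignment",
    "misassignment_truth",
    "build_partition_tree",
    "evolve_sequences",
]

#: Default eight-taxon balanced species tree (branch lengths in
#: substitutions/site) used when a config does not supply one.
DEFAULT_SPECIES_TREE = (
    "(((T1:0.1,T2:0.1):0.1,(T3:0.1,T4:0.1):0.1):0.1,"
    "((T5:0.1,T6:0.1):0.1,(T7:0.1,T8:0.1):0.1):0.1);"
)

PARALOGS = ("A", "B")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated gene family.

    Defaults model shallow EST sampling: per-branch paralog loss 0.2,
    per-taxon transcript detection 0.5, inter-paralog divergence 1.5
    substitutions/site (a duplication predating the speciations, deep
    enough that same-paralog similarity always exceeds cross-paralog
    similarity), 300 aligned sites under LG+Γ+I, and a contaminant
    transfer fraction of 0.05 where contamination is injected.
    """

    seed: int
    species_tree: str = DEFAULT_SPECIES_TREE
    inter_paralog_divergence: float = 1.5
    loss_prob: float = 0.2
    detection_prob: float | Mapping[str, float] = 0.5
    primer_taxa: frozenset[str] = frozenset({"T1", "T2"})
    reference_taxa: frozenset[str] = frozenset({"T1"})
    model: SubstitutionModel = field(default_factory=lambda: lg_model(alpha=0.8, pinv=0.1))
    n_sites: int = 300
    contamination_fraction: float = 0.05
    max_retries: int = 100

    def __post_init__(self):
        if not 0 <= self.loss_prob <= 1:
            raise ValueError("loss_prob outside [0, 1]")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction outside [0, 1]")
        if not self.reference_taxa <= self.primer_taxa:
            raise ValueError("reference taxa must be a subset of primer taxa")

    def detection_for(self, taxon: str) -> float:
        if isinstance(self.detection_prob, Mapping):
            p = self.detection_prob.get(taxon, 0.0)
        else:
            p = self.detection_prob
        if not 0 <= p <= 1:
            raise ValueError(f"detection probability {p} outside [0, 1]")
        return p


@dataclass
class SimTruth:
    """Ground truth: who carries what, and what ended up in the libraries."""

    genome_presence: dict[tuple[str, str], bool]
    library_presence: dict[tuple[str, str], bool] = field(default_factory=dict)
    paralog_of: dict[str, str] = field(default_factory=dict)
    contaminants: set[str] = field(default_factory=set)


@dataclass
class GeneFamily:
    """One simulated family: gene tree, per-copy sequences, ground truth."""

    gene_tree: dendropy.Tree
    sequences: dict[tuple[str, str], str]  # (taxon, paralog) -> aligned seq
    truth: SimTruth
    config: SimConfig

    def seq_id(self, taxon: str, paralog: str) -> str:
        return f"{taxon}|{paralog}"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def evolve_sequences(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve sequences along a tree under the model's Γ+I site-rate mixture.

    The root state is drawn from the equilibrium frequencies; each site is
    invariant with probability pinv, otherwise it carries one of the K
    discrete-gamma rates.  Returns leaf-name -> sequence.
    """
    invariant = rng.random(n_sites) < model.pinv
    cats = rng.integers(0, model.n_categories, size=n_sites)
    site_rate = np.where(invariant, 0.0, model.category_rates[cats])

    root_state = rng.choice(20, size=n_sites, p=model.frequencies)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_state}
    out: dict[str, str] = {}
    unique_rates = np.unique(site_rate)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            child = parent.copy()
            for r in unique_rates:
                if r == 0.0 or t == 0.0:
                    continue
                mask = site_rate == r
                P = model.transition_matrix(t * r)
                sub = parent[mask]
                u = rng.random(len(sub))
                cum = np.cumsum(P[sub], axis=1)
                child_states = (u[:, None] > cum).sum(axis=1)
                child[mask] = child_states
            states[id(node)] = child
        if node.is_leaf():
            seq = states[id(node)]
            out[node.taxon.label] = "".join(AMINO_ACIDS[s] for s in seq)
    return out


def _paralog_subtree(species_newick: str, paralog: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=species_newick, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = f"{leaf.taxon.label}|{paralog}"
    return tree


def simulate_gene_family(config: SimConfig) -> GeneFamily:
    """Simulate one two-paralog gene family with per-branch losses.

    The duplication sits at the root: paralog subtrees A and B each mirror
    the species tree and are joined by a stem of total length
    ``inter_paralog_divergence``.  Every branch of each paralog copy
    (including its stem) loses the copy with probability ``loss_prob``; a
    loss removes all descendant copies.  If a loss pattern leaves no
    sequence at all, the pattern is redrawn up to ``max_retries`` times.
    """
    rng = _rng(config.seed)
    species = dendropy.Tree.get(
        data=config.species_tree, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    taxa = sorted(l.taxon.label for l in species.leaf_node_iter())

    for attempt in range(config.max_retries):
        presence: dict[tuple[str, str], bool] = {}
        lost_stem: dict[str, bool] = {}
        lost_edges: dict[str, set[int]] = {}
        for paralog in PARALOGS:
            lost_stem[paralog] = rng.random() < config.loss_prob
            edges = set()
            # enumerate species-tree edges deterministically (preorder index)
            for i, node in enumerate(species.preorder_node_iter()):
                if node.parent_node is None:
                    continue
                if rng.random() < config.loss_prob:
                    edges.add(i)
            lost_edges[paralog] = edges
        # propagate: a taxon has the paralog iff stem survives and no edge
        # on its root-to-tip path was lost
        for paralog in PARALOGS:
            idx = {id(n): i for i, n in enumerate(species.preorder_node_iter())}
            for leaf in species.leaf_node_iter():
                alive = not lost_stem[paralog]
                node = leaf
                while alive and node.parent_node is not None:
                    if idx[id(node)] in lost_edges[paralog]:
                        alive = False
                    node = node.parent_node
                presence[(leaf.taxon.label, paralog)] = alive
        if any(presence.values()):
            break
    else:
        raise RuntimeError(
            f"no surviving sequence after {config.max_retries} loss drawings"
        )

    # build the gene tree: two paralog copies joined at the duplication node
    half = config.inter_paralog_divergence / 2.0
    sub_a = _paralog_subtree(config.species_tree, "A")
    sub_b = _paralog_subtree(config.species_tree, "B")
    ns = dendropy.TaxonNamespace()
    gene = dendropy.Tree(taxon_namespace=ns)
    for sub in (sub_a, sub_b):
        sub.migrate_taxon_namespace(ns)
        child = sub.seed_node
        child.edge.length = half
        gene.seed_node.add_child(child)
    gene.update_bipartitions(suppress_unifurcations=False)

    sequences_all = evolve_sequences(gene, config.model, config.n_sites, rng)
    sequences = {
        (taxon, paralog): sequences_all[f"{taxon}|{paralog}"]
        for taxon in taxa
        for paralog in PARALOGS
        if presence[(taxon, paralog)]
    }
    truth = SimTruth(
        genome_presence=presence,
        paralog_of={f"{t}|{p}": p for (t, p) in sequences},
    )
    # prune unobserved copies from the returned gene tree
    keep = [f"{t}|{p}" for (t, p) in sequences]
    if len(keep) >= 2:
        gene.retain_taxa_with_labels(keep)
    return GeneFamily(gene_tree=gene, sequences=sequences, truth=truth, config=config)


def sample_est_library(
    family: GeneFamily,
    detection_prob: float | Mapping[str, float] | None = None,
    seed: int | None = None,
) -> dict[str, dict[str, str]]:
    """Sample each genome-present transcript into its taxon's library.

    Each transcript enters independently with the taxon's detection
    probability.  Returns taxon -> {seq_id: sequence} and records library
    presence in the family's truth.
    """
    config = family.config
    if detection_prob is not None:
        config = replace(config, detection_prob=detection_prob)
    rng = _rng(seed if seed is not None else config.seed + 1)
    libraries: dict[str, dict[str, str]] = {}
    taxa = sorted({t for (t, _p) in family.truth.genome_presence})
    for taxon in taxa:
        libraries[taxon] = {}
        for paralog in PARALOGS:
            present = family.sequences.get((taxon, paralog))
            if present is None:
                family.truth.library_presence[(taxon, paralog)] = False
                continue
            hit = rng.random() < config.detection_for(taxon)
            family.truth.library_presence[(taxon, paralog)] = bool(hit)
            if hit:
                libraries[taxon][family.seq_id(taxon, paralog)] = present
    return libraries


def inject_contamination(
    donor_library: Mapping[str, str],
    recipient_library: Mapping[str, str],
    fraction: float,
    seed: int,
) -> tuple[dict[str, str], set[str]]:
    """Copy ``ceil(fraction * |donor|)`` donor transcripts into the recipient.

    Transcripts are copied verbatim and tagged with a ``contam:`` prefix in
    the recipient; the returned set holds the injected recipient IDs.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction outside [0, 1]")
    recipient = dict(recipient_library)
    n = math.ceil(fraction * len(donor_library))
    if n == 0:
        return recipient, set()
    rng = _rng(seed)
    ids = sorted(donor_library)
    chosen = [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
    injected = set()
    for sid in chosen:
        new_id = f"contam:{sid}"
        recipient[new_id] = donor_library[sid]
        injected.add(new_id)
    return recipient, injected


# ---------------------------------------------------------------------------
# orthology-assignment emulation


def make_alignment_scorer() -> Callable[[str, str], float]:
    """Global-alignment similarity scorer (BLOSUM62, affine gaps)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"

    def score(a: str, b: str) -> float:
        return float(aligner.score(a.replace("-", ""), b.replace("-", "")))

    return score


def validate_score_separation(
    family: GeneFamily, scorer: Callable[[str, str], float] | None = None
) -> None:
    """Check that same-paralog scores strictly exceed cross-paralog scores.

    The misassignment-iff-reciprocal-lack truth condition is provable only
    when the scorer always ranks a same-paralog sequence above any
    cross-paralog sequence; insufficient inter-paralog divergence breaks
    that and is a hard error at generation time.
    """
    scorer = scorer or make_alignment_scorer()
    by_paralog: dict[str, list[str]] = {p: [] for p in PARALOGS}
    for (taxon, paralog), seq in family.sequences.items():
        by_paralog[paralog].append(seq)
    min_same = math.inf
    max_cross = -math.inf
    for p in PARALOGS:
        seqs = by_paralog[p]
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                min_same = min(min_same, scorer(a, b))
    for a in by_paralog["A"]:
        for b in by_paralog["B"]:
            max_cross = max(max_cross, scorer(a, b))
    if min_same <= max_cross:
        raise ValueError(
            f"insufficient inter-paralog divergence: min same-paralog score "
            f"{min_same} <= max cross-paralog score {max_cross}; "
            "increase inter_paralog_divergence"
        )


@dataclass
class AssignmentResult:
    """Outcome of the emulated top-down orthology search for one taxon."""

    taxon: str
    forward_hit: str | None  # library seq id best matching the core-A profile
    accepted: bool
    per_reference: dict[str, bool] = field(default_factory=dict)


def emulate_orthology_assignment(
    libraries: Mapping[str, Mapping[str, str]],
    core_set_a: Mapping[str, tuple[str, str]],
    reference_taxa: Sequence[str],
    scorer: Callable[[str, str], float] | None = None,
    mode: str = "all",
) -> dict[str, AssignmentResult]:
    """Emulate profile search plus reciprocal back-check per query taxon.

    ``core_set_a`` maps each primer taxon to its curated paralog-A entry
    ``(seq_id, sequence)``.  Forward step: the query library sequence with
    the best score against the core-A profile (max over core sequences).
    Back step: that hit is scored against each reference taxon's library;
    the reference accepts iff its best-scoring sequence is its own core-A
    member.  The assignment is accepted iff all (``mode="all"``) or at
    least one (``mode="any"``) reference accepts.  Ties are broken by
    lexicographic sequence ID, so the emulation is deterministic.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    scorer = scorer or make_alignment_scorer()
    core_seqs = [seq for (_sid, seq) in core_set_a.values()]
    results: dict[str, AssignmentResult] = {}
    for taxon in sorted(libraries):
        library = libraries[taxon]
        if not library:
            results[taxon] = AssignmentResult(taxon, None, False)
            continue
        forward_id = max(
            sorted(library),
            key=lambda sid: max(scorer(library[sid], cs) for cs in core_seqs),
        )
        forward_seq = library[forward_id]
        per_ref: dict[str, bool] = {}
        for ref in sorted(reference_taxa):
            ref_lib = libraries.get(ref, {})
            if not ref_lib:
                per_ref[ref] = False
                continue
            back_id = max(
                sorted(ref_lib), key=lambda sid: scorer(ref_lib[sid], forward_seq)
            )
            core_id = core_set_a.get(ref, (None, None))[0]
            per_ref[ref] = back_id == core_id
        accepted = all(per_ref.values()) if mode == "all" else any(per_ref.values())
        if not per_ref:
            accepted = False
        results[taxon] = AssignmentResult(taxon, forward_id, accepted, per_ref)
    return results


def misassignment_truth(
    library_presence: Mapping[tuple[str, str], bool],
    reference_taxa: Sequence[str],
    mode: str = "all",
) -> set[str]:
    """Closed-form expected misassignment set under reciprocal lack.

    A taxon is expected to be misassigned (its paralog-B sequence filed
    under A) iff its library lacks A, contains B, and — for ``mode="all"``
    — every reference library lacks B while containing A (``mode="any"``:
    at least one reference does).
    """
    if mode not in ("all", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    refs = sorted(reference_taxa)

    def ref_fooled(r: str) -> bool:
        return (not library_presence.get((r, "B"), False)) and library_presence.get(
            (r, "A"), False
        )

    fooled = (
        all(ref_fooled(r) for r in refs) if mode == "all"
        else any(ref_fooled(r) for r in refs)
    ) if refs else False

    out = set()
    taxa = sorted({t for (t, _p) in library_presence})
    for taxon in taxa:
        if taxon in refs:
            continue
        lacks_a = not library_presence.get((taxon, "A"), False)
        has_b = library_presence.get((taxon, "B"), False)
        if lacks_a and has_b and fooled:
            out.add(taxon)
    return out


# ---------------------------------------------------------------------------
# a screening-ready multi-partition dataset with known defects


@dataclass
class ScreeningBundle:
    """Simulated pipeline inputs with ground truth for validation."""

    partitions: list[PartitionAlignment]
    trees: list["SupportTree"]
    best_hits: "BestHitTable"
    paralog_partition: str
    misassigned_taxa: set[str]
    contaminated_partitions: list[str]
    contaminated_pair: tuple[str, str]


def simulate_screening_bundle(
    seed: int,
    n_partitions: int = 6,
    n_sites: int = 200,
    n_boot: int = 100,
    contamination_fraction: float = 0.05,
    config: SimConfig | None = None,
) -> ScreeningBundle:
    """A multi-partition dataset with one induced paralog clade and an
    injected contaminant pair.

    One partition carries the reciprocal-lack defect: the primer and
    reference libraries hold only paralog A while two non-primer taxa hold
    only B, so the emulated orthology assignment files their B copies
    under A.  The remaining partitions are clean single-copy genes.
    Cross-contamination is injected by copying one taxon's sequence over
    another's in ``ceil(fraction * n_partitions)`` of the clean
    partitions.  Gene labels in the best-hit table come from scoring each
    assigned sequence against the reference genome's two labelled copies,
    so the label evidence is generated by the same similarity machinery
    the emulator uses, not read off the truth.
    """
    base = config or SimConfig(seed=seed, n_sites=n_sites)
    scorer = make_alignment_scorer()
    species = dendropy.Tree.get(
        data=base.species_tree, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    taxa = sorted(l.taxon.label for l in species.leaf_node_iter())
    primer = sorted(base.primer_taxa)
    refs = sorted(base.reference_taxa)
    non_primer = [t for t in taxa if t not in base.primer_taxa]
    misassigned = set(non_primer[-2:])
    donor, recipient = non_primer[0], non_primer[1]

    partitions: list[PartitionAlignment] = []
    trees: list[SupportTree] = []
    best_hits = BestHitTable()

    paralog_pid = "sim00"
    for i in range(n_partitions):
        pid = f"sim{i:02d}"
        fam = simulate_gene_family(
            replace(base, seed=seed * 1000 + i, loss_prob=0.0, n_sites=n_sites)
        )
        if pid == paralog_pid:
            validate_score_separation(fam, scorer)
            # reciprocal-lack library masks: everyone has A except the
            # misassigned taxa, which have only B
            libraries = {}
            for taxon in taxa:
                libraries[taxon] = {}
                for p in PARALOGS:
                    present = (p == "B") if taxon in misassigned else (p == "A")
                    fam.truth.library_presence[(taxon, p)] = present
                    if present:
                        libraries[taxon][fam.seq_id(taxon, p)] = fam.sequences[(taxon, p)]
            core = {t: (fam.seq_id(t, "A"), fam.sequences[(t, "A")]) for t in primer}
            assigned = emulate_orthology_assignment(libraries, core, refs, scorer)
            expected = misassignment_truth(fam.truth.library_presence, refs)
            got = {
                t for t, r in assigned.items()
                if r.accepted and r.forward_hit is not None
                and fam.truth.paralog_of[r.forward_hit] == "B"
            }
            if got != expected or expected != misassigned:
                raise RuntimeError(
                    f"emulator/truth mismatch in bundle: {got} vs {expected}"
                )
            rows = {
                t: libraries[t][r.forward_hit]
                for t, r in assigned.items()
                if r.accepted and r.forward_hit is not None
            }
            for t in primer:
                rows.setdefault(t, fam.sequences[(t, "A")])
        else:
            rows = {t: fam.sequences[(t, "A")] for t in taxa}
        # gene labels by similarity against the reference genome's copies
        ref_genome = {
            f"{pid} paralog A": fam.sequences[(refs[0], "A")],
            f"{pid} paralog B": fam.sequences[(refs[0], "B")],
        }
        for taxon, seq in rows.items():
            label, score = max(
                ((lab, scorer(seq, ref_seq)) for lab, ref_seq in ref_genome.items()),
                key=lambda kv: kv[1],
            )
            best_hits.rows.append(BestHitRow(
                query_taxon=taxon, partition_id=pid,
                subject_accession=label.replace(" ", "_"),
                gene_label=label,
                evalue=2.0 ** (-max(score, 0.0)), bitscore=score,
            ))
        partitions.append(PartitionAlignment(pid, rows))

    # inject contamination into clean partitions: recipient row := donor row
    clean_pids = [p.partition_id for p in partitions if p.partition_id != paralog_pid]
    n_contam = math.ceil(contamination_fraction * len(partitions))
    contam_pids = clean_pids[:n_contam]
    for i, part in enumerate(partitions):
        if part.partition_id in contam_pids:
            seqs = dict(part.sequences)
            seqs[recipient] = seqs[donor]
            partitions[i] = PartitionAlignment(part.partition_id, seqs)

    for part in partitions:
        trees.append(build_partition_tree(part, n_boot=n_boot, seed=seed + 17))

    return ScreeningBundle(
        partitions=partitions,
        trees=trees,
        best_hits=best_hits,
        paralog_partition=paralog_pid,
        misassigned_taxa=misassigned,
        contaminated_partitions=contam_pids,
        contaminated_pair=(donor, recipient),
    )


# ---------------------------------------------------------------------------
# trees with bootstrap supports on simulated partitions


def _p_distance_matrix(alignment: PartitionAlignment, cols: np.ndarray | None = None):
    taxa = list(alignment.taxa)
    arrays = {
        t: np.frombuffer(alignment.sequences[t].encode(), dtype="S1")
        for t in taxa
    }
    if cols is not None:
        arrays = {t: a[cols] for t, a in arrays.items()}
    n = len(taxa)
    D = np.zeros((n, n))
    missing = {b"-", b"X"}
    for i in range(n):
        ai = arrays[taxa[i]]
        oki = ~np.isin(ai, [b"-", b"X"])
        for j in range(i + 1, n):
            aj = arrays[taxa[j]]
            ok = oki & ~np.isin(aj, [b"-", b"X"])
            total = ok.sum()
            if total == 0:
                d = 1.0
            else:
                d = float((ai[ok] != aj[ok]).sum() / total)
            D[i, j] = D[j, i] = d
    return taxa, D


def build_partition_tree(
    alignment: PartitionAlignment,
    n_boot: int = 100,
    seed: int = 0,
) -> SupportTree:
    """Neighbor-joining tree with bootstrap supports for one partition.

    Distances are uncorrected p-distances over shared non-missing columns;
    supports are the percentage of ``n_boot`` column-resampled NJ trees
    containing each bipartition of the full-data tree.  Negative NJ branch
    lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(alignment.taxa) < 4:
        raise ValueError("need at least 4 taxa for an informative tree")

    def nj_tree(cols=None) -> SupportTree:
        taxa, D = _p_distance_matrix(alignment, cols)
        dm = DistanceMatrix(D, ids=taxa)
        newick = str(nj(dm)).strip()
        dt = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        for edge in dt.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
        return SupportTree(dt, alignment.partition_id)

    main = nj_tree()
    rng = _rng(seed)
    counts: dict[frozenset[frozenset[str]], int] = {
        bp: 0 for bp in main.bipartitions()
    }
    for _ in range(n_boot):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        rep = nj_tree(cols)
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_taxa = main.taxa
    for node in main.dendropy_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        bp = frozenset({side, all_taxa - side})
        node.support = round(100 * counts.get(bp, 0) / n_boot)
    return main
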