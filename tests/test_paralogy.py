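"""Best-hit selection, paralogy assessment, prune decisions, and the
branch-length diagnostics, including reproduction of the case-study cells."""

import numpy as np
import pytest

from paraprune.datasets import (
    PRIMER_TAXA,
    branch_profile_tree,
    case_study_best_hits,
    case_study_clades,
)
from paraprune.paralogy import (
    assess_paralogy,
    assess_paralogy_multi,
    best_hit_label,
    branch_diagnostics,
    decide_prune_action,
)
from paraprune.tree import SupportTree
from paraprune.types import (
    ACTION_EXCLUDE_PARTITION,
    ACTION_NONE,
    ACTION_PRUNE_SEQUENCES,
    CATEGORY_CONTAMINATION,
    CATEGORY_INDETERMINATE,
    CATEGORY_NO_PARALOG,
    CATEGORY_POTENTIAL_PARALOG,
    BestHitRow,
    BestHitTable,
    FlaggedClade,
)

from conftest import random_support_tree


def table(*rows):
    t = BestHitTable()
    for taxon, label, evalue, bits in rows:
        t.rows.append(BestHitRow(taxon, "p", "acc", label, evalue, bits))
    return t


class TestBestHit:
    def test_minimal_evalue_wins(self):
        t = table(("T", "beta", 1e-62, 100.0), ("T", "alpha", 1e-40, 300.0))
        assert best_hit_label(t, "T", "p")[0] == "beta"

    def test_evalue_tie_broken_by_bitscore(self):
        t = table(("T", "alpha", 0.0, 310.0), ("T", "beta", 0.0, 290.0))
        assert best_hit_label(t, "T", "p")[0] == "alpha"

    def test_full_tie_broken_lexicographically(self):
        t = table(("T", "zeta", 1e-5, 50.0), ("T", "alpha", 1e-5, 50.0))
        assert best_hit_label(t, "T", "p")[0] == "alpha"

    def test_singleton(self):
        t = table(("T", "only", 1e-9, 42.0))
        assert best_hit_label(t, "T", "p") == ("only", 1e-9, 42.0)

    def test_no_rows_is_distinguished_no_hit(self):
        assert best_hit_label(BestHitTable(), "T", "p") == (None, None, None)


def clade(*taxa, pid="p"):
    return FlaggedClade(pid, frozenset(taxa), 99, 0.3)


class TestAssess:
    def test_uniform_labels_is_no_paralog(self):
        rec = assess_paralogy(
            clade("A", "B"),
            {"A": "NSA2 ribosome biogenesis homolog", "B": "NSA2 ribosome biogenesis homolog"},
            {"P1": "NSA2 ribosome biogenesis homolog"},
        )
        assert rec.category == CATEGORY_NO_PARALOG

    def test_clade_deviating_from_primer_consensus(self):
        rec = assess_paralogy(
            clade("A", "B"), {"A": "PSMA2", "B": "PSMA2"},
            {"P1": "PSMA8", "P2": "PSMA8"},
        )
        assert rec.category == CATEGORY_POTENTIAL_PARALOG

    def test_inconsistent_primers_trump_clade_labels(self):
        rec = assess_paralogy(
            clade("A", "B"), {"A": "alpha", "B": "alpha"},
            {"P1": "alpha", "P2": "beta"},
        )
        assert rec.category == CATEGORY_POTENTIAL_PARALOG

    def test_label_comparison_normalizes_whitespace_and_case(self):
        rec = assess_paralogy(
            clade("A"), {"A": "Heat  Shock 70"}, {"P1": "heat shock 70"}
        )
        assert rec.category == CATEGORY_NO_PARALOG

    def test_no_hit_member_ignored_but_noted(self):
        rec = assess_paralogy(
            clade("A", "B"), {"A": "x", "B": None}, {"P1": "x"}
        )
        assert rec.category == CATEGORY_NO_PARALOG
        assert "no-hit" in rec.notes

    def test_all_no_hit_is_indeterminate(self):
        rec = assess_paralogy(clade("A"), {"A": None}, {"P1": None})
        assert rec.category == CATEGORY_INDETERMINATE
        assert decide_prune_action(rec, {"P1"}).kind == ACTION_NONE

    def test_multi_reference_any_split_decides(self):
        per_ref = {
            "Bt": ({"A": "CETN1", "B": "CETN1"}, {"P1": "CETN1"}),
            "Bf": ({"A": "CETN3", "B": "CETN3"}, {"P1": "CETN2"}),
        }
        rec = assess_paralogy_multi(clade("A", "B"), per_ref)
        assert rec.category == CATEGORY_POTENTIAL_PARALOG
        assert "Bf" in rec.notes


class TestDecide:
    def test_clean_primers_prune_only_deviating_members(self):
        rec = assess_paralogy(
            clade("S_armiger", "S_boa", "E_complanata", pid="22433"),
            {t: "PSMA2" for t in ("S_armiger", "S_boa", "E_complanata")},
            {t: "PSMA8" for t in PRIMER_TAXA},
        )
        act = decide_prune_action(rec, PRIMER_TAXA)
        assert act.kind == ACTION_PRUNE_SEQUENCES
        assert act.target_taxa == frozenset({"S_armiger", "S_boa", "E_complanata"})

    def test_inconsistent_primers_exclude_partition(self):
        rec = assess_paralogy(
            clade("U_caupo", "L_gigantea", pid="21904"),
            {"U_caupo": "GDI beta", "L_gigantea": "GDI beta"},
            {"C_teleta": "GDI alpha", "H_robusta": "GDI beta"},
        )
        assert decide_prune_action(rec, PRIMER_TAXA).kind == ACTION_EXCLUDE_PARTITION

    def test_affected_primer_inside_clade_excludes_partition(self):
        rec = assess_paralogy(
            clade("L_gigantea", "T_lageniformis", pid="24126"),
            {"L_gigantea": "XIRP2", "T_lageniformis": "LASP1"},
            {"C_teleta": "CSRP3", "H_robusta": "CSRP3"},
        )
        assert decide_prune_action(rec, PRIMER_TAXA).kind == ACTION_EXCLUDE_PARTITION

    def test_unaffected_primer_inside_clade_prunes_only_deviants(self):
        # complement-side artifact: primers sit in the clade but match the
        # consensus, so only the deviating members are pruned
        rec = assess_paralogy(
            clade("L_gigantea", "C_teleta", "X", "Y"),
            {"L_gigantea": "gene A", "C_teleta": "gene A",
             "X": "gene B", "Y": "gene B"},
            {"L_gigantea": "gene A", "C_teleta": "gene A", "H_robusta": "gene A"},
        )
        act = decide_prune_action(rec, PRIMER_TAXA)
        assert act.kind == ACTION_PRUNE_SEQUENCES
        assert act.target_taxa == frozenset({"X", "Y"})

    def test_no_paralog_means_no_action(self):
        rec = assess_paralogy(clade("A"), {"A": "x"}, {"P": "x"})
        assert decide_prune_action(rec, {"P"}).kind == ACTION_NONE


class TestBranchDiagnostics:
    def test_equal_internal_branches_give_ratio_one(self):
        t = SupportTree.parse(
            "((A:1,B:1)99:0.3,(C:1,D:1)99:0.3,E:1);", "p"
        )
        d = branch_diagnostics(t, clade("A", "B"))
        assert d.branch_ratio == pytest.approx(1.0)

    def test_single_internal_edge_ratio_is_one(self):
        t = SupportTree.parse("((A:1,B:1)100:0.7,C:1,D:1);", "p")
        assert branch_diagnostics(t, clade("A", "B")).branch_ratio == pytest.approx(1.0)

    def test_non_edge_clade_is_hard_error(self):
        t = SupportTree.parse("((A:1,B:1)100:0.7,C:1,D:1);", "p")
        with pytest.raises(KeyError):
            branch_diagnostics(t, clade("A", "C"))

    def test_printed_extreme_ratio_reconstructed(self):
        """A 17-leaf tree with leading branch 4.1762 and mean internal
        branch 0.31166 reproduces the tabulated ratio 13.40."""
        case = next(
            c for c in case_study_clades()
            if c.partition_id == "22433" and c.clade_key == "A"
        )
        tree = branch_profile_tree(case)
        d = branch_diagnostics(tree, case.flagged())
        assert d.leading_branch_length == pytest.approx(4.1762)
        assert d.branch_ratio == pytest.approx(13.40, abs=5e-3)

    def test_matches_brute_force_on_random_trees(self, rng):
        for i in range(5):
            t = random_support_tree(rng, 10, f"p{i}")
            edges = t.internal_edges()
            lengths = [e.length for e in edges]
            for e in edges[:3]:
                d = branch_diagnostics(t, FlaggedClade(f"p{i}", e.side, 99, e.length))
                assert d.branch_ratio == pytest.approx(
                    e.length / (sum(lengths) / len(lengths))
                )

    def test_scale_invariance(self, rng):
        t = random_support_tree(rng, 8, "p")
        e = t.internal_edges()[0]
        before = branch_diagnostics(t, FlaggedClade("p", e.side, 99, e.length))
        for edge in t.dendropy_tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 3.7
        e2 = t.find_edge(e.side)
        after = branch_diagnostics(t, FlaggedClade("p", e2.side, 99, e2.length))
        assert after.branch_ratio == pytest.approx(before.branch_ratio)


class TestCaseStudyCells:
    """The classifier reproduces every assessment and action of the bundled
    case-study screen (10 contamination, 10 potential paralog, 7 clean)."""

    @pytest.mark.parametrize(
        "case",
        [c for c in case_study_clades() if c.category != CATEGORY_CONTAMINATION],
        ids=lambda c: f"{c.partition_id}-{c.clade_key}",
    )
    def test_assessment_and_action_cells(self, case):
        rec = assess_paralogy(case.flagged(), case.clade_labels(), case.primer_labels())
        assert rec.category == case.category
        act = decide_prune_action(rec, PRIMER_TAXA)
        assert act.kind == case.action
        if case.prune_targets:
            assert act.target_taxa == frozenset(case.prune_targets)

    def test_labels_via_best_hit_table(self):
        """Feeding the tabulated hits through best-hit selection gives the
        same labels the assessment used."""
        hits = case_study_best_hits()
        for case in case_study_clades():
            for taxon, (label, evalue) in case.clade_hits.items():
                got_label, got_e, _ = best_hit_label(hits, taxon, case.partition_id)
                assert got_label == label
                assert got_e == pytest.approx(evalue)

    def test_determinism(self):
        case = case_study_clades()[12]
        recs = [
            assess_paralogy(case.flagged(), case.clade_labels(), case.primer_labels())
            for _ in range(3)
        ]
        assert len({r.category for r in recs}) == 1
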