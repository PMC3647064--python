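"""Simulator: loss/sampling statistics, contamination injection, and the
orthology-assignment emulator against its closed-form truth condition."""

import math

import numpy as np
import pytest

from paraprune.simulate import (
    PARALOGS,
    SimConfig,
    emulate_orthology_assignment,
    inject_contamination,
    make_alignment_scorer,
    misassignment_truth,
    sample_est_library,
    simulate_gene_family,
    validate_score_separation,
)


@pytest.fixture(scope="module")
def scorer():
    return make_alignment_scorer()


class TestGeneFamily:
    def test_no_loss_keeps_both_paralogs_everywhere(self):
        fam = simulate_gene_family(SimConfig(seed=1, loss_prob=0.0, n_sites=80))
        assert all(fam.truth.genome_presence.values())
        assert len(fam.sequences) == 16

    def test_same_seed_is_byte_identical(self):
        a = simulate_gene_family(SimConfig(seed=9, n_sites=60))
        b = simulate_gene_family(SimConfig(seed=9, n_sites=60))
        assert a.sequences == b.sequences
        assert a.truth.genome_presence == b.truth.genome_presence

    def test_presence_frequency_matches_closed_form(self):
        """Per-branch loss q on a k-branch root-to-tip path: presence
        frequency ~ (1-q)^k within 3 sigma over 500 replicates."""
        q = 0.15
        # T1 sits 3 branches below the species root, plus the paralog stem
        k = 3 + 1
        expected = (1 - q) ** k
        hits = 0
        n = 500
        for seed in range(n):
            fam = simulate_gene_family(
                SimConfig(seed=seed, loss_prob=q, n_sites=4, max_retries=10**6)
            )
            hits += fam.truth.genome_presence[("T1", "A")]
        p_hat = hits / n
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(p_hat - expected) <= 3 * sigma

    def test_total_loss_raises_after_retries(self):
        with pytest.raises(RuntimeError):
            simulate_gene_family(
                SimConfig(seed=3, loss_prob=1.0, n_sites=4, max_retries=5)
            )


class TestLibrarySampling:
    def test_full_detection_reproduces_genome_content(self):
        fam = simulate_gene_family(SimConfig(seed=2, loss_prob=0.3, n_sites=40))
        libs = sample_est_library(fam, detection_prob=1.0)
        n_lib = sum(len(v) for v in libs.values())
        assert n_lib == len(fam.sequences)
        assert fam.truth.library_presence == {
            k: v for k, v in fam.truth.genome_presence.items()
        }

    def test_zero_detection_gives_empty_libraries(self):
        fam = simulate_gene_family(SimConfig(seed=2, loss_prob=0.0, n_sites=40))
        libs = sample_est_library(fam, detection_prob=0.0)
        assert all(len(v) == 0 for v in libs.values())

    def test_inclusion_rate_within_binomial_ci(self):
        """p=0.3 over ~1000 Bernoulli trials lands in the 99% CI."""
        p = 0.3
        total = hits = 0
        for seed in range(63):  # 63 families x 16 transcripts ~ 1000 trials
            fam = simulate_gene_family(
                SimConfig(seed=seed, loss_prob=0.0, n_sites=4)
            )
            libs = sample_est_library(fam, detection_prob=p, seed=seed)
            total += 16
            hits += sum(len(v) for v in libs.values())
        se = math.sqrt(p * (1 - p) / total)
        assert abs(hits / total - p) <= 2.58 * se


class TestContaminationInjection:
    DONOR = {f"d{i}": "MKVL" for i in range(1000)}

    def test_zero_fraction_is_identity(self):
        recip, injected = inject_contamination(self.DONOR, {"r": "AAAA"}, 0.0, 1)
        assert recip == {"r": "AAAA"} and injected == set()

    def test_five_percent_of_thousand_copies_fifty(self):
        recip, injected = inject_contamination(self.DONOR, {}, 0.05, 1)
        assert len(injected) == 50

    def test_copies_are_verbatim_and_tagged(self):
        donor = {"d1": "MKVLITAE", "d2": "WWWWYYYY"}
        recip, injected = inject_contamination(donor, {}, 1.0, 1)
        assert injected == {"contam:d1", "contam:d2"}
        assert recip["contam:d1"] == donor["d1"]
        assert recip["contam:d2"] == donor["d2"]


def masked_libraries(fam, masks):
    """Libraries built from explicit (taxon, paralog) -> bool masks."""
    libs = {}
    for taxon in sorted({t for (t, _p) in fam.truth.genome_presence}):
        libs[taxon] = {}
        for p in PARALOGS:
            fam.truth.library_presence[(taxon, p)] = masks.get((taxon, p), False)
            if masks.get((taxon, p), False):
                libs[taxon][fam.seq_id(taxon, p)] = fam.sequences[(taxon, p)]
    return libs


@pytest.fixture(scope="module")
def family():
    fam = simulate_gene_family(SimConfig(seed=11, loss_prob=0.0, n_sites=150))
    validate_score_separation(fam)
    return fam


class TestEmulator:
    def core(self, fam, taxa=("T1", "T2")):
        return {t: (fam.seq_id(t, "A"), fam.sequences[(t, "A")]) for t in taxa}

    def test_reciprocal_lack_misassigns(self, family, scorer):
        """Query holds only B, the single reference only A: B is filed
        under A."""
        masks = {(t, "A"): True for t in [f"T{i}" for i in range(1, 8)]}
        masks[("T8", "A")] = False
        masks[("T8", "B")] = True
        masks[("T1", "B")] = False
        libs = masked_libraries(family, masks)
        res = emulate_orthology_assignment(libs, self.core(family), ["T1"], scorer)
        assert res["T8"].forward_hit == "T8|B"
        assert res["T8"].accepted

    def test_second_reference_retaining_b_blocks_assignment(self, family, scorer):
        masks = {(t, "A"): True for t in [f"T{i}" for i in range(1, 8)]}
        masks[("T8", "A")] = False
        masks[("T8", "B")] = True
        masks[("T2", "B")] = True  # second reference still holds B
        libs = masked_libraries(family, masks)
        res = emulate_orthology_assignment(
            libs, self.core(family), ["T1", "T2"], scorer, mode="all"
        )
        assert not res["T8"].accepted

    def test_query_with_both_paralogs_assigns_a(self, family, scorer):
        masks = {(t, "A"): True for t in [f"T{i}" for i in range(1, 9)]}
        masks[("T8", "B")] = True
        libs = masked_libraries(family, masks)
        res = emulate_orthology_assignment(libs, self.core(family), ["T1"], scorer)
        assert res["T8"].forward_hit == "T8|A"
        assert res["T8"].accepted

    def test_empty_query_library_yields_no_assignment(self, family, scorer):
        masks = {("T1", "A"): True, ("T2", "A"): True}
        libs = masked_libraries(family, masks)
        res = emulate_orthology_assignment(libs, self.core(family), ["T1"], scorer)
        assert res["T8"].forward_hit is None and not res["T8"].accepted


class TestTruthCondition:
    def test_reference_retaining_b_empties_expected_set(self):
        masks = {("T1", "A"): True, ("T1", "B"): True, ("T8", "B"): True}
        assert misassignment_truth(masks, ["T1"]) == set()

    def test_reciprocal_lack_masks_give_taxa_set_two(self):
        masks = {("T1", "A"): True, ("T2", "A"): True,
                 ("T7", "B"): True, ("T8", "B"): True}
        assert misassignment_truth(masks, ["T1", "T2"]) == {"T7", "T8"}

    def test_emulator_matches_closed_form_on_random_masks(self, scorer):
        """100 seeded random library masks: the emulated assignment equals
        the closed-form reciprocal-lack set in every replicate."""
        fam = simulate_gene_family(SimConfig(seed=21, loss_prob=0.0, n_sites=150))
        validate_score_separation(fam, scorer)
        core = {t: (fam.seq_id(t, "A"), fam.sequences[(t, "A")]) for t in ("T1", "T2")}
        refs = ["T1", "T2"]
        taxa = [f"T{i}" for i in range(1, 9)]
        mismatches = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            masks = {(t, p): bool(rng.random() < 0.6) for t in taxa for p in PARALOGS}
            for r in refs:
                masks[(r, "A")] = True  # core taxa always carry their core gene
            libs = masked_libraries(fam, masks)
            res = emulate_orthology_assignment(libs, core, refs, scorer, mode="all")
            got = {
                t for t, r in res.items()
                if r.accepted and r.forward_hit is not None
                and fam.truth.paralog_of[r.forward_hit] == "B"
            }
            expected = misassignment_truth(fam.truth.library_presence, refs, mode="all")
            if got != expected:
                mismatches += 1
        assert mismatches == 0

    def test_misassignment_rate_non_increasing_in_reference_count(self):
        """Monte-Carlo over random masks: adding reference taxa never
        increases the expected-misassignment frequency."""
        taxa = [f"T{i}" for i in range(1, 9)]
        rates = []
        for refs in (["T1"], ["T1", "T2"], ["T1", "T2", "T3"]):
            count = 0
            for seed in range(400):
                rng = np.random.default_rng(10_000 + seed)
                masks = {(t, p): bool(rng.random() < 0.5) for t in taxa for p in PARALOGS}
                for r in refs:
                    masks[(r, "A")] = True
                count += len(misassignment_truth(masks, refs, mode="all"))
            rates.append(count)
        assert rates[0] >= rates[1] >= rates[2]
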