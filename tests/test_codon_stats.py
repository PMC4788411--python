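"""Codon-usage table construction and per-gene diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidkit import (
    CdsRecord,
    CodonUsageTable,
    build_usage_table,
    classify_codon,
    compare_synonymous,
    diagnose,
    gc3,
    mean_freq_diff,
)
from plastidkit.codon_stats import (
    ALL_CODONS,
    STOP_SYMBOL,
    gene_usage_frequencies,
    synonym_families,
)
from plastidkit.errors import (
    AlphabetError,
    FrameError,
    NonSynonymousError,
    PlastidkitError,
)
from plastidkit.synth import gen_synonymous_pair, UsageProfileSpec

from conftest import random_cds


class TestCdsRecord:
    def test_uppercases_and_validates(self):
        rec = CdsRecord("x", "atgaaataa")
        assert rec.sequence == "ATGAAATAA"
        assert rec.n_codons == 3

    @pytest.mark.parametrize("bad", ["ATGAA", "", "ATGA"])
    def test_frame_violation_rejected(self, bad):
        with pytest.raises(FrameError):
            CdsRecord("x", bad)

    def test_ambiguity_codes_are_hard_errors(self):
        with pytest.raises(AlphabetError):
            CdsRecord("x", "ATGNNNTAA")


class TestGc3:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAAAAA", 0.0), ("GGGGGG", 1.0), ("AAGAAA", 0.5), ("ATGAAATAA", 1 / 3)],
    )
    def test_definition(self, seq, expected):
        assert gc3(CdsRecord("x", seq)) == pytest.approx(expected)

    def test_agrees_with_bruteforce_third_base_count(self, rng):
        for _ in range(200):
            cds = random_cds(rng, 30)
            brute = sum(
                1
                for i in range(2, len(cds.sequence), 3)
                if cds.sequence[i] in "GC"
            ) / (len(cds.sequence) // 3)
            assert gc3(cds) == pytest.approx(brute)


codons_st = st.sampled_from(ALL_CODONS)


class TestGc3Properties:
    @settings(max_examples=200, derandomize=True)
    @given(st.lists(codons_st, min_size=1, max_size=100))
    def test_gc3_equals_third_base_fraction_for_any_codon_list(self, codons):
        cds = CdsRecord("h", "".join(codons))
        brute = sum(c[2] in "GC" for c in codons) / len(codons)
        assert gc3(cds) == pytest.approx(brute, abs=1e-15)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(codons_st, min_size=2, max_size=60), st.randoms(use_true_random=False))
    def test_gc3_invariant_under_codon_permutation(self, codons, rnd):
        shuffled = list(codons)
        rnd.shuffle(shuffled)
        assert gc3(CdsRecord("a", "".join(codons))) == pytest.approx(
            gc3(CdsRecord("b", "".join(shuffled)))
        )


class TestBuildUsageTable:
    def test_single_cds_families(self):
        table = build_usage_table([CdsRecord("x", "ATGAAATAA")])
        f = table.freq_among_synonyms
        assert f["ATG"] == 1.0
        assert f["AAA"] == 1.0 and f["AAG"] == 0.0
        assert f["TAA"] == 1.0 and f["TAG"] == 0.0 and f["TGA"] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(PlastidkitError):
            build_usage_table([])

    def test_every_triplet_present_once(self, reference_table):
        assert sorted(reference_table.counts) == sorted(ALL_CODONS)

    def test_observed_family_frequencies_sum_to_one(self, reference_table):
        fams = synonym_families(reference_table.genetic_code_id)
        for aa, codons in fams.items():
            total = sum(reference_table.freq_among_synonyms[c] for c in codons)
            if aa in reference_table.unobserved_families:
                assert total == 0.0
            else:
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_frequency_normalization_many_random_tables(self, rng):
        fams = synonym_families(11)
        for _ in range(300):
            counts = {c: int(rng.integers(0, 50)) for c in ALL_CODONS}
            table = CodonUsageTable.from_counts(counts)
            for aa, codons in fams.items():
                total = sum(table.freq_among_synonyms[c] for c in codons)
                if sum(counts[c] for c in codons) > 0:
                    assert abs(total - 1.0) < 1e-12

    def test_exclude_stops_flags_stop_family(self):
        table = build_usage_table(
            [CdsRecord("x", "ATGAAATAA")], include_stops=False
        )
        assert STOP_SYMBOL in table.unobserved_families
        assert table.counts["TAA"] == 0

    def test_synthetic_profile_recovered_within_binomial_error(
        self, at_rich_profile, reference_cds_set, reference_table
    ):
        """Frequencies of a generated CDS set match the generating profile."""
        fams = synonym_families(11)
        counts = reference_table.counts
        for aa, codons in fams.items():
            if aa == STOP_SYMBOL:
                continue
            n_fam = sum(counts[c] for c in codons)
            if n_fam < 50:
                continue
            for c in codons:
                p = at_rich_profile.families[aa][c]
                se = np.sqrt(max(p * (1 - p), 1e-9) / n_fam)
                observed = reference_table.freq_among_synonyms[c]
                assert abs(observed - p) <= max(3 * se, 0.02)


class TestClassifyCodon:
    def test_single_member_family_always_optimal(self, reference_table):
        assert classify_codon("ATG", reference_table) == "optimal"
        assert classify_codon("TGG", reference_table) == "optimal"
        # even against a table in which Met/Trp never occur
        empty_met = CodonUsageTable.from_counts({"AAA": 5})
        assert classify_codon("ATG", empty_met) == "optimal"

    def test_rare_boundary_is_inclusive(self):
        table = CodonUsageTable.from_counts({"AAA": 90, "AAG": 10})
        assert classify_codon("AAG", table) == "rare"
        assert classify_codon("AAA", table) == "optimal"

    def test_intermediate_band(self):
        table = CodonUsageTable.from_counts({"GGA": 60, "GGT": 25, "GGC": 10, "GGG": 5})
        assert classify_codon("GGA", table) == "optimal"
        assert classify_codon("GGT", table) == "intermediate"
        assert classify_codon("GGC", table) == "rare"
        assert classify_codon("GGG", table) == "rare"

    def test_tie_broken_lexicographically_and_flagged(self):
        table = CodonUsageTable.from_counts({"GGA": 50, "GGT": 50})
        assert classify_codon("GGA", table) == "optimal"
        assert classify_codon("GGT", table) != "optimal"
        assert "G" in table.tied_families

    def test_exactly_one_optimal_per_observed_family(self, reference_table):
        fams = synonym_families(11)
        for aa, codons in fams.items():
            if aa in reference_table.unobserved_families:
                continue
            n_opt = sum(
                classify_codon(c, reference_table) == "optimal" for c in codons
            )
            assert n_opt == 1

    def test_invalid_triplet_rejected(self, reference_table):
        with pytest.raises(PlastidkitError):
            classify_codon("AXA", reference_table)


class TestMeanFreqDiff:
    def test_zero_when_gene_matches_table(self):
        cds = CdsRecord("x", "ATGAAATAA")
        table = build_usage_table([cds])
        for variant in ("position", "triplet_uniform", "gene_present"):
            assert mean_freq_diff(cds, table, variant) == pytest.approx(0.0)

    def test_unknown_variant_rejected(self, reference_table):
        with pytest.raises(PlastidkitError):
            mean_freq_diff(CdsRecord("x", "ATGAAATAA"), reference_table, "bogus")

    def test_position_variant_equals_occurrence_weighted_sum(
        self, rng, reference_table
    ):
        cds = random_cds(rng, 40)
        f_gene = gene_usage_frequencies(cds)
        f_ref = reference_table.freq_among_synonyms
        by_hand = (
            100.0
            * sum(abs(f_gene[c] - f_ref[c]) for c in cds.codons)
            / cds.n_codons
        )
        assert mean_freq_diff(cds, reference_table) == pytest.approx(by_hand)


class TestDiagnose:
    def test_report_is_consistent(self, rng, reference_table):
        cds = random_cds(rng, 50)
        rep = diagnose(cds, reference_table)
        assert len(rep.per_codon_classes) == cds.n_codons
        assert rep.n_optimal + rep.n_rare <= cds.n_codons
        assert rep.frac_optimal == pytest.approx(rep.n_optimal / cds.n_codons)
        assert 0.0 <= rep.gc3 <= 1.0

    def test_all_optimal_gene(self, reference_table):
        codons = [reference_table.optimal_codon("K")] * 20
        seq = "ATG" + "".join(codons) + reference_table.optimal_codon(STOP_SYMBOL)
        rep = diagnose(CdsRecord("opt", seq), reference_table)
        assert rep.frac_optimal == 1.0
        assert rep.n_rare == 0

    def test_codon_permutation_invariance(self, rng, reference_table):
        """Multiset statistics are invariant under codon-level shuffles."""
        cds = random_cds(rng, 60)
        codons = list(cds.codons)
        perm = list(rng.permutation(len(codons)))
        shuffled = CdsRecord("shuf", "".join(codons[i] for i in perm))
        a, b = diagnose(cds, reference_table), diagnose(shuffled, reference_table)
        assert a.gc3 == pytest.approx(b.gc3)
        assert (a.n_optimal, a.n_rare) == (b.n_optimal, b.n_rare)
        assert a.mean_freq_diff == pytest.approx(b.mean_freq_diff)


class TestCompareSynonymous:
    def test_self_comparison_is_zero(self, rng):
        cds = random_cds(rng)
        summary = compare_synonymous(cds, cds)
        assert summary.n_changed == 0
        assert sum(summary.per_segment) == 0

    def test_constructed_pair_counts_match_truth(self, at_rich_profile):
        a, b, changed = gen_synonymous_pair(
            n_codons=50,
            changes_per_segment=[4, 7, 2],
            segment_size=20,
            profile=at_rich_profile,
            rng_seed=5,
        )
        summary = compare_synonymous(a, b, segment_size=20)
        assert summary.n_changed == 13
        assert summary.per_segment == (4, 7, 2)
        assert summary.changed_positions == changed

    def test_symmetry(self, at_rich_profile):
        a, b, _ = gen_synonymous_pair(40, [3, 3], 20, at_rich_profile, rng_seed=9)
        s_ab = compare_synonymous(a, b, segment_size=20)
        s_ba = compare_synonymous(b, a, segment_size=20)
        assert s_ab.n_changed == s_ba.n_changed
        assert s_ab.per_segment == s_ba.per_segment

    def test_per_segment_sums_to_total(self, at_rich_profile):
        a, b, _ = gen_synonymous_pair(45, [5, 5, 1], 20, at_rich_profile, rng_seed=2)
        s = compare_synonymous(a, b, segment_size=20)
        assert sum(s.per_segment) == s.n_changed

    def test_unequal_length_rejected(self):
        with pytest.raises(PlastidkitError):
            compare_synonymous(
                CdsRecord("a", "ATGAAATAA"), CdsRecord("b", "ATGTAA")
            )

    def test_non_synonymous_difference_rejected_with_positions(self):
        a = CdsRecord("a", "ATGAAATAA")
        b = CdsRecord("b", "ATGGAATAA")  # K2E
        with pytest.raises(NonSynonymousError) as err:
            compare_synonymous(a, b)
        assert err.value.positions == [2]


class TestTsvRoundTrip:
    def test_lossless(self, tmp_path, reference_table):
        path = tmp_path / "table.tsv"
        reference_table.to_tsv(path)
        back = CodonUsageTable.from_tsv(path)
        assert back.counts == dict(reference_table.counts)
        assert back.genetic_code_id == reference_table.genetic_code_id
        assert back.n_cds == reference_table.n_cds
        for c in ALL_CODONS:
            assert back.freq_among_synonyms[c] == pytest.approx(
                reference_table.freq_among_synonyms[c], abs=1e-12
            )

    def test_tsv_marks_optimal_and_rare(self, tmp_path):
        table = CodonUsageTable.from_counts({"AAA": 90, "AAG": 10})
        path = tmp_path / "t.tsv"
        table.to_tsv(path)
        rows = {
            line.split("\t")[0]: line.split("\t")
            for line in path.read_text().splitlines()
            if not line.startswith(("#", "codon"))
        }
        assert rows["AAA"][4] == "True" and rows["AAA"][5] == "False"
        assert rows["AAG"][4] == "False" and rows["AAG"][5] == "True"
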