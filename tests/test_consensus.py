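"""Consensus base/quality rules, merged-read geometry and the per-pair workflow."""

import numpy as np
import pytest

from pestitch import (
    BaseFrequencies,
    QualityEncoding,
    Read,
    ReadPair,
    ScoringParams,
    ScoringTables,
    TestConfig,
    build_merged_read,
    merge_base,
    merge_pair,
    quality_to_error_prob,
    reverse_complement,
)
from pestitch.overlap import OverlapPlacement
from helpers import make_pair


def _pair_from_fragment(frag: str, read_len: int, qual: int = 40) -> ReadPair:
    """Error-free pair sequenced from both ends of a fragment (no padding)."""
    fwd = Read("f", frag[:read_len], np.full(min(read_len, len(frag)), qual))
    tail = frag[-read_len:]
    rev = reverse_complement(Read("rv", tail, np.full(len(tail), qual)))
    rev.id = "rv"
    return ReadPair(fwd, rev)


class TestMergeBase:
    def test_identical_bases_multiply_error_probabilities(self):
        assert merge_base("A", "A", 0.1, 0.01) == ("A", pytest.approx(0.001))

    def test_different_bases_keep_the_higher_quality_one(self):
        e30, e10 = quality_to_error_prob(30), quality_to_error_prob(10)
        base, e = merge_base("A", "C", e30, e10)
        assert base == "A" and e == e30

    def test_both_uncalled_keep_lower_quality(self):
        assert merge_base("N", "N", 0.2, 0.5) == ("N", 0.5)

    def test_single_uncalled_defers_to_called(self):
        assert merge_base("N", "G", 0.9, 0.05) == ("G", 0.05)
        assert merge_base("G", "N", 0.05, 0.9) == ("G", 0.05)

    def test_quality_tie_keeps_forward_base(self):
        assert merge_base("A", "C", 0.01, 0.01)[0] == "A"

    def test_identical_column_error_never_exceeds_either_input(self, rng):
        for _ in range(100):
            ex, ey = rng.uniform(1e-4, 1), rng.uniform(1e-4, 1)
            _, e = merge_base("T", "T", ex, ey)
            assert e <= min(ex, ey) + 1e-15


class TestBuildMergedRead:
    def test_reconstructs_fragment_through_standard_overlap(self, rng):
        frag = "".join(rng.choice(list("ACGT"), size=150))
        pair = _pair_from_fragment(frag, 100)
        placement = OverlapPlacement.from_offset(50, 100, 100)
        merged = build_merged_read(pair, placement)
        assert merged.bases == frag
        assert len(merged.quals) == 150
        assert merged.id == "f"

    def test_case_c_discards_read_through(self, rng):
        # 30-bp fragment, 40-bp reads padded with low-quality random bases
        frag = "".join(rng.choice(list("ACGT"), size=30))
        pad1 = "".join(rng.choice(list("ACGT"), size=10))
        pad2 = "".join(rng.choice(list("ACGT"), size=10))
        fwd = Read("f", frag + pad1, np.r_[np.full(30, 40), np.zeros(10, int)])
        rc_rev = Read("x", pad2 + frag, np.r_[np.zeros(10, int), np.full(30, 40)])
        pair = ReadPair(fwd, reverse_complement(rc_rev))
        placement = OverlapPlacement.from_offset(-10, 40, 40)
        merged = build_merged_read(pair, placement)
        assert merged.bases == frag
        assert len(merged) == placement.implied_fragment_len == 30

    def test_minimal_single_column_overlap_geometry(self):
        pair = _pair_from_fragment("ACGTACGTA", 5)  # fragment 9, reads 5, d=4, n=1
        placement = OverlapPlacement.from_offset(4, 5, 5)
        merged = build_merged_read(pair, placement)
        assert len(merged) == 5 + 5 - 1
        assert merged.bases == "ACGTACGTA"

    def test_consensus_qualities_sum_on_agreement_and_are_capped(self):
        fwd = Read("f", "AAAA", np.array([30, 30, 30, 60]))
        rc_rev = Read("x", "AAAA", np.array([20, 93, 30, 60]))
        pair = ReadPair(fwd, reverse_complement(rc_rev))
        placement = OverlapPlacement.from_offset(0, 4, 4)
        merged = build_merged_read(pair, placement, QualityEncoding(33, 93))
        assert list(merged.quals) == [50, 93, 60, 93]  # sums, capped at 93
        capped = build_merged_read(pair, placement, quality_cap=40)
        assert list(capped.quals) == [40, 40, 40, 40]

    def test_mismatch_keeps_winners_own_quality(self):
        fwd = Read("f", "AT", np.array([35, 10]))
        rc_rev = Read("x", "CT", np.array([12, 20]))
        pair = ReadPair(fwd, reverse_complement(rc_rev))
        merged = build_merged_read(pair, OverlapPlacement.from_offset(0, 2, 2))
        assert merged.bases[0] == "A" and merged.quals[0] == 35

    def test_inconsistent_placement_rejected(self):
        pair = _pair_from_fragment("ACGTACGT", 5)
        with pytest.raises(ValueError):
            build_merged_read(pair, OverlapPlacement(2, 10, 12))


class TestMergePair:
    def test_duplicate_pair_merges_full_length_significantly(self, uniform):
        frag = "ACGTTGCAACGTTGCAACGT"
        pair = _pair_from_fragment(frag, 20)
        result = merge_pair(pair, freqs=uniform,
                            test=TestConfig(mode="pvalue", cutoff=0.01, omega=10))
        assert result.status == "merged"
        assert result.merged.bases == frag
        assert result.p < 1e-6

    def test_independent_random_pairs_rarely_merge(self, rng, uniform):
        test = TestConfig(mode="pvalue", cutoff=0.01, omega=1)
        tables = ScoringTables(ScoringParams(), uniform)
        merged = sum(
            merge_pair(make_pair(rng, 100, 100), freqs=uniform, test=test,
                       tables=tables).status == "merged"
            for _ in range(150)
        )
        assert merged <= 6  # expected ~1% false positives at the 0.01 cutoff

    def test_unique_ten_base_overlap_with_test_disabled(self, rng):
        # fragment = left(90) + unique 10-mer overlap is implicit: reads share
        # exactly the last/first 10 bases of a 190-bp fragment
        frag = "".join(rng.choice(list("ACGT"), size=190))
        pair = _pair_from_fragment(frag, 100)
        result = merge_pair(pair, test=TestConfig(mode="disabled"), min_overlap=1)
        assert result.status == "merged"
        assert len(result.merged) == 190
        assert result.merged.bases == frag

    def test_no_candidate_when_omega_unreachable(self, uniform):
        pair = ReadPair(Read("f", "ACGTACGT", np.full(8, 30)),
                        Read("r", "ACG", np.full(3, 30)))
        result = merge_pair(pair, freqs=uniform, min_overlap=5)
        assert result.status == "unmerged"
        assert result.merged is None and np.isnan(result.assembly_score)

    def test_merged_length_always_implied_fragment_length(self, rng, uniform):
        tables = ScoringTables(ScoringParams(), uniform)
        for _ in range(100):
            pair = make_pair(rng, int(rng.integers(8, 30)), int(rng.integers(8, 30)))
            result = merge_pair(pair, freqs=uniform, tables=tables,
                                test=TestConfig(mode="disabled"))
            if result.status == "merged":
                assert len(result.merged) == result.placement.implied_fragment_len
                assert result.merged.quals.min() >= 0
                assert result.merged.quals.max() <= 93

    def test_table_and_scalar_oes_agree(self, rng, uniform):
        from pestitch.overlap import find_best_overlap, oes_score
        from pestitch import observed_expected_score

        params = ScoringParams()
        tables = ScoringTables(params, uniform)
        for _ in range(30):
            pair = make_pair(rng, 25, 25, n_prob=0.05)
            rc = reverse_complement(pair.reverse)
            best = find_best_overlap(pair, params, uniform, tables=tables, reverse_rc=rc)
            fast = oes_score(pair.forward, rc, best.placement, tables)
            slow = observed_expected_score(pair, best.placement, uniform, params)
            assert fast == pytest.approx(slow, abs=1e-9)
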