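"""Error model, base frequencies and posterior match probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pestitch import (
    BaseFrequencies,
    Read,
    ReadPair,
    ScoringParams,
    ScoringTables,
    base_posterior,
    error_prob_to_quality,
    estimate_base_frequencies,
    per_base_score,
    posterior_with_n,
    quality_to_error_prob,
    random_match_prob,
)
from helpers import posterior_match_oracle, posterior_n_oracle, random_freqs

prob = st.floats(0.0, 1.0, allow_nan=False)


def _read(bases, quals=None):
    return Read("r", bases, np.full(len(bases), 30) if quals is None else np.array(quals))


class TestQualityConversion:
    @pytest.mark.parametrize("q,e", [(0, 1.0), (10, 0.1), (40, 1e-4)])
    def test_phred_closed_form(self, q, e):
        assert quality_to_error_prob(q) == pytest.approx(e, rel=1e-12)

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            quality_to_error_prob(-1)

    def test_strictly_decreasing(self):
        e = quality_to_error_prob(np.arange(0, 94))
        assert np.all(np.diff(e) < 0)

    def test_error_to_quality_inverts_exact_powers(self):
        assert error_prob_to_quality(1e-4) == 40
        assert error_prob_to_quality(1e-3 * 1e-1) == 40
        assert error_prob_to_quality(1.0) == 0
        assert error_prob_to_quality(1e-30, max_quality=93) == 93  # capped


class TestBaseFrequencies:
    def test_counting_over_both_mates(self):
        pair = ReadPair(_read("AACG"), _read("TACG"))
        freqs = estimate_base_frequencies([pair])
        assert freqs.as_array() == pytest.approx([3 / 8, 2 / 8, 2 / 8, 1 / 8])

    def test_n_excluded_from_both_sides_of_ratio(self):
        pair = ReadPair(_read("NNNN"), _read("ANNN"))
        freqs = estimate_base_frequencies([pair])
        assert freqs.a == 1.0

    def test_all_n_is_an_error_suggesting_uniform(self):
        with pytest.raises(ValueError, match="uniform"):
            estimate_base_frequencies([ReadPair(_read("NN"), _read("NN"))])

    def test_uniform_generator_output_close_to_quarter(self):
        from pestitch import SimConfig, simulate_dataset

        pairs, _ = simulate_dataset(SimConfig(n_pairs=200, seed=11))
        freqs = estimate_base_frequencies(pairs)
        n = 200 * 2 * 100
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(freqs.as_array() - 0.25) < 3 * sigma + 1e-12)

    @pytest.mark.parametrize(
        "freq,q",
        [({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}, 0.25),
         ({"A": 1.0}, 1.0),
         ({"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}, 0.34)],
    )
    def test_random_match_prob_sum_of_squares(self, freq, q):
        assert random_match_prob(BaseFrequencies.from_mapping(freq)) == pytest.approx(q)


class TestPosteriors:
    def test_error_free_limits(self, uniform):
        assert base_posterior(True, 0.0, 0.0, uniform).p_true_match == 1.0
        assert base_posterior(False, 0.0, 0.0, uniform).p_true_match == 0.0

    @pytest.mark.parametrize("observed_match", [True, False])
    @pytest.mark.parametrize("e_x,e_y", [(0.1, 0.2), (0.01, 0.5), (0.3, 0.3), (1.0, 0.2)])
    def test_matches_enumeration_oracle(self, observed_match, e_x, e_y, uniform, rng):
        for freqs in (uniform, random_freqs(rng), random_freqs(rng)):
            got = base_posterior(observed_match, e_x, e_y, freqs).p_true_match
            want = posterior_match_oracle(observed_match, e_x, e_y, freqs)
            assert got == pytest.approx(want, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(m=st.booleans(), e_x=prob, e_y=prob)
    def test_normalization(self, m, e_x, e_y):
        post = base_posterior(m, e_x, e_y, BaseFrequencies.uniform())
        assert 0.0 <= post.p_true_match <= 1.0
        assert post.p_true_match + post.p_true_mismatch == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_error_probability(self, uniform):
        es = np.linspace(0.0, 0.74, 30)
        match = [base_posterior(True, e, 0.1, uniform).p_true_match for e in es]
        mismatch = [base_posterior(False, e, 0.1, uniform).p_true_match for e in es]
        assert np.all(np.diff(match) <= 1e-12)
        assert np.all(np.diff(mismatch) >= -1e-12)

    def test_informationless_point_recovers_prior(self, uniform, rng):
        # at e = 3/4 an observed base is uniform whatever the truth, so the
        # posterior must equal the prior q for any observation
        for freqs in (uniform, random_freqs(rng)):
            q = random_match_prob(freqs)
            for m in (True, False):
                assert base_posterior(m, 0.75, 0.75, freqs).p_true_match == pytest.approx(q)

    def test_out_of_range_error_prob_rejected(self, uniform):
        with pytest.raises(ValueError):
            base_posterior(True, -0.1, 0.5, uniform)


class TestPosteriorWithN:
    def test_both_uncalled_gives_prior(self, uniform):
        assert posterior_with_n("N", "N", 0.3, 0.9, uniform).p_true_match == 0.25

    def test_called_base_error_free_gives_its_frequency(self, rng):
        freqs = BaseFrequencies.from_mapping({"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4})
        assert posterior_with_n("A", "N", 0.0, 0.7, freqs).p_true_match == pytest.approx(0.4)

    def test_degenerate_frequency(self):
        freqs = BaseFrequencies.from_mapping({"C": 1.0})
        assert posterior_with_n("N", "C", 0.5, 0.0, freqs).p_true_match == pytest.approx(1.0)

    @pytest.mark.parametrize("e", [0.0, 0.1, 0.5, 1.0])
    def test_matches_enumeration_oracle(self, e, uniform, rng):
        for freqs in (uniform, random_freqs(rng)):
            for base in "ACGT":
                got = posterior_with_n(base, "N", e, 0.2, freqs).p_true_match
                assert got == pytest.approx(posterior_n_oracle(base, e, freqs), abs=1e-12)

    def test_requires_an_uncalled_base(self, uniform):
        with pytest.raises(ValueError):
            posterior_with_n("A", "C", 0.1, 0.1, uniform)


class TestPerBaseScore:
    def test_error_free_match_and_mismatch(self, uniform):
        params = ScoringParams(1.0, -1.0)
        assert per_base_score("A", "A", 0.0, 0.0, params, uniform) == 1.0
        assert per_base_score("A", "C", 0.0, 0.0, params, uniform) == -1.0

    def test_weighted_score_composes_posterior(self, uniform):
        params = ScoringParams(1.0, -1.0)
        p = posterior_match_oracle(True, 0.1, 0.1, uniform)
        got = per_base_score("A", "A", 0.1, 0.1, params, uniform)
        assert got == pytest.approx(1.0 * p - 1.0 * (1 - p), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(e_x=prob, e_y=prob, match=st.booleans())
    def test_score_bounded_by_alpha_beta(self, e_x, e_y, match):
        params = ScoringParams(1.0, -1.0)
        x, y = ("A", "A") if match else ("A", "C")
        s = per_base_score(x, y, e_x, e_y, params, BaseFrequencies.uniform())
        assert params.beta - 1e-12 <= s <= params.alpha + 1e-12

    def test_raw_mode_ignores_quality_and_zeroes_n(self, uniform):
        params = ScoringParams(1.0, -1.0, quality_weighted=False)
        assert per_base_score("A", "A", 0.9, 0.9, params, uniform) == 1.0
        assert per_base_score("A", "C", 0.0, 0.0, params, uniform) == -1.0
        assert per_base_score("A", "N", 0.1, 0.1, params, uniform) == 0.0


class TestScoringTables:
    def test_table_entries_equal_scalar_scores(self, rng):
        freqs = random_freqs(rng)
        params = ScoringParams(1.0, -1.2)
        tables = ScoringTables(params, freqs, max_quality=45)
        for qx in (0, 2, 17, 45):
            for qy in (0, 5, 45):
                ex, ey = quality_to_error_prob(qx), quality_to_error_prob(qy)
                assert tables.match[qx, qy] == per_base_score("A", "A", ex, ey, params, freqs)
                assert tables.mismatch[qx, qy] == per_base_score("A", "C", ex, ey, params, freqs)
                assert tables.n_called[1, qx] == per_base_score("C", "N", ex, 0.3, params, freqs)
        assert tables.n_both == per_base_score("N", "N", 0.5, 0.5, params, freqs)
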