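"""Significance of a merged overlap against the random-sequence null.

The statistic is the observed expected alignment score (OES) of the
chosen overlap: the expected value of the match/mismatch score given
the observed bases and their error probabilities, i.e. the sum over
overlap columns of alpha * P(true match | obs) + beta * P(true mismatch | obs).

Under the null the two reads are independent random sequences with no
sequencing errors, so the score of an overlap of length n is
S_n = alpha*K + beta*(n-K) with K ~ Binomial(n, q), q the random
base-match probability.  The P-value is the probability that some
placement with overlap >= omega reaches the observed OES.  Scores of
distinct placements compare disjoint base pairs and are treated as
independent, giving

    p = 1 - prod_over_placements P(S_n < s)

which coincides with the union bound sum P(S_n >= s) when p is small
and stays calibrated (verified by simulation) when it is not.

Two analytic derivations about competing mergers are included:
``flash_setting_pvalue`` evaluates this test with the score criterion
replaced by FLASH's match-fraction criterion, and
``pandaseq_random_merge_threshold`` solves for the per-base error rate
above which PANDAseq's column probabilities favor merging two
independent random sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .io import ReadPair
from .overlap import OverlapPlacement, placement_overlap_lengths
from .scoring import (
    BaseFrequencies,
    ScoringParams,
    per_base_score,
    quality_to_error_prob,
)

TEST_MODES = ("disabled", "pvalue", "map")


@dataclass(frozen=True)
class TestConfig:
    """Mode, cutoff and minimum overlap omega of the significance test.

    ``map`` re-evaluates the P-value with omega set to the overlap size
    the search actually chose; this recovers short true overlaps at the
    price of a formally invalid (data-dependent) null.
    """

    __test__ = False  # not a pytest class, despite the name

    mode: str = "pvalue"
    cutoff: float = 0.01
    omega: int = 1

    def __post_init__(self) -> None:
        if self.mode not in TEST_MODES:
            raise ValueError(f"mode must be one of {TEST_MODES}, got {self.mode!r}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.omega < 1:
            raise ValueError(f"omega must be >= 1, got {self.omega}")


@dataclass(frozen=True)
class TestOutcome:
    oes: float
    p: float
    significant: bool


def observed_expected_score(
    pair: ReadPair,
    placement: OverlapPlacement,
    freqs: BaseFrequencies,
    params: ScoringParams = ScoringParams(),
    reverse_rc=None,
) -> float:
    """OES of one placement: posterior-weighted score summed over the overlap."""
    from .overlap import reverse_complement  # local to avoid cycle at import time

    if placement.overlap_len < 1:
        raise ValueError("overlap must span at least one column")
    if reverse_rc is None:
        reverse_rc = reverse_complement(pair.reverse)
    weighted = ScoringParams(params.alpha, params.beta, quality_weighted=True)
    sl1, sl2 = placement.columns(len(pair.forward), len(reverse_rc))
    total = 0.0
    for x, y, qx, qy in zip(
        pair.forward.bases[sl1], reverse_rc.bases[sl2],
        pair.forward.quals[sl1], reverse_rc.quals[sl2],
    ):
        total += per_base_score(
            x, y, quality_to_error_prob(int(qx)), quality_to_error_prob(int(qy)),
            weighted, freqs,
        )
    return total


def _min_matches(s, n, params: ScoringParams):
    """Smallest match count k with alpha*k + beta*(n-k) >= s (lattice-exact)."""
    return np.ceil((s - params.beta * np.asarray(n)) / (params.alpha - params.beta) - 1e-9)


def null_score_tail(s: float, n: int, q: float, params: ScoringParams = ScoringParams()) -> float:
    """P(S_n >= s) for the score of one random overlap of length n."""
    if n < 1:
        raise ValueError("overlap length must be >= 1")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0,1), got {q}")
    k = _min_matches(s, n, params)
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(binom.sf(k - 1, n, q))


def p_value(
    oes_observed: float,
    len1: int,
    len2: int,
    q: float,
    config: TestConfig,
    params: ScoringParams = ScoringParams(),
    method: str = "product",
) -> float:
    """P-value of the maximal null score over all placements with overlap >= omega.

    ``method="product"`` (default) treats placements as independent;
    ``method="union"`` uses the Bonferroni sum capped at 1.
    """
    if config.omega > min(len1, len2):
        raise ValueError(
            f"omega {config.omega} exceeds the shorter read length {min(len1, len2)}"
        )
    if not math.isfinite(oes_observed):
        raise ValueError("observed OES must be finite")
    ns = placement_overlap_lengths(len1, len2, config.omega)
    k = _min_matches(oes_observed, ns, params)
    tails = np.where(k <= 0, 1.0, binom.sf(np.maximum(k, 1) - 1, ns, q))
    tails = np.where(k > ns, 0.0, tails)
    if method == "union":
        return float(min(1.0, tails.sum()))
    if method == "product":
        return float(min(1.0, 1.0 - np.prod(1.0 - tails)))
    raise ValueError(f"unknown method {method!r}")


def decide(
    oes_observed: float,
    best_placement: Optional[OverlapPlacement],
    pair_lengths: tuple[int, int],
    q: float,
    config: TestConfig,
    params: ScoringParams = ScoringParams(),
) -> TestOutcome:
    """Apply the configured test to the best placement's OES.

    Disabled mode reports p = 1.0 as a "not tested" sentinel and always
    accepts.  MAP mode replaces omega with the chosen overlap length.
    """
    if config.mode == "disabled":
        return TestOutcome(oes=oes_observed, p=1.0, significant=True)
    omega = config.omega
    if config.mode == "map":
        if best_placement is None:
            raise ValueError("MAP mode requires the chosen placement")
        omega = best_placement.overlap_len
    cfg = TestConfig(mode=config.mode, cutoff=config.cutoff, omega=omega)
    p = p_value(oes_observed, pair_lengths[0], pair_lengths[1], q, cfg, params)
    return TestOutcome(oes=oes_observed, p=p, significant=p <= config.cutoff)


def flash_setting_pvalue(f_threshold: float, omega: int, q: float = 0.25, read_len: int = 100) -> float:
    """P-value of FLASH's merge criterion under the random-sequence null.

    FLASH merges when some suffix-prefix overlap of size n >= omega has a
    match fraction of at least ``f_threshold``.  The closed form sums the
    binomial tails P(Bin(n, q) >= ceil(f*n)) over the overlap sizes
    n = omega .. read_len with a geometric-series normalization 1/(1-q),
    capped at 1.  At FLASH's defaults (f = 0.75, omega = 10, uniform
    q = 0.25, 100-bp reads) it evaluates to 1.56e-3.

    This is the published closed form for the comparative derivation; it
    exceeds the simulated tail of the max statistic by roughly the same
    1/(1-q) factor (see the methods note).
    """
    if not 0.0 < f_threshold <= 1.0:
        raise ValueError(f"f_threshold must be in (0,1], got {f_threshold}")
    if omega < 1 or omega > read_len:
        raise ValueError(f"omega must be in [1, {read_len}], got {omega}")
    ns = np.arange(omega, read_len + 1)
    kmin = np.ceil(f_threshold * ns - 1e-9)
    tails = binom.sf(kmin - 1, ns, q)
    return float(min(1.0, tails.sum() / (1.0 - q)))


def _pandaseq_column_logprob(e: float, alphabet_prob: float) -> float:
    """Expected log of PANDAseq's per-column probability for a random pair.

    Given a shared true base, an observed match has probability
    m1 = (1-e)^2 + e^2/3 and a specific observed mismatch
    m2 = 2e(1-e)/3 + 2e^2/9; for two independent random sequences a
    column is a match with probability ``alphabet_prob``.
    """
    m1 = (1.0 - e) ** 2 + e * e / 3.0
    m2 = 2.0 * e * (1.0 - e) / 3.0 + 2.0 * e * e / 9.0
    if m2 <= 0.0:
        return -math.inf
    return alphabet_prob * math.log(m1) + (1.0 - alphabet_prob) * math.log(m2)


def pandaseq_random_merge_threshold(alphabet_prob: float = 0.25) -> float:
    """Break-even per-base error probability for PANDAseq on random sequences.

    PANDAseq scores an overlap column by the probability of the two
    observed bases given a shared true base; absorbing a column into the
    overlap replaces two independent random bases whose baseline
    probability is ``alphabet_prob`` each.  Merging two unrelated random
    sequences becomes favorable once the expected per-column log
    probability exceeds the baseline log(alphabet_prob^2); this function
    solves that break-even for the error probability e (root found to
    1e-9).  At uniform base frequencies (0.25) the root is ~0.039: reads
    whose average error rate exceeds it get merged by PANDAseq even when
    the true fragments share nothing.
    """
    if not 0.0 < alphabet_prob < 1.0:
        raise ValueError(f"alphabet_prob must be in (0,1), got {alphabet_prob}")
    baseline = 2.0 * math.log(alphabet_prob)

    def gap(e: float) -> float:
        return _pandaseq_column_logprob(e, alphabet_prob) - baseline

    lo, hi = 1e-9, 0.75
    if not (gap(lo) < 0.0 < gap(hi)):
        raise ValueError("no break-even error probability in (0, 0.75)")
    return float(brentq(gap, lo, hi, xtol=1e-9))
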