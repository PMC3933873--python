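"""Quality-to-error conversion, base frequencies and posterior match scores.

The error model: a base call is wrong with the Phred probability
e = 10^(-Q/10), and an erroneous call substitutes uniformly among the
three alternative bases.  Errors on the two reads are independent.
Under this model, for a column of the overlap with observed bases X, Y
and error probabilities eX, eY:

    P(observed match    | true match)    = (1-eX)(1-eY) + eX eY / 3
    P(observed match    | true mismatch) = ((1-eX) eY + eX (1-eY)) / 3
                                           + 2 eX eY / 9

and the prior probability of a true match between two random bases is
q = sum_b freq(b)^2.  Bayes' rule then gives the posterior probability
of a true match given the observation, which weights the match reward
alpha and mismatch penalty beta in the per-column assembly score.

Uncalled bases (N) carry no match/mismatch evidence: the posterior
falls back to the prior chance that the unseen base agrees with the
other column member (or to q when both are uncalled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import Read, ReadPair

BASES = "ACGT"
#: integer codes used throughout the fast paths: A,C,G,T -> 0..3, N -> 4
BASE_CODE = {b: i for i, b in enumerate(BASES + "N")}
_CODE_TABLE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _i


def encode_bases(bases: str) -> np.ndarray:
    """Map a base string to integer codes (A,C,G,T,N -> 0,1,2,3,4)."""
    return _CODE_TABLE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def quality_to_error_prob(q):
    """Phred quality -> error probability, e = 10^(-Q/10)."""
    q_arr = np.asarray(q)
    if np.any(q_arr < 0):
        raise ValueError("quality scores must be non-negative")
    e = 10.0 ** (-q_arr / 10.0)
    return float(e) if np.isscalar(q) or q_arr.ndim == 0 else e


def error_prob_to_quality(e, max_quality: int = 93):
    """Error probability -> integer Phred quality, floored and capped.

    A tiny epsilon absorbs float representation error so that exact
    powers of ten land on their integer quality (e.g. 1e-4 -> 40).
    """
    e_arr = np.maximum(np.asarray(e, dtype=float), 1e-300)
    q = np.floor(-10.0 * np.log10(e_arr) + 1e-9)
    q = np.clip(q, 0, max_quality).astype(np.int16)
    return int(q) if np.isscalar(e) or np.asarray(e).ndim == 0 else q


@dataclass(frozen=True)
class BaseFrequencies:
    """Empirical frequencies of the four called bases (N excluded)."""

    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or np.any(arr > 1) or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"base frequencies must be in [0,1] and sum to 1, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.t], dtype=float)

    def __getitem__(self, base: str) -> float:
        return self.as_array()[BASE_CODE[base]]

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_mapping(cls, freq: Mapping[str, float]) -> "BaseFrequencies":
        return cls(*(freq.get(b, 0.0) for b in BASES))

    @classmethod
    def from_counts(cls, counts: Iterable[float]) -> "BaseFrequencies":
        arr = np.asarray(list(counts), dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError(
                "no called bases to estimate frequencies from; "
                "use uniform frequencies instead (uniform-freqs flag)"
            )
        return cls(*(arr / total))


def estimate_base_frequencies(pairs: Iterable[ReadPair | Read]) -> BaseFrequencies:
    """Count A/C/G/T over all reads; N is excluded from numerator and denominator."""
    counts = np.zeros(4)
    for item in pairs:
        reads = item if isinstance(item, ReadPair) else (item,)
        for read in reads:
            for i, b in enumerate(BASES):
                counts[i] += read.bases.count(b)
    return BaseFrequencies.from_counts(counts)


def random_match_prob(freqs: BaseFrequencies) -> float:
    """Probability q that two random bases match: sum of squared frequencies."""
    arr = freqs.as_array()
    return float(arr @ arr)


@dataclass(frozen=True)
class ScoringParams:
    """Match reward alpha (>0), mismatch penalty beta (<0), and whether the
    per-column score is weighted by the posterior true-match probability."""

    alpha: float = 1.0
    beta: float = -1.0
    quality_weighted: bool = True

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not self.beta < 0:
            raise ValueError(f"beta must be negative, got {self.beta}")


@dataclass(frozen=True)
class BasePosterior:
    p_true_match: float
    p_true_mismatch: float


def _p_obs_match_given_true_match(e_x, e_y):
    # both correct, or both wrong the same way (1/3 chance of agreeing)
    return (1.0 - e_x) * (1.0 - e_y) + e_x * e_y * (1.0 / 3.0)


def _p_obs_match_given_true_mismatch(e_x, e_y):
    # one correct + the other errs onto it, or both err onto a common base
    return ((1.0 - e_x) * e_y + e_x * (1.0 - e_y)) * (1.0 / 3.0) + e_x * e_y * (2.0 / 9.0)


def _posterior_match(observed_match, e_x, e_y, q):
    """P(true match | observation); vectorized over e_x/e_y."""
    m1 = _p_obs_match_given_true_match(e_x, e_y)
    m2 = _p_obs_match_given_true_mismatch(e_x, e_y)
    if observed_match:
        num = q * m1
        den = q * m1 + (1.0 - q) * m2
    else:
        num = q * (1.0 - m1)
        den = q * (1.0 - m1) + (1.0 - q) * (1.0 - m2)
    # a zero denominator means the observation has probability zero under
    # the model (degenerate frequencies); fall back to the prior
    return np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), q)


def base_posterior(
    observed_match: bool, e_x: float, e_y: float, freqs: BaseFrequencies
) -> BasePosterior:
    """Posterior probability of a true match given an observed match/mismatch."""
    if not (0.0 <= e_x <= 1.0 and 0.0 <= e_y <= 1.0):
        raise ValueError(f"error probabilities must be in [0,1], got {e_x}, {e_y}")
    q = random_match_prob(freqs)
    p = float(_posterior_match(observed_match, e_x, e_y, q))
    return BasePosterior(p, 1.0 - p)


def posterior_with_n(
    x: str, y: str, e_x: float, e_y: float, freqs: BaseFrequencies
) -> BasePosterior:
    """Posterior true-match probability when at least one base is uncalled.

    An uncalled base is uniform over the model prior, so the posterior
    reduces to the chance that the hidden base agrees with the (posterior
    over the) other column member; with both uncalled it is exactly q.
    """
    if x != "N" and y != "N":
        raise ValueError("posterior_with_n requires at least one uncalled base")
    q = random_match_prob(freqs)
    if x == "N" and y == "N":
        return BasePosterior(q, 1.0 - q)
    called, e_called = (x, e_x) if y == "N" else (y, e_y)
    b = freqs.as_array()
    code = BASE_CODE[called]
    # posterior over the called read's true base, then chance the unseen
    # read's true base (prior b) agrees with it
    w = b * (e_called / 3.0)
    w[code] = b[code] * (1.0 - e_called)
    den = w.sum()
    p = float(w @ b / den) if den > 0 else q
    return BasePosterior(p, 1.0 - p)


def per_base_score(
    x: str,
    y: str,
    e_x: float,
    e_y: float,
    params: ScoringParams,
    freqs: BaseFrequencies,
) -> float:
    """Contribution of one overlap column to the assembly score.

    Quality-weighted: alpha * P(true match | obs) + beta * P(true mismatch | obs).
    Raw: alpha for an observed match, beta for a mismatch, 0 for any N.
    """
    if x == "N" or y == "N":
        if not params.quality_weighted:
            return 0.0
        post = posterior_with_n(x, y, e_x, e_y, freqs)
        return params.alpha * post.p_true_match + params.beta * post.p_true_mismatch
    if not params.quality_weighted:
        return params.alpha if x == y else params.beta
    post = base_posterior(x == y, e_x, e_y, freqs)
    return params.alpha * post.p_true_match + params.beta * post.p_true_mismatch


@dataclass
class ScoringTables:
    """Precomputed per-column score lookups over the quality grid.

    ``match[qx, qy]`` / ``mismatch[qx, qy]`` hold the assembly-score
    contribution for a called-base column under ``params``;
    ``n_called[code, q]`` the contribution when the other base is N;
    ``n_both`` when both are N.  ``oes_*`` are the same lookups with
    quality weighting forced on (the observed expected alignment score
    always weights by the posteriors, whatever the search mode).

    Entries are produced by the same vectorized expressions as the
    scalar functions above, so table lookups and scalar calls agree
    bit-for-bit.
    """

    params: ScoringParams
    freqs: BaseFrequencies
    max_quality: int = 93
    match: np.ndarray = field(init=False)
    mismatch: np.ndarray = field(init=False)
    n_called: np.ndarray = field(init=False)
    n_both: float = field(init=False)
    oes_match: np.ndarray = field(init=False)
    oes_mismatch: np.ndarray = field(init=False)
    oes_n_called: np.ndarray = field(init=False)
    oes_n_both: float = field(init=False)
    error_prob: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        qgrid = np.arange(self.max_quality + 1)
        # scalar conversion per grid point: vectorized pow can differ from the
        # scalar path by one ulp, and table lookups must match scalar scoring
        # exactly (the remaining table arithmetic is elementwise and exact)
        self.error_prob = np.array([quality_to_error_prob(int(q)) for q in qgrid])
        e_x = self.error_prob[:, None]
        e_y = self.error_prob[None, :]
        q = random_match_prob(self.freqs)
        a, b = self.params.alpha, self.params.beta

        p_match = _posterior_match(True, e_x, e_y, q)
        p_mismatch = _posterior_match(False, e_x, e_y, q)
        self.oes_match = a * p_match + b * (1.0 - p_match)
        self.oes_mismatch = a * p_mismatch + b * (1.0 - p_mismatch)
        self.oes_n_called = np.empty((4, self.max_quality + 1))
        for code, base in enumerate(BASES):
            for qi in qgrid:
                p = posterior_with_n(base, "N", self.error_prob[qi], 0.0, self.freqs).p_true_match
                self.oes_n_called[code, qi] = a * p + b * (1.0 - p)
        self.oes_n_both = a * q + b * (1.0 - q)

        if self.params.quality_weighted:
            self.match = self.oes_match
            self.mismatch = self.oes_mismatch
            self.n_called = self.oes_n_called
            self.n_both = self.oes_n_both
        else:
            shape = (self.max_quality + 1,) * 2
            self.match = np.full(shape, a)
            self.mismatch = np.full(shape, b)
            self.n_called = np.zeros((4, self.max_quality + 1))
            self.n_both = 0.0
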