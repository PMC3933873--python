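"""Shared test utilities: random fixtures and independent oracles.

The oracles deliberately avoid the implementation's fast paths: the
posterior oracle enumerates every (true base, observed base) outcome of
the error model, and the overlap oracle loops over offsets and columns
directly, scoring with the posterior formulas.  They are the reference
the vectorized code is checked against.
"""

from __future__ import annotations

import numpy as np

from pestitch import (
    BaseFrequencies,
    Read,
    ReadPair,
    ScoringParams,
    base_posterior,
    posterior_with_n,
)

BASES = "ACGT"


def make_read(
    rng: np.random.Generator,
    length: int,
    read_id: str = "r",
    n_prob: float = 0.0,
    qual_range: tuple[int, int] = (2, 41),
) -> Read:
    codes = rng.integers(0, 4, size=length)
    bases = "".join("ACGTN"[c] for c in codes)
    if n_prob > 0:
        bases = "".join(
            "N" if rng.random() < n_prob else b for b in bases
        )
    quals = rng.integers(qual_range[0], qual_range[1] + 1, size=length)
    return Read(id=read_id, bases=bases, quals=quals)


def make_pair(rng: np.random.Generator, len1: int, len2: int, **kw) -> ReadPair:
    return ReadPair(make_read(rng, len1, "f", **kw), make_read(rng, len2, "rv", **kw))


def random_freqs(rng: np.random.Generator) -> BaseFrequencies:
    raw = rng.dirichlet(np.ones(4) * 5)
    return BaseFrequencies(*(raw / raw.sum()))


# ---------------------------------------------------------------- oracles

def _p_obs(obs: int, true: int, e: float) -> float:
    """P(observed base | true base) under uniform substitution among 3."""
    return 1.0 - e if obs == true else e / 3.0


def posterior_match_oracle(
    observed_match: bool, e_x: float, e_y: float, freqs: BaseFrequencies
) -> float:
    """P(true match | observed match/mismatch) by exhaustive enumeration."""
    f = freqs.as_array()
    num = den = 0.0
    for tx in range(4):
        for ty in range(4):
            prior = f[tx] * f[ty]
            for x in range(4):
                px = _p_obs(x, tx, e_x)
                for y in range(4):
                    if (x == y) != observed_match:
                        continue
                    p = prior * px * _p_obs(y, ty, e_y)
                    den += p
                    if tx == ty:
                        num += p
    return num / den


def posterior_n_oracle(called: str, e_called: float, freqs: BaseFrequencies) -> float:
    """P(true match | one observed base, the other uncalled), by enumeration
    over the called read's true base and the unobserved read's true base."""
    f = freqs.as_array()
    x = BASES.index(called)
    num = den = 0.0
    for tx in range(4):
        p = f[tx] * _p_obs(x, tx, e_called)
        den += p
        num += p * f[tx]  # chance the unseen true base equals tx
    return num / den


def column_score_oracle(
    x: str, y: str, e_x: float, e_y: float, params: ScoringParams, freqs: BaseFrequencies
) -> float:
    """Per-column score via the package's posterior primitives (scalar path)."""
    if x == "N" or y == "N":
        if not params.quality_weighted:
            return 0.0
        p = posterior_with_n(x, y, e_x, e_y, freqs).p_true_match
    elif params.quality_weighted:
        p = base_posterior(x == y, e_x, e_y, freqs).p_true_match
    else:
        return params.alpha if x == y else params.beta
    return params.alpha * p + params.beta * (1.0 - p)


def best_overlap_oracle(
    pair: ReadPair,
    params: ScoringParams,
    freqs: BaseFrequencies,
    min_overlap: int = 1,
):
    """Brute-force search: loop over every offset and column explicitly.

    Returns (offset, overlap_len, implied_fragment_len, score) of the
    best placement under the score/overlap/fragment tie-break, or None.
    """
    fwd = pair.forward
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc_bases = "".join(comp[b] for b in reversed(pair.reverse.bases))
    rc_quals = list(reversed([int(q) for q in pair.reverse.quals]))
    len1, len2 = len(fwd), len(pair.reverse)
    best = None
    for d in range(-(len2 - 1), len1):
        i0, i1 = max(0, d), min(len1, len2 + d)
        n = i1 - i0
        if n < min_overlap:
            continue
        score = 0.0
        for i in range(i0, i1):
            j = i - d
            score += column_score_oracle(
                fwd.bases[i], rc_bases[j],
                10.0 ** (-np.asarray(int(fwd.quals[i])) / 10.0),
                10.0 ** (-np.asarray(int(rc_quals[j])) / 10.0),
                params, freqs,
            )
        frag = d + len2 if d >= 0 else n
        key = (score, n, frag, d)
        if best is None or key > best[0]:
            best = (key, d)
    if best is None:
        return None
    (score, n, frag, _), d = best
    return d, n, frag, score


def mc_max_null_scores(
    n_pairs: int,
    len1: int,
    len2: int,
    freqs: np.ndarray,
    min_overlap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Maximal match-mismatch score (alpha=1, beta=-1) over all ungapped
    placements, for a batch of independent random sequence pairs."""
    x = rng.choice(4, size=(n_pairs, len1), p=freqs)
    y = rng.choice(4, size=(n_pairs, len2), p=freqs)
    best = np.full(n_pairs, -np.inf)
    for d in range(-(len2 - 1), len1):
        i0, i1 = max(0, d), min(len1, len2 + d)
        n = i1 - i0
        if n < min_overlap:
            continue
        matches = (x[:, i0:i1] == y[:, i0 - d : i1 - d]).sum(axis=1)
        best = np.maximum(best, 2 * matches - n)
    return best
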