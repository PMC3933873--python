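"""The overlap significance test on two hand-built read pairs, plus the two
analytic results about competing merge criteria.

A genuine 40-bp overlap gives a vanishing P-value; the best overlap between
two unrelated random reads does not come close to the 0.01 cutoff.
"""

import numpy as np

from pestitch import (
    BaseFrequencies,
    Read,
    ReadPair,
    TestConfig,
    decide,
    find_best_overlap,
    flash_setting_pvalue,
    merge_pair,
    observed_expected_score,
    pandaseq_random_merge_threshold,
    reverse_complement,
    ScoringParams,
)

rng = np.random.default_rng(7)
uniform = BaseFrequencies.uniform()
L = 100


def random_read(length, read_id):
    return Read(read_id, "".join(rng.choice(list("ACGT"), size=length)),
                rng.integers(25, 41, size=length))


# a pair sequenced from a 160-bp fragment: true overlap = 40 bp
frag = "".join(rng.choice(list("ACGT"), size=160))
forward = Read("f", frag[:L], np.full(L, 35))
reverse = reverse_complement(Read("r", frag[-L:], np.full(L, 35)))
pair = ReadPair(forward, reverse)

best = find_best_overlap(pair, ScoringParams(), uniform, min_overlap=1)
oes = observed_expected_score(pair, best.placement, uniform)
outcome = decide(oes, best.placement, (L, L), 0.25, TestConfig(mode="pvalue", omega=1))
print(f"true overlap pair : overlap={best.placement.overlap_len} "
      f"OES={oes:.1f} p={outcome.p:.3g} -> merge={outcome.significant}")

# two unrelated random reads: the search still finds *some* best overlap,
# but its score is what chance alone produces
random_pair = ReadPair(random_read(L, "x"), random_read(L, "y"))
result = merge_pair(random_pair, freqs=uniform,
                    test=TestConfig(mode="pvalue", cutoff=0.01, omega=1))
print(f"random pair       : status={result.status} OES={result.oes:.1f} p={result.p:.3f}")

print()
print("analytic comparisons with other merge criteria:")
print(f"  FLASH defaults (f=0.75, omega=10, 100-bp reads): "
      f"P-value = {flash_setting_pvalue(0.75, 10, 0.25, 100):.5f}")
print(f"  PANDAseq favors merging random sequences once the mean per-base "
      f"error rate exceeds {pandaseq_random_merge_threshold(0.25):.4f}")
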