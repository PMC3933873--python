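# Methods

## Scope

`pestitch` merges Illumina paired-end reads whose target fragments may be of
any length: longer than two reads (no overlap — should not merge), between
one and two read lengths (partial overlap), or shorter than a single read
(the reads run through the fragment into adapter noise; the overlap *is* the
fragment). The search is exhaustive over ungapped placements; gapped
alignment is out of scope because indels are rare on Illumina platforms
relative to substitutions.

## Error model and posterior column scores

A called base is wrong with probability e = 10^(−Q/10) (Phred); an erroneous
call is uniform over the three alternative bases, and errors on the two
reads are independent. Base frequencies b are estimated by counting A/C/G/T
over both input files (N excluded from numerator and denominator), or fixed
at 0.25 with the uniform-frequencies flag; q = Σ_b b² is the chance two
random bases match.

For an overlap column with observed bases X, Y:

- P(observed match | true match) = m1 = (1−e_X)(1−e_Y) + e_X e_Y/3
- P(observed match | true mismatch) = m2 = ((1−e_X)e_Y + e_X(1−e_Y))/3 + 2 e_X e_Y/9

Bayes' rule with prior q gives P(true match | observation); the per-column
score is α·P(true match | obs) + β·P(true mismatch | obs). Defaults
α = +1, β = −1 (overridable). A raw mode scores α/β by observed
match/mismatch only and gives N columns a score of 0; in weighted mode an N
column contributes the prior evidence of the called partner (or exactly q·α
+ (1−q)·β when both are N).

Two properties of this model worth noting (both are property-tested):

- The *informationless point* is e = 3/4, where an observed base is uniform
  whatever the truth and the posterior equals the prior q exactly. At e = 1
  the observation is anti-informative (the observed base is known **not** to
  be the true one), and the posterior for an observed match at uniform
  frequencies tends to 1/3, not q. Monotonicity in e therefore holds on
  [0, 3/4].
- Posteriors are validated against exhaustive enumeration over every
  (true base pair, observed base pair) outcome of the model, for uniform and
  skewed frequency vectors.

## Overlap search

All offsets d ∈ [−(L2−1), L1−1] of the reverse-complemented reverse read
against the forward read are scored; the overlap length is
n = min(L1−d, L2) for d ≥ 0 and n = min(L1, L2+d) for d < 0, and the implied
fragment length is d+L2 respectively n. The assembly score of each placement
is the sum of per-column scores; the maximizer wins. Ties (possible in raw
mode, where scores are integers) are broken deterministically: larger
overlap, then larger implied fragment, then larger offset. The
implementation evaluates all placements as diagonal sums of an L1×L2
per-cell score matrix built from precomputed quality-indexed lookup tables;
a brute-force per-offset enumerator in the test suite must agree exactly
(same placement, bit-identical score). To keep that exactness, table entries
are generated through the same scalar quality→error conversion as the scalar
scoring path (vectorized `pow` can differ by one ulp from the scalar one),
and diagonal accumulation visits columns in the same order as the reference
loop.

The cost is O(L1·L2) per pair — exhaustiveness, not sub-quadratic search, is
the point. At 100–150-bp reads this is ~0.3 ms per pair.

## Significance test

The observed expected alignment score (OES) of the chosen overlap is the
posterior-weighted score above (identical to the weighted assembly score;
it is recomputed with weighting even when the search ran in raw mode). The
null: two independent random sequences without sequencing errors, so an
overlap of size n scores S_n = αK + β(n−K), K ~ Binomial(n, q). "Score ≥ s"
is resolved on the lattice via k ≥ ⌈(s−βn)/(α−β)⌉ (with a 1e-9 guard), never
by floating-point tail summation.

The P-value of the maximal null score over all placements with n ≥ ω is
computed as 1 − Π (1 − P(S_n ≥ s)) over the placements (each overlap size
with its multiplicity). Distinct placements compare disjoint base pairs, and
for uniform composition the per-cell match indicators are pairwise
uncorrelated, so the independence approximation is accurate across the whole
range (simulation check: within 3 Monte-Carlo standard errors of the
empirical tail of 1e5 brute-force-scored random pairs, up to tail
probabilities of ~0.85). For strongly skewed composition the placements are
positively dependent through shared letters (Σ b³ > q²) and the form remains
accurate in the small-p tail — the regime the merger actually operates in at
the 0.01 cutoff. A Bonferroni union bound is available as an alternative
`method`; it coincides with the product for small p.

Modes: `disabled` (always merge, p reported as a 1.0 sentinel), `pvalue`
(fixed ω), `map` (ω replaced by the observed overlap length after the
search; more merges, formally data-dependent null). Default cutoff 0.01.

### FLASH's default setting

`flash_setting_pvalue` applies the same null with the score criterion
replaced by FLASH's match-fraction criterion: a placement "merges" when
matches/overlap ≥ f and overlap ≥ ω, over the suffix–prefix overlap sizes
n = ω..L. The closed form is

    p = min(1, Σ_{n=ω}^{L} P(Bin(n, q) ≥ ⌈f·n⌉) / (1 − q)),

i.e. the union over overlap sizes with a geometric-series normalization
1/(1−q). At FLASH's defaults (f = 0.75, ω = 10, q = 0.25, 100-bp reads) it
evaluates to 1.565e-3. Note the normalization is part of the closed form
this function reproduces, not of the merger's own test: the plain union over
sizes is 1.174e-3 and matches direct simulation of the max-fraction
statistic; the closed form is conservative by roughly the 1/(1−q) factor.
The merger's `p_value` therefore does **not** carry the factor.

### PANDAseq's random-merge threshold

PANDAseq scores an overlap column by the probability of the two observed
bases given a shared true base (m1 above for a match, m2 for a specific
mismatch) and compares merged against unmerged interpretations in which an
unpaired base has probability 1/4. Absorbing a column replaces two
independent bases (baseline (1/4)²). Because the column probabilities enter
as a product over the overlap, the relevant break-even for long random
overlaps is the expected *log* probability:

    (1/4)·ln m1(e) + (3/4)·ln m2(e) = ln(1/16)

with equal error probability e on both reads and uniform base frequencies.
(The arithmetic-mean version of this comparison is identically break-even at
every e by the law of total probability and has no positive root — the
geometric form is the meaningful one.) `pandaseq_random_merge_threshold`
solves it by bracketed root-finding on (0, 3/4) to 1e-9; the root is
e* = 0.0392. Reads whose mean error rate exceeds it — common toward Illumina
read ends — push PANDAseq into merging unrelated sequences, which is the
mechanistic explanation for its high false-positive rate on non-overlapping
libraries.

## Consensus and output

Accepted overlaps are collapsed column-wise: identical called bases keep the
base with error probability e_X·e_Y (qualities add, floored at the integer
and capped at the encoding maximum, 93 for Phred+33 — a lower cap is
configurable); different called bases keep the higher-quality base *with its
own quality* (ties keep the forward base); one N defers to the called base;
two Ns stay N with the larger error probability. For d ≥ 0 the merged read
is forward-flank + consensus + reverse-flank, truncated to the implied
fragment length (which also drops forward read-through past a short
fragment); for d < 0 the merged read is the consensus alone. Merged length
always equals the implied fragment length.

Post-merge filters (defaults permissive): unmerged reads are trimmed before
the first two consecutive bases below the trimming quality (0 = off), then
merged products and trimmed mates alike are checked against minimum length
(default 50), maximum length (0 = off) and the maximum uncalled-base
proportion (1.0 = off). Mates of an unmerged pair are filtered
independently — one can be discarded while the other survives — and the
reverse mate is written in its as-sequenced orientation. Every input pair
contributes either its merged product once or both mates once each across
the four output files (`<prefix>.assembled/.unassembled.forward/
.unassembled.reverse/.discarded.fastq`).

Pairing is strictly positional (no identifier parsing); Phred+33 is the
default encoding with Phred+64 selectable; gzip I/O is transparent by
extension. Reads are processed in chunks (default 5000 pairs) with at most
two chunks resident; with multiple workers each chunk is split across a
process pool and reassembled in order, so outputs are byte-identical for any
worker count.

## Simulator

The synthetic-data generator emulates the standard merger-benchmark
protocol: uniform-random reference sequences (default 20 × 800 bp),
fragments sampled at a uniformly chosen reference position with lengths
drawn from Normal(mean, sd = 10), rounded and clamped to [1, reference
length]; 100-bp reads from both fragment ends; two linearly decaying
quality profiles (forward 38→20, reverse 36→18 — a desk-scale stand-in for
the empirical growth of Illumina error rates along the read); substitution
errors drawn per base with probability 10^(−Q/10), uniform over the three
alternatives; and, when the fragment is shorter than the read, uniform
random padding at quality 0 with no further error injection (the padding is
already pure noise). A no-overlap variant clamps fragments to at least twice
the read length. Everything is reproducible from a single seed, and the true
fragment behind each pair is retained.

What the simulator does *not* model — real reference composition and
paralogy (random references make spurious overlaps rarer than, say, 16S
gene families), indels, chimeras, position-correlated quality noise — bounds
what passing tests show: they validate the algorithm and its calibration,
not performance on any particular organism's library. Evaluation follows
the benchmark convention: a mergeable pair (fragment < 2 × read length) is
correct only when merged at exactly the true fragment length; an
unmergeable pair is correct when left unmerged. FPR is incorrect merges
over merged reads for sets containing mergeable pairs, and merged reads
over all pairs for a pure no-overlap set; 0/0 counts as 0.

## Problem sizes used in the checks

The simulation-based acceptance checks run 10,000 pairs per scenario
(50-bp mean overlap; no-overlap; 150-bp reads over 101-bp fragments), 1,500
pairs for the consensus error-correction property, and 1e5 random pairs per
batch (21 configurations) for the P-value calibration — sizes at which the
binomial sampling error is well below the asserted margins while the whole
suite stays in the minutes range.

## Known limitations

- The significance test's independence-across-placements approximation
  degrades for strongly skewed base composition at moderate-to-large p;
  calibration there is only guaranteed in the tail.
- Consensus qualities from agreeing columns assume independent errors and
  can saturate the encoding cap quickly; use the configurable cap if
  downstream tools mistrust very high qualities.
- Merging with the test disabled force-merges every pair that admits any
  placement (the search always has a maximizer); the test, or a minimum
  overlap, is what provides specificity.
- No gapped alignment, no adapter detection, no k-mer prescreening.
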