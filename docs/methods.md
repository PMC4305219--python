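# Methods

## Data model and binarization

Input is a probe × sample matrix of log intensity ratios, probes ordered
by genomic position within each chromosome (the `ProbeTrack` enforces
this ordering; the interval constraint below is meaningless without it).
A cell is a candidate copy-number gain when its value exceeds +τ and a
candidate loss when it falls below −τ, with strict inequality — a value
equal to the threshold stays 0. Gains and losses form two disjoint binary
matrices that are mined separately; a gain pattern and a loss pattern are
distinct events even on the same cells.

τ can be chosen from the data: `select_tau(X, target_density)` returns
the (1 − target) empirical quantile of |values| pooled over the whole
matrix, i.e. the smallest threshold at which the fraction of cells with
|value| > τ does not exceed the target. The quantile is global, not
per-probe or per-sample, because the target is a cohort-wide CNV density
(typical working points: ~10% for germline arrays, ~20% for tumour data
where more aberration is expected). Ties at τ can only push the achieved
density below the target, never above; absent ties it is within 1/(m·n).
Non-finite cells are rejected at construction, naming the first offending
probe and sample; an explicit `fill_missing=True` zero-fills them and
records the count, because silent imputation would corrupt support
counts.

## Frequent interval model

With D the m × n binary matrix (probes × samples), an interval
I = [a, b] of contiguous probes is a **weak error-tolerant itemset** at
tolerance ε when some sample subset T′ satisfies

    |T′| ≥ ⌈sup_min · n⌉   and   Σ_{i∈I, t∈T′} D[i,t] / (|I|·|T′|) ≥ 1 − ε.

The *strong* variant instead requires every sample of T′ individually to
have in-interval density ≥ 1 − ε; it is implemented only as a checker in
the oracle module because its requirement is rarely met on noisy data and
it is not a mining mode here. An interval is **recursively weak** when it
and every contiguous sub-interval are weak ETIs; this restores the
anti-monotonicity that makes level-wise pruning sound (if an interval
fails, no super-interval can succeed). Only contiguous sub-intervals are
enumerated in the recursion — non-contiguous subsets are outside the
search space by the spatial constraint, not an approximation of it.

Singletons are special-cased with ε = 0: their support is the exact
carrier fraction. Without this convention a singleton could be "frequent"
on the strength of empty columns alone.

### Exact weak support by a greedy prefix

`weak_eti_support` ranks samples by their 1-count inside the interval
(descending, ties broken by ascending sample index) and returns the
longest prefix whose cumulative density meets 1 − ε. This is exactly
optimal, not a heuristic: for every subset size k the top-k prefix
maximizes the total number of 1s, so if any size-k subset is feasible the
prefix is; and because counts are sorted, cumulative density is
non-increasing in k, making the feasible sizes a prefix of 1..n. The
brute-force oracle (exhaustive over all 2^n subsets, n ≤ 16) exists to
verify this claim mechanically, and the test suite compares the two on
hundreds of random instances. Density comparisons use a 1e-9 slack so
that exact rational boundaries (e.g. 0.8 at ε = 0.2) are not lost to
floating-point rounding.

The reported support set is the maximizing prefix — any maximizing set is
equally valid under the definition, and the fixed ranking makes output
deterministic and byte-identical across runs.

### Level-wise search and the merge criterion

Round 1 keeps the frequent singletons. Round k → k+1 considers each
adjacent pair of frequent size-k intervals (same chromosome, offset by
one probe, union contiguous of size k+1) and merges them when two
criteria pass:

1. **Support overlap (δ).** The Jaccard distance |S₁ Δ S₂| / |S₁ ∪ S₂|
   between the parents' support sets must be ≤ δ. The published
   description asks only for a bounded "percentage of non-overlapping
   transactions"; Jaccard distance is the choice made here because it
   reproduces the worked example's rejection (sets of 10 and a nested 5
   give 5/10 = 0.5) and meets both stated endpoints — δ = 0 forces
   identical support, δ = 1 imposes no constraint. The δ check runs
   *before* the candidate's support is computed; rejected candidates
   still log their would-be support at debug level (and in the optional
   `MergeDecision` trace) since that number is informative.
2. **Recursive weak frequency.** The candidate's weak support must reach
   ⌈sup_min · n⌉ and both maximal sub-intervals must be frequent — which
   they are by construction of the candidate generation, so level-wise
   order inductively certifies all contiguous sub-intervals.

A successful merge consumes *both* parents; a parent consumed by any
merge (left or right) is not reported, while unconsumed frequent
intervals are reported even when a sibling merged elsewhere — "the
individual itemsets are kept" applies to the failure branch only. The
search stops when a round produces no new interval, and the maximal
patterns are returned sorted by (start, end). A candidate interval is
unique to one parent pair per round, so no deduplication is needed.

At δ = 1 the frequent family is exactly the recursive-weak family, and
the reported patterns equal the maximal intervals of the independent DP
enumerator (tested on random matrices). At ε = 0 the model collapses to
classical exact-support interval mining. Two qualitative monotonicities
follow and are asserted on a fixed cohort: probe coverage of reported
patterns is non-increasing in sup_min and, at δ = 1, non-decreasing in ε.
No such monotonicity holds in δ, which gates individual merges.

## Hyper-parameters

| parameter | range | default | meaning |
|---|---|---|---|
| `sup_min` | (0, 1] | required | minimum support fraction; integer requirement ⌈sup_min·n⌉ |
| `epsilon` | [0, 1) | 0.0 | tolerated fraction of 0s in a pattern's submatrix |
| `delta` | [0, 1] | 1.0 | maximum Jaccard distance between support sets of merged intervals |
| `tau` | ≥ 0 | data-driven | binarization threshold on the log-ratio scale |

`sup_min` is a fraction, never a count; CLI arguments above 1 are
rejected rather than reinterpreted. Working points that behave well on
array-scale data: sup_min 0.1–0.3, ε 0.2–0.4, δ 0.1–0.4.

## Group-specificity testing

For each pattern the cohort splits into support and non-support groups;
a Pearson χ² statistic on the 2 × K table (K sample groups) is referred
to the χ² distribution with K − 1 degrees of freedom, without continuity
correction. The 2 × K form (rather than collapsing to target-vs-rest
2 × 2) is used because the question is association with the grouping as
a whole. A zero group margin flags the pattern instead of testing it;
expected counts below 5 warn but do not switch methods. The default
filter keeps p < 10⁻³ per pattern with no multiplicity adjustment — the
convention for this style of screen — and an optional Bonferroni mode is
available but off by default. Region output is 1-based inclusive base
pairs (positions of the first and last probe); internal probe indices and
the sample indices in pattern files are 0-based.

## Synthetic cohorts

`generate_binary_cohort` draws i.i.d. Bernoulli background noise and
overwrites rectangular implants — a contiguous probe interval × a sample
subset drawn uniformly without replacement — with per-cell presence
probability `presence_prob` (1 − flip-out noise); overlapping implants
OR. `generate_intensity_cohort` is the continuous analogue: N(0,
noise_sd²) background, implants shifted by ±shift_mean with Gaussian
jitter. Both are pure functions of their arguments including the seed.

What this emulates: subgroup-specific CNV regions over a sparse
background of isolated calls, with realistic dropout inside a true
region. What it does not emulate: GC/wave artifacts, probe-density
variation, segmentation autocorrelation of real LRR data, linked or
nested CNV architecture, and family structure. Passing recovery tests
therefore demonstrates algorithmic correctness under the stated noise
model, not calling accuracy on real arrays.

Default study conditions used by the recovery checks: m = 120–200 probes,
n = 50–60 samples, background density 0.02, implant presence 0.9, implant
sample fraction 0.3–0.4, mined at sup_min below the implant fraction with
ε = 0.2. Under these conditions the mean best cell-Jaccard against truth
across 20 seeds is ≥ 0.8; with zero noise and ε = 0 recovery is exact
(intervals and sample sets). Exactness at ε > 0 is deliberately *not*
claimed: the weak density condition provably admits all-zero columns
(up to ⌊carriers/(1−ε)⌋ total samples), which is the documented
weak-vs-strong trade-off, not a bug. Oracle-equivalence tests run at
n ≤ 12 samples and m ≤ 40 probes, where exhaustive enumeration is exact
and fast; these sizes are a property of the oracle's 2^n cost, and the
greedy computation they certify is size-independent.

## Known limitations

- No significance measure is attached to patterns themselves (that would
  require swap-permutation null models and multiple-testing control);
  the χ² test addresses group association of a given pattern only.
- The miner reports one maximizing support set per pattern; other sets of
  the same size may exist.
- Asymmetric gain/loss thresholds are not offered; τ is symmetric.
- Per-chromosome matrices are mined independently; patterns cannot span
  assembly gaps or chromosome boundaries by design.
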