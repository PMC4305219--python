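# cnvminer

Error-tolerant subspace pattern mining of copy-number variation (CNV)
regions shared by arbitrary sample subsets.

## The problem

SNP-array and aCGH studies produce a probe × sample matrix of log
intensity ratios (log R ratios); a run of adjacent probes with shifted
values in a sample marks a copy-number gain or loss. Cohort questions such
as *"which chromosomal fragments show nearly identical deletions in more
than 30% of the individuals?"* require finding regions that are aberrant
in an **arbitrary subset** of samples — not just regions recurrent across
the whole cohort — and the data are noisy, so a shared region rarely has
every probe called in every carrier.

`cnvminer` treats the thresholded matrix as a transaction database (probes
= items, samples = transactions) and mines **recursive weak error-tolerant
itemsets (ETIs) under a spatial constraint**: the only admissible itemsets
are contiguous probe intervals, and an interval I is frequent when some
sample subset T′ with |T′| ≥ ⌈sup_min · n⌉ satisfies

```
( Σ_{i∈I} Σ_{t∈T′} D[i,t] ) / ( |I| · |T′| )  ≥  1 − ε
```

together with the same condition on every contiguous sub-interval of I
(the recursion that prunes the level-wise search). Singletons get no
tolerance: their support is the exact carrier fraction. The search merges
adjacent frequent intervals Apriori-style; a merge additionally requires
the parents' support sets to be similar — Jaccard distance ≤ δ — so a
ubiquitous probe cannot absorb a rarer neighbour into one washed-out
region. Intervals never consumed by a successful merge are reported as the
maximal patterns, each with its maximizing support set. Gains and losses
are binarized (|log ratio| > τ, sign-split) and mined separately.

Mined patterns can then be tested for group specificity (a Pearson χ² test
of support-set membership against sample groups such as populations or
survival strata, 2×K table, K−1 degrees of freedom) and mapped back to
genomic base-pair regions.

## Worked example

The package ships a 7-probe × 10-sample toy cohort
(`cnvminer.worked_example_fixture()`) in which probe i1 is carried by 4/10
samples, probes i2–i5 by the same 6 samples, i6 by all 10 and i7 by a
nested 5:

```python
from cnvminer import CNVPatternMiner, worked_example_fixture

B, params = worked_example_fixture()          # sup_min=0.5, epsilon=0.2, delta=0.4
res = CNVPatternMiner(B, params.sup_min, params.epsilon, params.delta).fit()
print(res.summary())
```

```
CNV subspace pattern mining results
===================================================
samples: 10    probes: 7    matrices: 1
sup_min: 0.5 (>= 5 samples)    epsilon: 0.2    delta: 0.4
patterns: 2   of size >= 2: 1   probes covered: 6
---------------------------------------------------
chromosome direction  start_probe  end_probe  size  bp_start  bp_stop  support_count  support
      chr1      gain            1          5     5      2000     6000              8      0.8
      chr1      gain            6          6     1      7000     7000              5      0.5
```

Reading the run: probe i1 (index 0) has exact support 0.4 < sup_min and is
pruned before any merge. Probes i2–i6 (indices 1–5) coalesce into one
maximal pattern whose weak support is 0.8 — eight samples whose joint
submatrix is ≥ 80% ones. The i6+i7 merge is *rejected* even though the
candidate's weak support would also be 0.8: the parents' support sets (all
10 samples vs a nested 5) disagree on 5/10 = 0.5 of the union, which
exceeds δ = 0.4, so i7 (index 6) is reported as its own singleton pattern
with support 0.5.

The same run from a shell (`chr_data` is a probe-ID-first 0/1 table, one
row per probe in genomic order):

```sh
cnvmine chr1.bin 0.5 0.2 0.4 > patterns.txt
```

Subcommands `binarize`, `mine`, `stats` and `simulate` cover thresholding
intensity tables, genome-wide runs over several chromosome files, χ²
group-specificity testing and seeded synthetic cohorts; see
`cnvmine --help`.

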