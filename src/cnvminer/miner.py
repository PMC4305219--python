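"""Level-wise mining of error-tolerant frequent probe intervals.

The search space is the set of contiguous probe intervals (the spatial
constraint: probes involved in one CNV event are genomically adjacent).
An interval I is frequent when it is a *recursive weak error-tolerant
itemset*: some sample subset T' of size >= ceil(sup_min * n) has average
1-density >= 1 - epsilon over the I x T' submatrix, and every contiguous
sub-interval of I satisfies the same condition.  Singletons get no
tolerance: their support is the exact fraction of samples carrying them.

The search proceeds Apriori-style in rounds.  Round 1 keeps the frequent
singletons.  Round k -> k+1 tries to merge each adjacent pair of frequent
size-k intervals; the merge additionally requires the two parents' support
sets to be similar (Jaccard distance <= delta), which stops a ubiquitous
probe from absorbing its rarer neighbours into one washed-out region.  A
successful merge consumes both parents; intervals never consumed are
reported as the maximal patterns.

Weak-ETI support is computed exactly by a greedy prefix scheme: ranking
samples by their 1-count inside the interval (descending, ties by ascending
index) and taking the longest prefix whose cumulative density meets
1 - epsilon.  For every subset size the top-count prefix maximizes the
total number of 1s, so the longest feasible prefix attains the global
maximum over all sample subsets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .datatypes import (
    BinaryMatrix,
    Direction,
    Interval,
    MergeDecision,
    MergeReason,
    MiningParams,
    Pattern,
    ValidationError,
)

__all__ = [
    "singleton_support",
    "weak_eti_support",
    "is_adjacent",
    "merge_dissimilarity",
    "is_recursive_weak",
    "mine_chromosome",
    "mine_genome",
]

logger = logging.getLogger(__name__)


def _chromosome_of(B: BinaryMatrix) -> str:
    chroms = B.track.chromosomes
    if len(chroms) != 1:
        raise ValidationError(
            f"matrix spans {len(chroms)} chromosomes; mine_chromosome expects one "
            "(use mine_genome for multi-chromosome input)"
        )
    return chroms[0]


def singleton_support(
    B: BinaryMatrix, probe: int, sup_min: float
) -> Pattern | None:
    """Exact support of one probe; None if below the support threshold.

    Singletons get no error tolerance: the support set is exactly the
    samples with a 1 at this probe.
    """
    m, n = B.shape
    if not (0 <= probe < m):
        raise IndexError(f"probe index {probe} out of range [0, {m})")
    carriers = np.flatnonzero(B.cells[probe]).tolist()
    need = MiningParams(sup_min).min_count(n)
    if len(carriers) < need:
        return None
    return Pattern(
        Interval(probe, probe, _chromosome_of(B)),
        carriers,
        support=len(carriers) / n,
        direction=B.direction,
    )


def weak_eti_support(
    B: BinaryMatrix, iv: Interval, epsilon: float
) -> tuple[float, tuple[int, ...]]:
    """Maximum weak-ETI support of an interval and one maximizing sample set.

    Returns the largest |T'|/n over sample subsets T' whose submatrix
    density over ``iv`` is >= 1 - epsilon, with the maximizing prefix set
    (sample indices ascending).  Size-1 intervals use exact support
    (epsilon forced to 0).  Returns (0.0, ()) when no sample qualifies.
    """
    m, n = B.shape
    if not (0 <= iv.start <= iv.end < m):
        raise IndexError(f"interval [{iv.start}, {iv.end}] out of range for m={m}")
    if iv.size == 1:
        epsilon = 0.0
    counts = B.cells[iv.start : iv.end + 1].sum(axis=0).astype(np.int64)
    # rank: count descending, ties broken by ascending sample index
    order = np.lexsort((np.arange(n), -counts))
    csum = np.cumsum(counts[order])
    k_range = np.arange(1, n + 1)
    # density >= 1-eps  <=>  csum >= (1-eps) * size * k  (integer-safe margin)
    feasible = csum >= (1.0 - epsilon) * iv.size * k_range - 1e-9
    # density is non-increasing along the prefix, so feasibility is a prefix
    if not feasible[0]:
        return 0.0, ()
    k = int(np.max(np.flatnonzero(feasible))) + 1
    tset = tuple(sorted(int(i) for i in order[:k]))
    return k / n, tset


def is_adjacent(a: Interval, b: Interval) -> bool:
    """True when two same-size intervals differ only in first and last probe.

    Equivalently their union is one contiguous interval of size k+1 and they
    overlap in k-1 probes — the only pairs the level-wise merge considers.
    """
    if a.chromosome != b.chromosome or a.size != b.size:
        return False
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return hi.start == lo.start + 1


def merge_dissimilarity(s1: Iterable[int], s2: Iterable[int]) -> float:
    """Fraction of non-overlapping samples between two support sets.

    Jaccard distance |s1 ^ s2| / |s1 | s2|: 0 iff identical, 1 iff disjoint.
    A merge is permitted iff this is <= delta.
    """
    a, b = set(s1), set(s2)
    if not a or not b:
        raise ValidationError("merge_dissimilarity requires non-empty support sets")
    union = a | b
    return len(a ^ b) / len(union)


def is_recursive_weak(
    B: BinaryMatrix,
    iv: Interval,
    params: MiningParams,
    frequent_table: dict[tuple[int, int], Pattern],
) -> bool:
    """Is ``iv`` a recursive weak ETI given its sub-intervals' status?

    True iff the interval's own weak support meets sup_min and both maximal
    proper sub-intervals are in ``frequent_table`` — which, level-wise,
    certifies every contiguous sub-interval.  The table must already hold
    the status of all proper sub-intervals (guaranteed by level-wise order);
    a missing entry for a frequent parent is an internal-invariant error.
    """
    n = B.shape[1]
    if iv.size == 1:
        return singleton_support(B, iv.start, params.sup_min) is not None
    left = (iv.start, iv.end - 1)
    right = (iv.start + 1, iv.end)
    if left not in frequent_table or right not in frequent_table:
        return False
    support, tset = weak_eti_support(B, iv, params.epsilon)
    return len(tset) >= params.min_count(n)


def mine_chromosome(
    B: BinaryMatrix,
    params: MiningParams,
    decisions: list[MergeDecision] | None = None,
) -> list[Pattern]:
    """Mine all maximal frequent intervals of one chromosome, one direction.

    Returns frequent intervals never consumed by a successful merge, each
    with its maximizing support set, sorted by (start, end).  Passing a list
    as ``decisions`` records every attempted merge for inspection.
    """
    m, n = B.shape
    chrom = _chromosome_of(B)
    need = params.min_count(n)

    # round 1: frequent singletons, exact support
    frequent: dict[tuple[int, int], Pattern] = {}
    level: list[Pattern] = []
    for probe in range(m):
        pat = singleton_support(B, probe, params.sup_min)
        if pat is not None:
            frequent[(probe, probe)] = pat
            level.append(pat)
    consumed: set[tuple[int, int]] = set()

    while len(level) > 1:
        by_start = {p.interval.start: p for p in level}
        next_level: list[Pattern] = []
        for left in level:
            right = by_start.get(left.interval.start + 1)
            if right is None:
                continue
            d = merge_dissimilarity(left.support_set, right.support_set)
            cand = Interval(left.interval.start, right.interval.end, chrom)
            if d > params.delta:
                support, _ = weak_eti_support(B, cand, params.epsilon)
                logger.debug(
                    "merge %s + %s rejected: dissimilarity %.3f > delta %.3f "
                    "(candidate weak support would be %.3f)",
                    left.interval, right.interval, d, params.delta, support,
                )
                if decisions is not None:
                    decisions.append(
                        MergeDecision(left.interval, right.interval, d,
                                      MergeReason.DELTA_EXCEEDED, support)
                    )
                continue
            support, tset = weak_eti_support(B, cand, params.epsilon)
            if len(tset) >= need and is_recursive_weak(B, cand, params, frequent):
                pat = Pattern(cand, tset, support=support, direction=B.direction)
                frequent[(cand.start, cand.end)] = pat
                next_level.append(pat)
                consumed.add((left.interval.start, left.interval.end))
                consumed.add((right.interval.start, right.interval.end))
                if decisions is not None:
                    decisions.append(
                        MergeDecision(left.interval, right.interval, d,
                                      MergeReason.ACCEPTED, support)
                    )
            else:
                if decisions is not None:
                    decisions.append(
                        MergeDecision(left.interval, right.interval, d,
                                      MergeReason.SUPPORT_BELOW_MIN, support)
                    )
        level = next_level

    maximal = [
        pat for key, pat in frequent.items() if key not in consumed
    ]
    maximal.sort(key=lambda p: (p.interval.start, p.interval.end))
    return maximal


def split_by_chromosome(B: BinaryMatrix) -> list[tuple[int, BinaryMatrix]]:
    """Split a matrix into per-chromosome blocks, keeping the row offsets."""
    from .datatypes import ProbeTrack  # local to avoid cycle at import time

    blocks: list[tuple[int, BinaryMatrix]] = []
    start = 0
    chrom = B.track.chromosome
    m = B.shape[0]
    for i in range(1, m + 1):
        if i == m or chrom[i] != chrom[start]:
            sub_track = ProbeTrack(
                B.track.probe_ids[start:i],
                chrom[start:i],
                B.track.position_bp[start:i],
            )
            blocks.append(
                (
                    start,
                    BinaryMatrix(
                        B.cells[start:i],
                        sample_ids=B.sample_ids,
                        track=sub_track,
                        direction=B.direction,
                    ),
                )
            )
            start = i
    return blocks


def _shift(pat: Pattern, offset: int) -> Pattern:
    if offset == 0:
        return pat
    iv = pat.interval
    return Pattern(
        Interval(iv.start + offset, iv.end + offset, iv.chromosome),
        pat.support_set,
        support=pat.support,
        direction=pat.direction,
    )


def mine_matrix(B: BinaryMatrix, params: MiningParams) -> list[Pattern]:
    """Mine a (possibly multi-chromosome) matrix; intervals never cross
    chromosome boundaries and are reported in global probe coordinates."""
    out: list[Pattern] = []
    for offset, block in split_by_chromosome(B):
        out.extend(_shift(p, offset) for p in mine_chromosome(block, params))
    return out


def mine_genome(
    matrices: Sequence[BinaryMatrix], params: MiningParams
) -> list[Pattern]:
    """Mine each per-chromosome matrix independently and concatenate.

    Patterns never span chromosome boundaries; gain and loss matrices are
    mined separately and keep their direction labels.  All matrices must
    share the same sample IDs (same cohort, same column order).
    """
    if not matrices:
        return []
    ref_ids = matrices[0].sample_ids
    for B in matrices[1:]:
        if B.sample_ids != ref_ids:
            raise ValidationError("inconsistent sample_ids across chromosome matrices")
    out: list[Pattern] = []
    for B in matrices:
        out.extend(mine_matrix(B, params))
    return out
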