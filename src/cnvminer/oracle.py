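"""Independent brute-force references for testing the miner.

These implementations exhaustively enumerate sample subsets (weak-ETI
support), check the per-sample strong-ETI condition, and enumerate the full
recursive-weak frequent-interval family by dynamic programming over all
intervals.  They are exponential/quadratic by intent, size-guarded, and
deliberately share no code with the production search path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .datatypes import BinaryMatrix, Interval, MiningParams, ValidationError

__all__ = [
    "OracleResult",
    "bruteforce_weak_support",
    "check_strong_eti",
    "mine_bruteforce",
]

_MAX_N = 16
_MAX_M = 40


@dataclass(frozen=True)
class OracleResult:
    interval: Interval
    best_support: float
    best_set: tuple[int, ...]
    is_strong: bool


def _guard(B: BinaryMatrix, max_m: int | None = None) -> tuple[int, int]:
    m, n = B.shape
    if n > _MAX_N:
        raise ValidationError(f"oracle guard: n={n} > {_MAX_N} samples")
    if max_m is not None and m > max_m:
        raise ValidationError(f"oracle guard: m={m} > {max_m} probes")
    return m, n


def bruteforce_weak_support(
    B: BinaryMatrix, iv: Interval, epsilon: float
) -> OracleResult:
    """Exhaustive weak-ETI support: maximize |T'| over all 2^n sample subsets
    subject to submatrix density >= 1 - epsilon.

    Among maximizing subsets the lexicographically smallest is returned, so
    only the support *size* is comparable with the greedy implementation.
    """
    m, n = _guard(B)
    counts = B.cells[iv.start : iv.end + 1].sum(axis=0).astype(np.int64)
    size = iv.size
    # enumerate every subset as a bitmask; total 1s and cardinality per mask
    masks = np.arange(1 << n, dtype=np.int64)
    totals = np.zeros(1 << n, dtype=np.int64)
    popcnt = np.zeros(1 << n, dtype=np.int64)
    for b in range(n):
        bit = (masks >> b) & 1
        totals += bit * counts[b]
        popcnt += bit
    feasible = (popcnt > 0) & (
        totals >= (1.0 - epsilon) * size * popcnt - 1e-9
    )
    if not feasible.any():
        return OracleResult(iv, 0.0, (), False)
    k = int(popcnt[feasible].max())
    cand = np.flatnonzero(feasible & (popcnt == k))
    subsets = [
        tuple(b for b in range(n) if (int(mask) >> b) & 1) for mask in cand
    ]
    best = min(subsets)
    strong = check_strong_eti(B, iv, epsilon, best)
    return OracleResult(iv, k / n, best, strong)


def check_strong_eti(
    B: BinaryMatrix, iv: Interval, epsilon: float, tset: Iterable[int]
) -> bool:
    """Strong-ETI condition: every sample in tset individually has
    in-interval density >= 1 - epsilon."""
    tset = tuple(tset)
    if not tset:
        raise ValidationError("check_strong_eti requires a non-empty sample set")
    sub = B.cells[iv.start : iv.end + 1][:, list(tset)]
    dens = sub.mean(axis=0)
    return bool((dens >= 1.0 - epsilon - 1e-9).all())


def mine_bruteforce(
    B: BinaryMatrix, params: MiningParams
) -> tuple[dict[tuple[int, int], float], list[Interval]]:
    """DP enumeration of all recursive-weak frequent intervals (delta = 1).

    frequent(a, b) := brute-force weak support >= sup_min AND
    frequent(a, b-1) AND frequent(a+1, b); singletons use exact support with
    no tolerance.  Returns the table {(a, b): support} of frequent intervals
    and the maximal ones (those contained in no larger frequent interval).
    """
    if params.delta != 1.0:
        raise ValidationError("the DP oracle only models delta = 1")
    m, n = _guard(B, max_m=_MAX_M)
    chrom = B.track.chromosomes[0]
    need = params.min_count(n)
    table: dict[tuple[int, int], float] = {}
    for a in range(m):
        count = int(B.cells[a].sum())
        if count >= need:
            table[(a, a)] = count / n
    for size in range(2, m + 1):
        for a in range(0, m - size + 1):
            b = a + size - 1
            if (a, b - 1) not in table or (a + 1, b) not in table:
                continue
            res = bruteforce_weak_support(B, Interval(a, b, chrom), params.epsilon)
            if len(res.best_set) >= need:
                table[(a, b)] = res.best_support
    maximal = [
        Interval(a, b, chrom)
        for (a, b) in table
        if (a - 1, b) not in table and (a, b + 1) not in table
    ]
    maximal.sort()
    return table, maximal
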