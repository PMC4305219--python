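"""Post-mining evaluation of patterns.

Group specificity: for each pattern the cohort splits into the support
group (samples in the pattern's maximizing set) and the non-support group;
a Pearson chi-squared test on the resulting 2 x K contingency table (K
sample groups, e.g. populations or survival strata) asks whether support
membership is independent of group.  Small p-values flag patterns whose
carriers concentrate in particular groups.

Also here: mapping probe-index intervals to genomic base-pair regions and
a cohort-level density summary of the mined patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import Pattern, ProbeTrack, ValidationError

__all__ = [
    "GroupLabels",
    "SpecificityResult",
    "specificity_test",
    "filter_specific",
    "pattern_to_region",
    "pattern_density",
    "covered_probes",
    "total_pattern_length",
]


@dataclass(frozen=True)
class GroupLabels:
    """Group assignment of every sample, by index (column order)."""

    labels: tuple[str, ...]

    def __init__(self, labels: Sequence[str] | Mapping[str, str], sample_ids: Sequence[str] | None = None) -> None:
        if isinstance(labels, Mapping):
            if sample_ids is None:
                raise ValidationError("mapping labels require sample_ids for ordering")
            missing = [s for s in sample_ids if s not in labels]
            if missing:
                raise ValidationError(f"samples without group label: {missing[:5]}")
            labels = [labels[s] for s in sample_ids]
        labels = tuple(str(g) for g in labels)
        if len(set(labels)) < 2:
            raise ValidationError("need K >= 2 distinct groups")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def groups(self) -> tuple[str, ...]:
        """Distinct group names, in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.labels:
            seen.setdefault(g, None)
        return tuple(seen)


@dataclass(frozen=True)
class SpecificityResult:
    pattern: Pattern
    groups: tuple[str, ...]
    contingency: np.ndarray  # 2 x K: support / non-support counts per group
    statistic: float
    dof: int
    p_value: float
    flagged: bool = False  # zero column margin: test not performed

    @property
    def specific(self) -> bool:
        return not self.flagged


def specificity_test(pattern: Pattern, labels: GroupLabels) -> SpecificityResult:
    """Pearson chi-squared test of support-group membership vs sample group.

    The 2 x K table counts the pattern's supporting and non-supporting
    samples per group.  No continuity correction; dof = K - 1 (the support
    margin is fixed).  A zero column margin (an empty group) flags the
    result instead of testing; small expected counts only warn.
    """
    n = len(labels)
    groups = labels.groups
    K = len(groups)
    if K < 2:
        raise ValidationError("need K >= 2 groups")
    if max(pattern.support_set) >= n:
        raise ValidationError("pattern references a sample index beyond the labels")
    in_support = np.zeros(n, dtype=bool)
    in_support[list(pattern.support_set)] = True
    table = np.zeros((2, K), dtype=np.int64)
    for j, g in enumerate(groups):
        members = np.array([lab == g for lab in labels.labels])
        table[0, j] = int((members & in_support).sum())
        table[1, j] = int((members & ~in_support).sum())
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    if (col == 0).any() or (row == 0).any():
        return SpecificityResult(
            pattern, groups, table, float("nan"), K - 1, float("nan"), flagged=True
        )
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        warnings.warn(
            "chi-squared expected count below 5; asymptotic p-value may be unreliable",
            stacklevel=2,
        )
    statistic = float(((table - expected) ** 2 / expected).sum())
    dof = K - 1
    p_value = float(sps.chi2.sf(statistic, dof))
    return SpecificityResult(pattern, groups, table, statistic, dof, p_value)


def filter_specific(
    results: Sequence[SpecificityResult],
    alpha: float = 1e-3,
    bonferroni: bool = False,
) -> list[SpecificityResult]:
    """Keep results with p < alpha; flagged results never pass.

    No multiplicity adjustment by default (per-pattern threshold
    convention); ``bonferroni=True`` divides alpha by the number of tested
    patterns.
    """
    tested = [r for r in results if not r.flagged]
    cut = alpha / len(tested) if (bonferroni and tested) else alpha
    return [r for r in tested if r.p_value < cut]


def pattern_to_region(pattern: Pattern, track: ProbeTrack) -> tuple[str, int, int]:
    """Genomic region of a pattern: (chromosome, bp_start, bp_stop),
    1-based inclusive base pairs (positions of the first and last probe)."""
    iv = pattern.interval
    if iv.end >= len(track):
        raise ValidationError("pattern extends beyond the probe track")
    chroms = {track.chromosome[i] for i in iv.probes()}
    if len(chroms) != 1 or iv.chromosome not in chroms:
        raise ValidationError(
            f"pattern chromosome {iv.chromosome!r} does not match track rows {sorted(chroms)}"
        )
    return iv.chromosome, track.position_bp[iv.start], track.position_bp[iv.end]


def region_to_interval(
    track: ProbeTrack, chromosome: str, bp_start: int, bp_stop: int
) -> tuple[int, int]:
    """Inverse lookup: probe-index span [i, j] covered by a bp region."""
    idx = [
        i
        for i in range(len(track))
        if track.chromosome[i] == chromosome
        and bp_start <= track.position_bp[i] <= bp_stop
    ]
    if not idx:
        raise ValidationError("region covers no probe of the track")
    return idx[0], idx[-1]


def pattern_density(patterns: Sequence[Pattern], m: int, n: int) -> float:
    """Fraction of the m x n cells covered by at least one pattern.

    Cells are counted once per direction (a gain pattern and a loss pattern
    on the same cell are distinct events), overlapping same-direction
    patterns once.
    """
    if m <= 0 or n <= 0:
        raise ValidationError("m and n must be positive")
    covered: set[tuple[str, int, int, str]] = set()
    for p in patterns:
        d = p.direction.value
        c = p.interval.chromosome
        for i in p.interval.probes():
            for t in p.support_set:
                covered.add((c, i, t, d))
    return len(covered) / (m * n)


def covered_probes(patterns: Sequence[Pattern]) -> set[tuple[str, int]]:
    """Distinct (chromosome, probe index) pairs covered by the patterns."""
    out: set[tuple[str, int]] = set()
    for p in patterns:
        for i in p.interval.probes():
            out.add((p.interval.chromosome, i))
    return out


def total_pattern_length(patterns: Sequence[Pattern], min_size: int = 1) -> int:
    """Number of distinct probes in patterns of at least ``min_size`` probes
    (the usual summary for parameter sweeps)."""
    return len(covered_probes([p for p in patterns if p.size >= min_size]))
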