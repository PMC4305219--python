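"""Core containers for interval-constrained CNV pattern mining.

The mining formulation treats a probe x sample matrix as a transaction
database: probes are items, samples are transactions.  Because CNV events
span runs of genomically adjacent probes, the only admissible itemsets are
contiguous probe intervals; these types carry the probe ordering metadata
that makes that spatial constraint meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Direction",
    "ProbeTrack",
    "IntensityMatrix",
    "BinarizeParams",
    "BinaryMatrix",
    "Interval",
    "MiningParams",
    "Pattern",
    "MergeDecision",
    "MergeReason",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data or parameters violate a documented contract."""


class Direction(str, Enum):
    """Direction of a copy-number change relative to the reference."""

    GAIN = "gain"
    LOSS = "loss"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_direction(d: "Direction | str") -> Direction:
    if isinstance(d, Direction):
        return d
    try:
        return Direction(str(d).lower())
    except ValueError:
        raise ValidationError(f"unknown direction {d!r}; expected 'gain' or 'loss'")


@dataclass(frozen=True)
class ProbeTrack:
    """Genomic annotation of the probe axis: IDs, chromosome, position.

    Probes must appear in genomic order within each chromosome (positions
    non-decreasing); the interval constraint of the miner is meaningless on
    unsorted probes, so disorder is rejected loudly.
    """

    probe_ids: tuple[str, ...]
    chromosome: tuple[str, ...]
    position_bp: tuple[int, ...]

    def __init__(
        self,
        probe_ids: Sequence[str],
        chromosome: Sequence[str] | str,
        position_bp: Sequence[int],
    ) -> None:
        probe_ids = tuple(str(p) for p in probe_ids)
        if isinstance(chromosome, str):
            chromosome = (chromosome,) * len(probe_ids)
        chromosome = tuple(str(c) for c in chromosome)
        position_bp = tuple(int(p) for p in position_bp)
        if not (len(probe_ids) == len(chromosome) == len(position_bp)):
            raise ValidationError("probe_ids, chromosome and position_bp lengths differ")
        if len(set(probe_ids)) != len(probe_ids):
            raise ValidationError("duplicate probe IDs in track")
        if any(p < 0 for p in position_bp):
            raise ValidationError("negative base-pair position in track")
        # positions must be sorted within each chromosome block
        for i in range(1, len(probe_ids)):
            if chromosome[i] == chromosome[i - 1] and position_bp[i] < position_bp[i - 1]:
                raise ValidationError(
                    f"probe {probe_ids[i]!r} out of genomic order on "
                    f"chromosome {chromosome[i]!r} (bp {position_bp[i]} < {position_bp[i-1]})"
                )
        object.__setattr__(self, "probe_ids", probe_ids)
        object.__setattr__(self, "chromosome", chromosome)
        object.__setattr__(self, "position_bp", position_bp)

    def __len__(self) -> int:
        return len(self.probe_ids)

    @classmethod
    def default(cls, m: int, chromosome: str = "chr1", spacing: int = 1000) -> "ProbeTrack":
        """Evenly spaced synthetic track: probe_0..probe_{m-1} on one chromosome."""
        return cls(
            [f"probe_{i}" for i in range(m)],
            chromosome,
            [spacing * (i + 1) for i in range(m)],
        )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        """Distinct chromosome labels in track order."""
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return tuple(seen)


def _check_track(track: ProbeTrack | None, m: int) -> ProbeTrack:
    if track is None:
        return ProbeTrack.default(m)
    if len(track) != m:
        raise ValidationError(f"track length {len(track)} != probe dimension {m}")
    return track


@dataclass(frozen=True)
class IntensityMatrix:
    """Continuous log-intensity-ratio matrix, probes (rows) x samples (cols).

    Entries near 0 indicate normal copy number; positive / negative
    excursions are candidate gains / losses.  Entries must be finite:
    missing values are rejected at construction, naming the first offender,
    unless ``fill_missing`` zero-fills them (the number filled is recorded
    in ``n_filled``).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    track: ProbeTrack
    n_filled: int = 0

    def __init__(
        self,
        values: np.ndarray,
        sample_ids: Sequence[str] | None = None,
        track: ProbeTrack | None = None,
        fill_missing: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError("intensity matrix must be 2-D with m>=1, n>=1")
        m, n = values.shape
        n_filled = 0
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            if fill_missing:
                n_filled = len(bad)
                values = np.where(np.isfinite(values), values, 0.0)
            else:
                i, j = bad[0]
                track_ = _check_track(track, m)
                sid = sample_ids[j] if sample_ids is not None else f"sample_{j}"
                raise ValidationError(
                    f"non-finite intensity at probe {track_.probe_ids[i]!r}, "
                    f"sample {sid!r}; impute or pass fill_missing=True"
                )
        if sample_ids is None:
            sample_ids = tuple(f"sample_{j}" for j in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
            if len(sample_ids) != n:
                raise ValidationError("sample_ids length != sample dimension")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "track", _check_track(track, m))
        object.__setattr__(self, "n_filled", n_filled)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinarizeParams:
    """Threshold tau (on |log ratio|) and direction for binarization."""

    tau: float
    direction: Direction

    def __init__(self, tau: float, direction: Direction | str) -> None:
        tau = float(tau)
        if not (tau >= 0.0 and np.isfinite(tau)):
            raise ValidationError(f"tau must be a finite non-negative real, got {tau}")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "direction", _as_direction(direction))


@dataclass(frozen=True)
class BinaryMatrix:
    """0/1 candidate-CNV indicator matrix, probes x samples, one direction.

    This is the transaction database D the miner consumes: D[j, k] = 1 means
    probe j is a candidate gain (or loss) in sample k.  Gain and loss
    matrices derived from the same intensities are cell-wise disjoint.
    """

    cells: np.ndarray
    sample_ids: tuple[str, ...]
    track: ProbeTrack
    direction: Direction

    def __init__(
        self,
        cells: np.ndarray,
        sample_ids: Sequence[str] | None = None,
        track: ProbeTrack | None = None,
        direction: Direction | str = Direction.GAIN,
    ) -> None:
        cells = np.asarray(cells)
        if cells.ndim != 2 or cells.shape[0] < 1 or cells.shape[1] < 1:
            raise ValidationError("binary matrix must be 2-D with m>=1, n>=1")
        if not np.isin(cells, (0, 1)).all():
            raise ValidationError("binary matrix entries must be 0 or 1")
        cells = cells.astype(np.uint8)
        m, n = cells.shape
        if sample_ids is None:
            sample_ids = tuple(f"sample_{j}" for j in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
            if len(sample_ids) != n:
                raise ValidationError("sample_ids length != sample dimension")
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "track", _check_track(track, m))
        object.__setattr__(self, "direction", _as_direction(direction))

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def density(self) -> float:
        """Fraction of 1 cells."""
        return float(self.cells.mean())


@dataclass(frozen=True, order=True)
class Interval:
    """Contiguous run of probe indices on one chromosome, both ends inclusive."""

    start: int
    end: int
    chromosome: str = "chr1"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValidationError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def probes(self) -> range:
        return range(self.start, self.end + 1)

    def contains(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class MiningParams:
    """The three user hyper-parameters of the search.

    sup_min : minimum support as a fraction of samples in (0, 1]; a pattern
        needs at least ceil(sup_min * n) supporting samples.
    epsilon : error-tolerance rate in [0, 1); a sample subset T' supports an
        interval I when the 1-density of the I x T' submatrix is >= 1 - epsilon.
    delta : merge threshold in [0, 1]; two intervals may merge only if the
        Jaccard distance between their support sets is <= delta (0 = identical
        support required, 1 = unconstrained).
    """

    sup_min: float
    epsilon: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sup_min <= 1.0):
            raise ValidationError(f"sup_min must be in (0, 1], got {self.sup_min}")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValidationError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValidationError(f"delta must be in [0, 1], got {self.delta}")

    def min_count(self, n: int) -> int:
        """Integer support requirement for n samples (at least 1)."""
        return max(1, int(np.ceil(self.sup_min * n - 1e-12)))


@dataclass(frozen=True)
class Pattern:
    """A frequent interval with its maximizing support set.

    support_set holds the sample indices of one maximizing transaction set
    T' (ascending); support = |T'| / n.
    """

    interval: Interval
    support_set: tuple[int, ...]
    support: float
    direction: Direction

    def __init__(
        self,
        interval: Interval,
        support_set: Sequence[int],
        support: float | None = None,
        direction: Direction | str = Direction.GAIN,
        n_samples: int | None = None,
    ) -> None:
        support_set = tuple(sorted(int(i) for i in support_set))
        if not support_set:
            raise ValidationError("pattern support_set must be non-empty")
        if support is None:
            if n_samples is None:
                raise ValidationError("need support or n_samples")
            support = len(support_set) / n_samples
        object.__setattr__(self, "interval", interval)
        object.__setattr__(self, "support_set", support_set)
        object.__setattr__(self, "support", float(support))
        object.__setattr__(self, "direction", _as_direction(direction))

    @property
    def size(self) -> int:
        return self.interval.size

    @property
    def n_support(self) -> int:
        return len(self.support_set)

    def cells(self) -> set[tuple[int, int]]:
        """The (probe, sample) cells this pattern covers."""
        return {(i, t) for i in self.interval.probes() for t in self.support_set}


class MergeReason(str, Enum):
    NOT_ADJACENT = "not_adjacent"
    DELTA_EXCEEDED = "delta_exceeded"
    SUPPORT_BELOW_MIN = "support_below_min"
    ACCEPTED = "accepted"


@dataclass(frozen=True)
class MergeDecision:
    """Outcome of an attempted merge of two same-size adjacent intervals."""

    left: Interval
    right: Interval
    dissimilarity: float
    reason: MergeReason
    candidate_support: float | None = None

    @property
    def accepted(self) -> bool:
        return self.reason is MergeReason.ACCEPTED
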