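"""Synthetic CNV cohorts with implanted subgroup-specific aberrations.

Real array cohorts carry CNV regions shared by sample subsets against a
sparse background of isolated candidate calls.  The binary generator
emulates exactly that: i.i.d. Bernoulli background noise plus rectangular
implants (a contiguous probe interval x a drawn sample subset) whose cells
are present with probability ``presence_prob`` (1 minus flip-out noise).
The continuous generator produces Gaussian log-ratio background with
shifted implants, mimicking the normalized log R ratio signal of SNP
arrays.  Generators are pure functions of their arguments, seed included.

The toy worked-example fixture (``worked_example_fixture``) is a reconstruction:
only its singleton and pairwise support values are constrained by the
published worked example, not its exact cell layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    BinaryMatrix,
    Direction,
    IntensityMatrix,
    Interval,
    MiningParams,
    Pattern,
    ProbeTrack,
    ValidationError,
)

__all__ = [
    "ImplantSpec",
    "CohortTruth",
    "generate_binary_cohort",
    "generate_intensity_cohort",
    "worked_example_fixture",
    "recovery_score",
    "RecoveryScore",
]


@dataclass(frozen=True)
class ImplantSpec:
    """One implanted aberrant region: where, in what fraction of samples,
    how cleanly, and (continuous mode) how strongly shifted."""

    interval: Interval
    sample_fraction: float
    direction: Direction = Direction.GAIN
    presence_prob: float = 1.0
    shift_mean: float = 1.0
    shift_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValidationError("sample_fraction must be in (0, 1]")
        if not (0.0 < self.presence_prob <= 1.0):
            raise ValidationError("presence_prob must be in (0, 1]")
        if self.shift_sd < 0:
            raise ValidationError("shift_sd must be non-negative")


@dataclass(frozen=True)
class RealizedImplant:
    spec: ImplantSpec
    samples: tuple[int, ...]

    def cells(self) -> set[tuple[int, int]]:
        return {
            (i, t) for i in self.spec.interval.probes() for t in self.samples
        }


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a generated cohort: realized implants, background
    density and the seed that reproduces it."""

    implants: tuple[RealizedImplant, ...]
    background_density: float
    seed: int


def _draw_samples(rng: np.random.Generator, n: int, frac: float) -> tuple[int, ...]:
    k = max(1, int(round(frac * n)))
    return tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))


def generate_binary_cohort(
    m: int,
    n: int,
    background_density: float,
    implants: list[ImplantSpec] | tuple[ImplantSpec, ...] = (),
    seed: int = 0,
    direction: Direction | str = Direction.GAIN,
    chromosome: str = "chr1",
) -> tuple[BinaryMatrix, CohortTruth]:
    """Sparse Bernoulli background with implanted blocks, fully seeded.

    Background cells are i.i.d. Bernoulli(background_density); implant
    cells are overwritten with Bernoulli(presence_prob) for the drawn
    sample subset.  Overlapping implants combine by OR.
    """
    if not (0.0 <= background_density < 1.0):
        raise ValidationError("background_density must be in [0, 1)")
    for spec in implants:
        if not (0 <= spec.interval.start <= spec.interval.end < m):
            raise ValidationError(f"implant interval {spec.interval} outside [0, {m})")
        if spec.sample_fraction * n < 1:
            raise ValidationError("implant sample_fraction selects no sample")
    rng = np.random.default_rng(seed)
    cells = (rng.random((m, n)) < background_density).astype(np.uint8)
    realized = []
    for spec in implants:
        samples = _draw_samples(rng, n, spec.sample_fraction)
        iv = spec.interval
        block = (
            rng.random((iv.size, len(samples))) < spec.presence_prob
        ).astype(np.uint8)
        sub = cells[iv.start : iv.end + 1][:, samples]
        cells[np.ix_(range(iv.start, iv.end + 1), samples)] = np.maximum(sub, block)
        realized.append(RealizedImplant(spec, samples))
    B = BinaryMatrix(
        cells,
        track=ProbeTrack.default(m, chromosome),
        direction=direction,
    )
    return B, CohortTruth(tuple(realized), background_density, seed)


def generate_intensity_cohort(
    m: int,
    n: int,
    noise_sd: float,
    implants: list[ImplantSpec] | tuple[ImplantSpec, ...] = (),
    seed: int = 0,
    chromosome: str = "chr1",
) -> tuple[IntensityMatrix, CohortTruth]:
    """Gaussian log-ratio background with shifted implanted blocks.

    Background cells ~ N(0, noise_sd^2); implanted cells are shifted by
    +shift_mean (gain) or -shift_mean (loss) with N(0, shift_sd^2) jitter,
    for the drawn sample subset, with per-cell dropout 1 - presence_prob.
    Overlapping implants add their shifts.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    for spec in implants:
        if not (0 <= spec.interval.start <= spec.interval.end < m):
            raise ValidationError(f"implant interval {spec.interval} outside [0, {m})")
        if spec.sample_fraction * n < 1:
            raise ValidationError("implant sample_fraction selects no sample")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(m, n))
    realized = []
    for spec in implants:
        samples = _draw_samples(rng, n, spec.sample_fraction)
        iv = spec.interval
        sign = 1.0 if spec.direction is Direction.GAIN else -1.0
        shift = sign * spec.shift_mean + rng.normal(
            0.0, spec.shift_sd, size=(iv.size, len(samples))
        )
        present = rng.random((iv.size, len(samples))) < spec.presence_prob
        values[np.ix_(range(iv.start, iv.end + 1), samples)] += shift * present
        realized.append(RealizedImplant(spec, samples))
    X = IntensityMatrix(values, track=ProbeTrack.default(m, chromosome))
    return X, CohortTruth(tuple(realized), 0.0, seed)


def worked_example_fixture() -> tuple[BinaryMatrix, MiningParams]:
    """Reconstructed 7-probe x 10-sample toy worked example.

    The layout satisfies every support value the worked example quotes:
    probe i1 present in 4/10 samples (pruned at sup_min=0.5), probes
    i2..i5 in the same 6 samples, i6 in all 10, i7 in 5 samples nested in
    i6's support.  Under (sup_min, epsilon, delta) = (0.5, 0.2, 0.4) the
    i6+i7 merge is rejected on the merge criterion (support-set
    dissimilarity 0.5 > 0.4) even though the candidate's weak support is
    0.8, and probes i2..i6 coalesce into one maximal pattern.
    """
    m, n = 7, 10
    cells = np.zeros((m, n), dtype=np.uint8)
    cells[0, :4] = 1        # i1: support 0.4 -> pruned
    cells[1:5, :6] = 1      # i2..i5: support 0.6, identical sets
    cells[5, :] = 1         # i6: support 1.0
    cells[6, :5] = 1        # i7: support 0.5, nested in i6
    B = BinaryMatrix(cells, track=ProbeTrack.default(m))
    return B, MiningParams(sup_min=0.5, epsilon=0.2, delta=0.4)


@dataclass(frozen=True)
class RecoveryScore:
    """Per-implant best cell-Jaccard and precision/recall/F1 summary."""

    per_implant_jaccard: tuple[float, ...]
    recall: float
    precision: float
    f1: float

    @property
    def mean_jaccard(self) -> float:
        return float(np.mean(self.per_implant_jaccard)) if self.per_implant_jaccard else 0.0


def recovery_score(
    patterns: list[Pattern],
    truth: CohortTruth,
    jaccard_threshold: float = 0.8,
) -> RecoveryScore:
    """Score mined patterns against the implanted ground truth.

    For each implant: the best Jaccard index between its realized cell set
    (probe x sample rectangle) and any reported pattern's cell set.  An
    implant is recovered when that Jaccard is >= ``jaccard_threshold``;
    a pattern is a true positive when it is the best match of some
    recovered implant.  F1 combines recall over implants with precision
    over reported patterns.
    """
    if not truth.implants:
        return RecoveryScore((), 0.0, 0.0, 0.0)
    pat_cells = [p.cells() for p in patterns]
    best_j: list[float] = []
    matched: set[int] = set()
    for implant in truth.implants:
        tc = implant.cells()
        scores = [
            len(tc & pc) / len(tc | pc) if (tc or pc) else 0.0
            for pc in pat_cells
        ]
        if scores:
            j = max(scores)
            if j >= jaccard_threshold:
                matched.add(int(np.argmax(scores)))
        else:
            j = 0.0
        best_j.append(j)
    recovered = sum(1 for j in best_j if j >= jaccard_threshold)
    recall = recovered / len(truth.implants)
    precision = len(matched) / len(patterns) if patterns else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return RecoveryScore(tuple(best_j), recall, precision, f1)
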