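"""Model/Results interface over the interval pattern miner.

``CNVPatternMiner`` wraps a cohort (one or more per-chromosome binary
matrices, or a continuous intensity matrix to be binarized) together with
the mining hyper-parameters; ``fit()`` runs the level-wise search and
returns a ``CNVPatternResults`` carrying the patterns and the usual
post-estimation conveniences: a summary table, group-specificity tests,
genomic region mapping, density summaries and a heatmap plot.

Example
-------
>>> from cnvminer import simulate, CNVPatternMiner
>>> B, truth = simulate.generate_binary_cohort(
...     60, 30, 0.02,
...     [simulate.ImplantSpec(simulate.Interval(20, 29), 0.4)], seed=1)
>>> res = CNVPatternMiner(B, sup_min=0.3, epsilon=0.2, delta=0.5).fit()
>>> len(res.patterns) >= 1
True
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .binarize import binarize, select_tau
from .datatypes import (
    BinarizeParams,
    BinaryMatrix,
    Direction,
    IntensityMatrix,
    MiningParams,
    Pattern,
    ValidationError,
)
from .miner import mine_matrix
from .stats import (
    GroupLabels,
    SpecificityResult,
    filter_specific,
    pattern_density,
    pattern_to_region,
    specificity_test,
    total_pattern_length,
)

__all__ = ["CNVPatternMiner", "CNVPatternResults"]


class CNVPatternMiner:
    """Error-tolerant frequent-interval miner bound to a cohort.

    Parameters
    ----------
    data : BinaryMatrix or sequence of BinaryMatrix
        Per-chromosome binarized cohort(s); matrices must share sample IDs.
    sup_min : float
        Minimum support fraction in (0, 1].
    epsilon : float
        Error-tolerance rate in [0, 1) of the weak density condition.
    delta : float
        Merge threshold in [0, 1] on support-set Jaccard distance.
    """

    def __init__(
        self,
        data: BinaryMatrix | Sequence[BinaryMatrix],
        sup_min: float,
        epsilon: float = 0.0,
        delta: float = 1.0,
    ) -> None:
        if isinstance(data, BinaryMatrix):
            data = [data]
        data = list(data)
        if not data:
            raise ValidationError("need at least one binary matrix")
        ids = data[0].sample_ids
        for B in data[1:]:
            if B.sample_ids != ids:
                raise ValidationError("matrices must share sample IDs")
        self.matrices = data
        self.params = MiningParams(sup_min=sup_min, epsilon=epsilon, delta=delta)

    @classmethod
    def from_intensity(
        cls,
        X: IntensityMatrix,
        sup_min: float,
        epsilon: float = 0.0,
        delta: float = 1.0,
        tau: float | None = None,
        target_density: float | None = None,
        directions: Sequence[Direction | str] = (Direction.GAIN, Direction.LOSS),
    ) -> "CNVPatternMiner":
        """Binarize a continuous cohort and bind the miner to the result.

        Exactly one of ``tau`` / ``target_density`` must be given; both
        requested directions are binarized at the same symmetric threshold
        and mined separately.
        """
        if (tau is None) == (target_density is None):
            raise ValidationError("supply exactly one of tau / target_density")
        if tau is None:
            tau = select_tau(X, target_density)
        mats = [binarize(X, BinarizeParams(tau, d)) for d in directions]
        model = cls(mats, sup_min, epsilon, delta)
        model.tau_ = float(tau)
        return model

    @classmethod
    def from_files(
        cls,
        paths: Sequence[str],
        sup_min: float,
        epsilon: float = 0.0,
        delta: float = 1.0,
        direction: Direction | str = Direction.GAIN,
    ) -> "CNVPatternMiner":
        """Read chr_data files (one per chromosome) and bind the miner."""
        mats = [
            _io.read_chr_data(p, direction=direction, chromosome=f"chr{i + 1}")
            for i, p in enumerate(paths)
        ]
        return cls(mats, sup_min, epsilon, delta)

    @property
    def n_samples(self) -> int:
        return self.matrices[0].shape[1]

    def fit(self) -> "CNVPatternResults":
        """Run the level-wise search and return the mined patterns."""
        patterns: list[Pattern] = []
        for B in self.matrices:
            patterns.extend(mine_matrix(B, self.params))
        return CNVPatternResults(self, patterns)


class CNVPatternResults:
    """Mined maximal patterns plus post-estimation utilities."""

    def __init__(self, model: CNVPatternMiner, patterns: list[Pattern]) -> None:
        self.model = model
        self.patterns = patterns
        self.params = model.params

    def __len__(self) -> int:
        return len(self.patterns)

    # -- tabular views ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per pattern: location, size, support, supporting samples."""
        tracks = {
            c: B.track for B in self.model.matrices for c in B.track.chromosomes
        }
        rows = []
        for p in self.patterns:
            track = tracks.get(p.interval.chromosome)
            bp_start = bp_stop = None
            if track is not None and p.interval.end < len(track):
                _, bp_start, bp_stop = pattern_to_region(p, track)
            rows.append(
                {
                    "chromosome": p.interval.chromosome,
                    "direction": p.direction.value,
                    "start_probe": p.interval.start,
                    "end_probe": p.interval.end,
                    "size": p.size,
                    "bp_start": bp_start,
                    "bp_stop": bp_stop,
                    "support_count": p.n_support,
                    "support": p.support,
                    "samples": ",".join(map(str, p.support_set)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chromosome", "direction", "start_probe", "end_probe", "size",
                "bp_start", "bp_stop", "support_count", "support", "samples",
            ],
        )

    def summary(self) -> str:
        """Plain-text run summary: parameters, counts, and the patterns."""
        p = self.params
        n = self.model.n_samples
        m_total = sum(B.shape[0] for B in self.model.matrices)
        lines = [
            "CNV subspace pattern mining results",
            "=" * 51,
            f"samples: {n}    probes: {m_total}    matrices: {len(self.model.matrices)}",
            f"sup_min: {p.sup_min:g} (>= {p.min_count(n)} samples)    "
            f"epsilon: {p.epsilon:g}    delta: {p.delta:g}",
            f"patterns: {len(self.patterns)}   "
            f"of size >= 2: {sum(1 for q in self.patterns if q.size >= 2)}   "
            f"probes covered: {total_pattern_length(self.patterns)}",
            "-" * 51,
        ]
        frame = self.to_frame()
        if len(frame):
            lines.append(
                frame.drop(columns=["samples"]).to_string(index=False)
            )
        else:
            lines.append("(no pattern met the support threshold)")
        return "\n".join(lines)

    # -- post-estimation -------------------------------------------------

    def specificity(
        self,
        labels: Sequence[str] | Mapping[str, str] | GroupLabels,
        alpha: float | None = None,
        min_size: int = 1,
    ) -> list[SpecificityResult]:
        """Chi-squared group-specificity test for each pattern.

        ``labels`` follow sample column order (or map sample ID to group).
        With ``alpha`` given, only patterns with p < alpha are returned.
        """
        if not isinstance(labels, GroupLabels):
            labels = GroupLabels(labels, self.model.matrices[0].sample_ids)
        results = [
            specificity_test(p, labels)
            for p in self.patterns
            if p.size >= min_size
        ]
        if alpha is not None:
            return filter_specific(results, alpha)
        return results

    def density(self) -> float:
        """Fraction of cells covered by the patterns (per direction)."""
        m_total = sum(B.shape[0] for B in self.model.matrices)
        return pattern_density(self.patterns, m_total, self.model.n_samples)

    def total_length(self, min_size: int = 1) -> int:
        return total_pattern_length(self.patterns, min_size)

    def write(self, stream) -> None:
        _io.write_patterns(self.patterns, stream)

    def plot_matrix(self, matrix_index: int = 0, ax=None):
        """Heatmap of one binary matrix with mined intervals outlined."""
        import matplotlib.pyplot as plt
        from matplotlib import patches

        B = self.model.matrices[matrix_index]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.imshow(B.cells, aspect="auto", interpolation="nearest", cmap="Greys")
        chroms = set(B.track.chromosomes)
        for p in self.patterns:
            if p.interval.chromosome not in chroms:
                continue
            for t in p.support_set:
                ax.add_patch(
                    patches.Rectangle(
                        (t - 0.5, p.interval.start - 0.5), 1, p.size,
                        fill=False, edgecolor="tab:red", linewidth=0.8,
                    )
                )
        ax.set_xlabel("sample")
        ax.set_ylabel("probe (genomic order)")
        return ax
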