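"""Binarization of continuous log-intensity-ratio data.

A probe/sample cell is a candidate copy-number gain when its log ratio
exceeds +tau, and a candidate loss when it falls below -tau; values in
[-tau, tau] are treated as normal copy number.  Gains and losses are
binarized — and later mined — separately.  tau is either supplied directly
or chosen from the data so that a target fraction of cells (gains plus
losses pooled over the whole matrix) become candidate CNVs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    BinarizeParams,
    BinaryMatrix,
    Direction,
    IntensityMatrix,
    ValidationError,
)

__all__ = ["binarize", "select_tau", "binarize_both"]


def binarize(X: IntensityMatrix, p: BinarizeParams) -> BinaryMatrix:
    """Threshold an intensity matrix into a one-direction binary matrix.

    Strict inequality is used: cell = 1 iff value > tau (gain) or
    value < -tau (loss); ties at the threshold stay 0.  Dimensions, sample
    IDs and the probe track carry over unchanged.
    """
    if not isinstance(X, IntensityMatrix):
        raise ValidationError("binarize expects an IntensityMatrix")
    if p.direction is Direction.GAIN:
        cells = X.values > p.tau
    else:
        cells = X.values < -p.tau
    return BinaryMatrix(
        cells.astype(np.uint8),
        sample_ids=X.sample_ids,
        track=X.track,
        direction=p.direction,
    )


def binarize_both(X: IntensityMatrix, tau: float) -> tuple[BinaryMatrix, BinaryMatrix]:
    """Gain and loss matrices at a common symmetric threshold."""
    return (
        binarize(X, BinarizeParams(tau, Direction.GAIN)),
        binarize(X, BinarizeParams(tau, Direction.LOSS)),
    )


def select_tau(X: IntensityMatrix, target_density: float) -> float:
    """Choose tau so that a target fraction of cells become candidate CNVs.

    Returns the (1 - target_density) empirical quantile of |values| over the
    pooled matrix: the smallest threshold for which the fraction of cells
    with |value| > tau does not exceed ``target_density``.  Absent ties at
    the threshold, the combined density of the gain and loss matrices is
    within 1/(m*n) of the target; tie mass at tau can only lower it.
    """
    if not (0.0 < target_density < 1.0):
        raise ValidationError(f"target_density must be in (0, 1), got {target_density}")
    a = np.abs(X.values).ravel()
    N = a.size
    if np.ptp(a) == 0.0:
        warnings.warn(
            "degenerate intensity matrix (all |values| identical); "
            "returning that value, achieved density is 0",
            stacklevel=2,
        )
        return float(a[0])
    a_sorted = np.sort(a)[::-1]  # descending
    k = int(np.floor(target_density * N + 1e-12))  # cells allowed above tau
    tau = float(a_sorted[k]) if k < N else float(a_sorted[-1])
    return tau
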