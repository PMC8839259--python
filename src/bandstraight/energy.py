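"""Energy terms of the band-straightening objective.

The straightening field DY* minimises

    E(DY; I) = f(mean column correlation of the warped lane)      (external)
             + wx * sum|d(DY)/dx| + wy * sum|d(DY)/dy|            (internal)

subject to the per-row zero-mean constraint on DY.  The external term
rewards column profiles whose peaks and valleys coincide (straight
horizontal bands); the internal term is an elastic regulariser penalising
shear strain (x-derivative) and normal strain (y-derivative).  f is a
decreasing function with f(0) = 1 and f(1) = 0; here f(c) = (1 - c)^p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lane import DimensionError, LaneImage
from .warp import DeformationField, apply_deformation

#: Tolerance on the per-row mean shift for a field fed to total_energy.
ROW_ZERO_TOL = 1e-3


class ConstraintError(ValueError):
    """A deformation field violates the per-row zero-mean constraint."""


@dataclass(frozen=True)
class EnergyParams:
    """Weights and shape parameters of the energy.

    wx, wy : internal-energy weights per pixel of absolute derivative.
    p : exponent of the decreasing function f(c) = (1 - clamp(c, 0, 1))^p.
    min_overlap : minimum shared non-missing rows for a column pair's
        correlation to enter the external-energy average.
    """

    wx: float = 5e-2
    wy: float = 2.5e-2
    p: float = 1.0
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if self.wx < 0 or self.wy < 0:
            raise ValueError("energy weights must be non-negative")
        if self.p <= 0:
            raise ValueError("f exponent must be positive")

    def f(self, c: float) -> float:
        """The decreasing correlation-to-energy map; f(0)=1, f(1)=0."""
        return float((1.0 - np.clip(c, 0.0, 1.0)) ** self.p)

    def scaled(self, factor: float) -> "EnergyParams":
        return EnergyParams(self.wx * factor, self.wy * factor, self.p,
                            self.min_overlap)


def column_correlation_matrix(
    lane: LaneImage, min_overlap: int = 10
) -> np.ndarray:
    """Pairwise Pearson correlation of lane columns under pairwise masking.

    R[i, j] is computed over the rows where *both* columns i and j are
    non-missing, so masked artifacts cannot bias the correlations.  Pairs
    with fewer than ``min_overlap`` shared rows or zero variance, and the
    diagonal, are returned as NaN (invalid).
    """
    if lane.width < 2:
        raise DimensionError("need at least 2 columns for a correlation matrix")
    valid = (~lane.missing).astype(float)
    x = lane.intensity * valid

    n = valid.T @ valid
    sx = x.T @ valid
    sxx = (x * x).T @ valid
    sxy = x.T @ x

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_i = np.maximum(sxx - sx**2 / n, 0.0)
        denom = np.sqrt(var_i * var_i.T)
        r = cov / denom
    bad = (n < max(min_overlap, 2)) | (denom <= 1e-12)
    r[bad] = np.nan
    np.fill_diagonal(r, np.nan)
    return np.clip(r, -1.0, 1.0)


def mean_column_correlation(lane: LaneImage, params: EnergyParams) -> float:
    """Mean of valid off-diagonal correlations, negatives clamped to 0.

    Returns NaN when no column pair is valid.
    """
    r = column_correlation_matrix(lane, params.min_overlap)
    vals = r[np.isfinite(r)]
    if vals.size == 0:
        return float("nan")
    return float(np.clip(vals, 0.0, 1.0).mean())


def external_energy(lane: LaneImage, params: EnergyParams = EnergyParams()) -> float:
    """Image-driven energy f(mean column correlation), in [0, 1]."""
    c = mean_column_correlation(lane, params)
    if np.isnan(c):
        warnings.warn(
            "no valid column pair for the correlation energy; returning 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return params.f(c)


def internal_energy(
    field: DeformationField, params: EnergyParams = EnergyParams()
) -> float:
    """Elastic regulariser wx*sum|forward x-diffs| + wy*sum|forward y-diffs|."""
    dy = field.dy
    ex = np.abs(np.diff(dy, axis=1)).sum()
    ey = np.abs(np.diff(dy, axis=0)).sum()
    return float(params.wx * ex + params.wy * ey)


def total_energy(
    lane: LaneImage,
    field: DeformationField,
    params: EnergyParams = EnergyParams(),
) -> float:
    """External energy of the warped lane plus internal energy of the field.

    The field must satisfy the per-row zero-mean constraint within
    ``ROW_ZERO_TOL`` pixels.
    """
    if field.shape != lane.shape:
        raise DimensionError(
            f"field shape {field.shape} != lane shape {lane.shape}"
        )
    worst = np.abs(field.row_means()).max() if field.dy.size else 0.0
    if worst > ROW_ZERO_TOL:
        raise ConstraintError(
            f"per-row mean shift up to {worst:.2e} px violates the "
            f"zero-mean constraint (tol {ROW_ZERO_TOL})"
        )
    warped = apply_deformation(lane, field)
    return external_energy(warped, params) + internal_energy(field, params)
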