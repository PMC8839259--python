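"""Vertical deformation fields and their application to lane images.

A deformation field ``dy`` assigns every pixel (x, y) a vertical shift
DY(x, y) in pixels (positive = downward).  Warping follows the forward
model  I'(x, y + DY(x, y)) = I(x, y): content at source row y lands at
target row y + DY.  Because the shift is vertical only, each column is
resampled independently along y by linear interpolation of the inverse
map; the forward map y -> y + DY(x, y) is assumed monotone in y (smooth
fields with |dDY/dy| < 1, which both the optimizer and the simulator
produce).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lane import DimensionError, LaneImage


@dataclass
class DeformationField:
    """Per-pixel vertical shift DY(x, y), same shape as its lane."""

    dy: np.ndarray

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dy.ndim != 2:
            raise DimensionError(f"field must be 2-D, got shape {self.dy.shape}")
        if not np.all(np.isfinite(self.dy)):
            raise ValueError("deformation field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    def row_means(self) -> np.ndarray:
        return self.dy.mean(axis=1)

    def copy(self) -> "DeformationField":
        return DeformationField(self.dy.copy())

    def __neg__(self) -> "DeformationField":
        return DeformationField(-self.dy)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, dy=self.dy)

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        with np.load(path) as z:
            return cls(z["dy"])

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DeformationField":
        return cls(np.zeros(shape))

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of DY at real-valued (x, y) positions."""
        h, w = self.dy.shape
        x = np.clip(np.asarray(x, dtype=float), 0, w - 1)
        y = np.clip(np.asarray(y, dtype=float), 0, h - 1)
        x0 = np.clip(np.floor(x).astype(int), 0, w - 2) if w > 1 else np.zeros_like(x, int)
        y0 = np.clip(np.floor(y).astype(int), 0, h - 2) if h > 1 else np.zeros_like(y, int)
        fx = x - x0
        fy = y - y0
        d = self.dy
        return (
            d[y0, x0] * (1 - fy) * (1 - fx)
            + d[np.minimum(y0 + 1, h - 1), x0] * fy * (1 - fx)
            + d[y0, np.minimum(x0 + 1, w - 1)] * (1 - fy) * fx
            + d[np.minimum(y0 + 1, h - 1), np.minimum(x0 + 1, w - 1)] * fy * fx
        )


def warp_columns(
    intensity: np.ndarray, missing: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level columnwise warp of an intensity grid and its mask.

    Returns the warped intensity and mask.  Target rows with no source
    support (content shifted away from the lane ends) are missing, as are
    targets whose nearest source pixel is missing.
    """
    h, w = intensity.shape
    targets = np.arange(h, dtype=float)
    out = np.empty_like(intensity)
    out_miss = np.zeros((h, w), dtype=bool)
    miss_f = missing.astype(float)
    for x in range(w):
        src_pos = targets + dy[:, x]  # forward-mapped position of each source row
        out[:, x] = np.interp(targets, src_pos, intensity[:, x])
        m = np.interp(targets, src_pos, miss_f[:, x], left=1.0, right=1.0)
        out_miss[:, x] = m >= 0.5
        out_miss[targets < src_pos[0], x] = True
        out_miss[targets > src_pos[-1], x] = True
    out[out_miss] = 0.0
    return out, out_miss


def apply_deformation(lane: LaneImage, field: DeformationField) -> LaneImage:
    """Warp a lane by a vertical deformation field (forward model above)."""
    if field.shape != lane.shape:
        raise DimensionError(
            f"field shape {field.shape} != lane shape {lane.shape}"
        )
    out, miss = warp_columns(lane.intensity, lane.missing, field.dy)
    return LaneImage(out, miss)
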