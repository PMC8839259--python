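"""Rolling-ellipsoid background removal.

A morphological background estimator in the rolling-ball family: an
ellipsoid with radii (rx, ry, rz) — rx along the columns, ry along the
migration axis, rz along the intensity axis — is rolled underneath the 3-D
intensity surface of the lane, and the upper envelope it traces is taken as
the background.  ry is chosen much larger than any band width so the
ellipsoid cannot enter the valleys between horizontal bands (band peaks are
preserved); rx is small enough that smooth along-x irregularities are
followed and removed.

All processing happens in *signal polarity*: bands are peaks.  Scanned
membranes have dark bands on a light background, so raw grayscale lanes are
inverted (signal = 255 - gray) before rolling; synthetic lanes are already
generated in signal polarity.

Mathematically the background is the grayscale opening of the signal with
the non-flat ellipsoidal structuring function
``b(dx, dy) = rz * (sqrt(1 - (dx/rx)^2 - (dy/ry)^2) - 1)``.
For large radii the opening is computed on a min-shrunk image and
interpolated back up (see :func:`rolling_ellipsoid_background`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .lane import DimensionError, LaneImage

#: Signal ceiling of an 8-bit grayscale lane, used for polarity inversion.
WHITE_LEVEL = 255.0


@dataclass(frozen=True)
class EllipsoidParams:
    """Radii of the rolling ellipsoid.

    rx, ry are in pixels (columns, rows); rz is in intensity units.
    """

    rx: float = 15.0
    ry: float = 300.0
    rz: float = 40.0

    def __post_init__(self) -> None:
        if min(self.rx, self.ry, self.rz) <= 0:
            raise ValueError("ellipsoid radii must all be positive")


def _ellipsoid_structure(rx: float, ry: float, rz: float):
    """Footprint and height function of the ellipsoid structuring element."""
    hx, hy = int(np.floor(rx)), int(np.floor(ry))
    dx = np.arange(-hx, hx + 1)
    dy = np.arange(-hy, hy + 1)
    norm2 = (dy[:, None] / ry) ** 2 + (dx[None, :] / rx) ** 2
    footprint = norm2 <= 1.0
    height = np.zeros_like(norm2)
    height[footprint] = rz * (np.sqrt(1.0 - norm2[footprint]) - 1.0)
    return footprint, height


def _inpaint_nearest(intensity: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill missing pixels with their nearest valid neighbour's value."""
    if not missing.any():
        return intensity
    idx = ndimage.distance_transform_edt(
        missing, return_distances=False, return_indices=True
    )
    return intensity[tuple(idx)]


def _block_min(a: np.ndarray, sy: int, sx: int) -> np.ndarray:
    """Min-reduce over sy-by-sx blocks, edge-padding partial blocks."""
    h, w = a.shape
    pad_y = (-h) % sy
    pad_x = (-w) % sx
    a = np.pad(a, ((0, pad_y), (0, pad_x)), mode="edge")
    return a.reshape(a.shape[0] // sy, sy, a.shape[1] // sx, sx).min(axis=(1, 3))


def rolling_ellipsoid_background(
    lane: LaneImage,
    params: EllipsoidParams = EllipsoidParams(),
    max_halfwidth: int = 20,
) -> LaneImage:
    """Estimate the lane background by rolling an ellipsoid under the surface.

    The input must already be in signal polarity (bands = peaks).  The
    result satisfies ``background <= intensity`` everywhere non-missing.
    Missing pixels are excluded from support (filled by nearest-neighbour
    inpainting before rolling, so artifact holes do not dig spurious
    valleys) and flagged missing in the output.

    When a radius exceeds ``max_halfwidth`` samples, the image is first
    shrunk by a block-min filter, the ellipsoid is rolled at the coarse
    scale with proportionally reduced radii, and the coarse background is
    interpolated back to full resolution and clipped below the surface.
    With shrink factors of 1 the computation is the exact non-flat
    grayscale opening.
    """
    if lane.n_valid == 0:
        raise ValueError("cannot estimate a background on an all-missing lane")
    filled = _inpaint_nearest(lane.intensity, lane.missing)

    sy = max(1, int(np.ceil(params.ry / max_halfwidth)))
    sx = max(1, int(np.ceil(params.rx / max_halfwidth)))
    if sy == 1 and sx == 1:
        footprint, height = _ellipsoid_structure(params.rx, params.ry, params.rz)
        bg = ndimage.grey_opening(
            filled, footprint=footprint, structure=height, mode="nearest"
        )
    else:
        small = _block_min(filled, sy, sx)
        footprint, height = _ellipsoid_structure(
            max(params.rx / sx, 1.0), max(params.ry / sy, 1.0), params.rz
        )
        bg_small = ndimage.grey_opening(
            small, footprint=footprint, structure=height, mode="nearest"
        )
        # bilinear interpolation from block centres back to the full raster
        h, w = filled.shape
        yc = (np.arange(bg_small.shape[0]) + 0.5) * sy - 0.5
        xc = (np.arange(bg_small.shape[1]) + 0.5) * sx - 0.5
        tmp = np.empty((h, bg_small.shape[1]))
        ys = np.arange(h, dtype=float)
        for j in range(bg_small.shape[1]):
            tmp[:, j] = np.interp(ys, yc, bg_small[:, j])
        bg = np.empty((h, w))
        xs = np.arange(w, dtype=float)
        for i in range(h):
            bg[i] = np.interp(xs, xc, tmp[i])
        bg = np.minimum(bg, filled)
    return LaneImage(bg, lane.missing.copy())


def subtract_background(lane: LaneImage, background: LaneImage) -> LaneImage:
    """Remove the estimated background, leaving non-negative band signal."""
    if background.shape != lane.shape:
        raise DimensionError(
            f"background shape {background.shape} != lane shape {lane.shape}"
        )
    missing = lane.missing | background.missing
    signal = lane.intensity - background.intensity
    signal[~missing] = np.maximum(signal[~missing], 0.0)
    signal[missing] = 0.0
    return LaneImage(signal, missing)


class RollingEllipsoidBackground(TransformerMixin, BaseEstimator):
    """Stateless transformer: lane in, background-subtracted lane out.

    Parameters
    ----------
    rx, ry, rz : float
        Ellipsoid radii (see :class:`EllipsoidParams`).  Defaults rx=15 px,
        ry=300 px, rz=40 intensity units: ry is an order of magnitude above
        the widest band (~30 px FWHM) while rx matches the band-width scale.
    invert : bool
        If True (scanned membranes), convert to signal polarity first
        (signal = 255 - gray).  Synthetic lanes are already signal-polarity
        and should use ``invert=False``.
    max_halfwidth : int
        Largest structuring-element half-width computed exactly; larger
        radii trigger the shrink-and-interpolate approximation.
    """

    def __init__(
        self,
        rx: float = 15.0,
        ry: float = 300.0,
        rz: float = 40.0,
        invert: bool = True,
        max_halfwidth: int = 20,
    ):
        self.rx = rx
        self.ry = ry
        self.rz = rz
        self.invert = invert
        self.max_halfwidth = max_halfwidth

    def _params(self) -> EllipsoidParams:
        return EllipsoidParams(self.rx, self.ry, self.rz)

    def fit(self, X: LaneImage, y=None) -> "RollingEllipsoidBackground":
        """Validate parameters; the transform itself is stateless."""
        self._params()
        self.n_features_in_ = X.width if isinstance(X, LaneImage) else None
        return self

    def transform(self, X: LaneImage) -> LaneImage:
        lane = X
        if self.invert:
            lane = LaneImage(WHITE_LEVEL - lane.intensity, lane.missing.copy())
        bg = rolling_ellipsoid_background(lane, self._params(), self.max_halfwidth)
        return subtract_background(lane, bg)

    def background(self, X: LaneImage) -> LaneImage:
        """The estimated background itself (signal polarity), for inspection."""
        lane = X
        if self.invert:
            lane = LaneImage(WHITE_LEVEL - lane.intensity, lane.missing.copy())
        return rolling_ellipsoid_background(lane, self._params(), self.max_halfwidth)
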