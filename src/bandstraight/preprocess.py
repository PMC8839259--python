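"""Membrane-scan pre-processing: grayscale conversion, margin cropping and
lane rectification.

The upstream steps (lane-edge segmentation, artifact detection, ROI
detection) are external prerequisites; this module consumes their outputs
(a :class:`~bandstraight.lane.LaneGeometry` and an optional artifact mask)
and produces a rectified, ROI-limited :class:`~bandstraight.lane.LaneImage`
whose horizontal distortion has been removed, leaving only the vertical
band deformation for the straightening stage.
"""

from __future__ import annotations

import numpy as np

from .lane import DimensionError, LaneGeometry, LaneImage

#: RGB -> grayscale weights for scanned IEF membranes.
GRAY_WEIGHTS = (0.16, 0.52, 0.32)

#: Blank margins of a 600-dpi membrane scan, in pixel rows.
DEFAULT_CROP_TOP_PX = 505
DEFAULT_CROP_BOTTOM_PX = 100
REFERENCE_DPI = 600


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Convert a 24-bit RGB membrane scan to grayscale.

    Uses the linear combination 0.16*R + 0.52*G + 0.32*B (weights chosen for
    immunoblot membranes; they sum to 1, so the 0-255 range is preserved).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(
            f"expected an (H, W, 3) RGB image, got shape {image.shape}"
        )
    wr, wg, wb = GRAY_WEIGHTS
    return wr * image[..., 0] + wg * image[..., 1] + wb * image[..., 2]


def crop_margins(
    gray: np.ndarray,
    top_px: int | None = None,
    bottom_px: int | None = None,
    dpi: float = REFERENCE_DPI,
) -> np.ndarray:
    """Remove the blank sample-free margins at the top and bottom of a scan.

    Defaults remove 505 rows at the top and 100 at the bottom of a 600-dpi
    scan; for other resolutions the defaults scale linearly (rounded to the
    nearest row).  Explicit ``top_px``/``bottom_px`` are used as-is.
    """
    gray = np.asarray(gray)
    scale = dpi / REFERENCE_DPI
    if top_px is None:
        top_px = int(round(DEFAULT_CROP_TOP_PX * scale))
    if bottom_px is None:
        bottom_px = int(round(DEFAULT_CROP_BOTTOM_PX * scale))
    if top_px < 0 or bottom_px < 0:
        raise ValueError("crop sizes must be non-negative")
    n_rows = gray.shape[0]
    if top_px + bottom_px >= n_rows:
        raise DimensionError(
            f"crop of {top_px}+{bottom_px} rows exceeds image height {n_rows}"
        )
    return gray[top_px : n_rows - bottom_px]


def compute_wmax(geometry: LaneGeometry) -> int:
    """Maximum lane width over rows: w_max = max_y(xright(y) - xleft(y))."""
    return int(np.ceil(geometry.widths.max()))


def rectify_lane(gray: np.ndarray, geometry: LaneGeometry) -> LaneImage:
    """Map a segmented lane to a perfectly vertical strip of width w_max.

    Each row is translated horizontally so the midline between the lane
    edges, (xleft + xright)/2, lands on the output centre column.  Midline
    offsets are real-valued, so rows are resampled by linear interpolation;
    columns outside the lane extent for a row are flagged missing ("empty
    borders").  Rows outside [roi_top, roi_bottom] are dropped.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise DimensionError(f"expected a 2-D grayscale image, got {gray.shape}")
    if gray.shape[0] != geometry.n_rows:
        raise DimensionError(
            f"geometry has {geometry.n_rows} rows but image has {gray.shape[0]}"
        )
    top = geometry.roi_top
    bottom = min(geometry.roi_bottom, gray.shape[0] - 1)
    wmax = compute_wmax(geometry)
    centre = wmax / 2.0

    n_out = bottom - top + 1
    out = np.zeros((n_out, wmax))
    missing = np.ones((n_out, wmax), dtype=bool)
    x_out = np.arange(wmax, dtype=float)
    for i, y in enumerate(range(top, bottom + 1)):
        left = geometry.left_edge[y]
        right = geometry.right_edge[y]
        mid = 0.5 * (left + right)
        # source column for each output column; the midline maps to `centre`.
        # membership uses half-open pixel-centre intervals so a row always
        # keeps exactly xright - xleft valid pixels, whatever the sub-pixel
        # translation
        src = x_out + (mid - centre)
        inside = (
            (src >= left - 0.5)
            & (src < right - 0.5)
            & (src >= -0.5)
            & (src < gray.shape[1] - 0.5)
        )
        out[i, inside] = np.interp(src[inside], np.arange(gray.shape[1]), gray[y])
        missing[i, inside] = False
    return LaneImage(out, missing)


def apply_artifact_mask(lane: LaneImage, mask: np.ndarray) -> LaneImage:
    """Rule out artifact pixels by adding them to the missing mask.

    The union with the existing mask makes repeated application idempotent;
    intensities are untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != lane.shape:
        raise DimensionError(
            f"artifact mask shape {mask.shape} != lane shape {lane.shape}"
        )
    return LaneImage(lane.intensity.copy(), lane.missing | mask)
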