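"""Core containers for rectified gel-lane images and their metadata.

A *lane* is one vertical sample strip of an isoelectric-focusing (IEF)
membrane after rectification: a 2-D grayscale intensity grid together with a
boolean *missing* mask marking pixels that carry no data (empty borders left
by rectification, or artifacts masked upstream).  Missing values are always
carried out-of-band in the mask, never as a sentinel intensity.

Coordinate convention (used throughout the package): 0-based indices,
``y`` = row index increasing downward along the migration axis, ``x`` =
column index.  Vertical shifts are in pixels, positive = downward.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DimensionError(ValueError):
    """Shapes of related inputs do not agree."""


class ValidationError(ValueError):
    """An input violates a structural invariant."""


@dataclass
class LaneImage:
    """A rectified grayscale lane: intensity grid plus missing-value mask.

    Parameters
    ----------
    intensity : ndarray of float, shape (H, W)
        Grayscale values on a 0-255 scale (or non-negative "signal" units
        after background subtraction).  Must be finite wherever
        ``missing`` is False.
    missing : ndarray of bool, shape (H, W), optional
        True where the pixel carries no data.  Defaults to all-False.
    """

    intensity: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise DimensionError(
                f"lane intensity must be 2-D, got shape {self.intensity.shape}"
            )
        if self.missing is None:
            self.missing = np.zeros(self.intensity.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.intensity.shape:
            raise DimensionError(
                f"mask shape {self.missing.shape} != intensity shape "
                f"{self.intensity.shape}"
            )
        if not np.all(np.isfinite(self.intensity[~self.missing])):
            raise ValidationError("non-finite intensity outside the missing mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def height(self) -> int:
        return self.intensity.shape[0]

    @property
    def width(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_valid(self) -> int:
        return int((~self.missing).sum())

    def copy(self) -> "LaneImage":
        return LaneImage(self.intensity.copy(), self.missing.copy())

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the lane as a lossless ``.npz`` archive."""
        np.savez_compressed(path, intensity=self.intensity, missing=self.missing)

    @classmethod
    def load(cls, path: str | Path) -> "LaneImage":
        with np.load(path) as z:
            return cls(z["intensity"], z["missing"])

    def save_tiff(self, image_path: str | Path, mask_path: str | Path) -> None:
        """Write a float32 grayscale TIFF plus a uint8 mask TIFF."""
        import tifffile

        tifffile.imwrite(str(image_path), self.intensity.astype(np.float32))
        tifffile.imwrite(str(mask_path), self.missing.astype(np.uint8))

    @classmethod
    def load_tiff(
        cls, image_path: str | Path, mask_path: str | Path | None = None
    ) -> "LaneImage":
        import tifffile

        intensity = tifffile.imread(str(image_path)).astype(float)
        missing = None
        if mask_path is not None:
            missing = tifffile.imread(str(mask_path)).astype(bool)
        return cls(intensity, missing)


@dataclass
class LaneGeometry:
    """Per-row lane edges and region-of-interest bounds, produced upstream.

    ``left_edge``/``right_edge`` give the column coordinate of the lane's
    left/right border for every image row (real-valued: the upstream lane
    segmentation is a parametric active contour).  ``roi_top``/``roi_bottom``
    bound the IgG migration zone (inclusive row indices).
    """

    left_edge: np.ndarray
    right_edge: np.ndarray
    roi_top: int
    roi_bottom: int

    def __post_init__(self) -> None:
        self.left_edge = np.asarray(self.left_edge, dtype=float).ravel()
        self.right_edge = np.asarray(self.right_edge, dtype=float).ravel()
        if self.left_edge.shape != self.right_edge.shape:
            raise DimensionError("left and right edge arrays differ in length")
        if not np.all(self.left_edge < self.right_edge):
            raise ValidationError("left edge must be strictly left of right edge")
        self.roi_top = int(self.roi_top)
        self.roi_bottom = int(self.roi_bottom)
        if not 0 <= self.roi_top < self.roi_bottom:
            raise ValidationError("need 0 <= roi_top < roi_bottom")

    @property
    def n_rows(self) -> int:
        return self.left_edge.size

    @property
    def widths(self) -> np.ndarray:
        return self.right_edge - self.left_edge

    def save(self, path: str | Path) -> None:
        """Write as CSV: header comments hold the ROI, one edge pair per row."""
        with open(path, "w") as fh:
            fh.write(f"# roi_top={self.roi_top}\n# roi_bottom={self.roi_bottom}\n")
            pd.DataFrame(
                {"xleft": self.left_edge, "xright": self.right_edge}
            ).to_csv(fh, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "LaneGeometry":
        meta: dict[str, int] = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = int(val)
                else:
                    body.append(line)
        try:
            df = pd.read_csv(_io.StringIO("".join(body)))
            return cls(
                df["xleft"].to_numpy(),
                df["xright"].to_numpy(),
                meta["roi_top"],
                meta["roi_bottom"],
            )
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"malformed geometry file {path}: {exc}") from exc


@dataclass
class BandAnnotation:
    """A band midline traced as control points, linearly interpolated.

    ``x`` must be strictly increasing; the midline ``y(x)`` is defined over
    the extent ``[x[0], x[-1]]`` by linear interpolation between control
    points, as in expert band tracing.
    """

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise DimensionError("annotation x and y differ in length")
        if self.x.size < 2:
            raise ValidationError("an annotation needs at least 2 control points")
        if not np.all(np.diff(self.x) > 0):
            raise ValidationError("annotation x coordinates must strictly increase")

    @property
    def extent(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def columns(self) -> np.ndarray:
        """Integer columns covered by the extent."""
        lo, hi = self.extent
        return np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)

    def midline(self, xs: np.ndarray | None = None) -> np.ndarray:
        """Interpolated midline y(x); endpoints extended as constants."""
        if xs is None:
            xs = self.columns()
        return np.interp(np.asarray(xs, dtype=float), self.x, self.y)

    @property
    def mean_height(self) -> float:
        return float(self.midline().mean())


def save_annotations(bands: list[BandAnnotation], path: str | Path) -> None:
    """Write band annotations as JSON (one control-point list per band)."""
    payload = [
        {"label": b.label, "x": b.x.tolist(), "y": b.y.tolist()} for b in bands
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_annotations(path: str | Path) -> list[BandAnnotation]:
    try:
        payload = json.loads(Path(path).read_text())
        return [
            BandAnnotation(np.asarray(b["x"]), np.asarray(b["y"]), b.get("label", ""))
            for b in payload
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValidationError(f"malformed annotation file {path}: {exc}") from exc
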