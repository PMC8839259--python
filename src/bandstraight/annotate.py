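"""Annotation-driven straightening (the tracing-assistant warp).

Given expert-traced band midlines, build the vertical deformation that
maps every traced line to the horizontal line at its own mean height.
Between consecutive traced lines the shift is linearly interpolated in y;
above the top line and below the bottom line it is held constant.  By
construction every annotated band has zero standard deviation after the
warp, which makes this the reference straightening for evaluation and the
live feedback shown while tracing.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .lane import BandAnnotation, LaneImage, ValidationError
from .warp import DeformationField, apply_deformation


def annotation_field(
    bands: list[BandAnnotation], shape: tuple[int, int]
) -> DeformationField:
    """Deformation field mapping each traced midline to its mean height."""
    if not bands:
        raise ValidationError("need at least one band annotation")
    h, w = shape
    bands = sorted(bands, key=lambda b: b.mean_height)
    xs = np.arange(w, dtype=float)
    midlines = np.stack([b.midline(xs) for b in bands])  # (n_bands, W)
    if np.any(np.diff(midlines, axis=0) <= 0):
        raise ValidationError("band annotations cross (midlines must not touch)")
    targets = midlines.mean(axis=1)  # mean height of each band
    shifts = targets[:, None] - midlines  # shift at the midline itself

    dy = np.empty((h, w))
    ys = np.arange(h, dtype=float)
    for x in range(w):
        # piecewise-linear in y through the traced lines, constant beyond
        dy[:, x] = np.interp(ys, midlines[:, x], shifts[:, x])
        # the continuous map has a kink at each midline, which plain
        # integer-row sampling would smear; adjust the row just below each
        # midline so linear interpolation between the bracketing rows
        # reproduces the midline's shift exactly (bands more than 1 px
        # apart never share a bracketing cell, so corrections don't clash)
        for yb, sb in zip(midlines[:, x], shifts[:, x]):
            y0 = int(np.floor(yb))
            t = yb - y0
            if t < 1e-12:
                if 0 <= y0 < h:
                    dy[y0, x] = sb
            elif 0 <= y0 and y0 + 1 < h:
                dy[y0 + 1, x] = (sb - (1.0 - t) * dy[y0, x]) / t
    return DeformationField(dy)


def straighten_from_annotations(
    lane: LaneImage, bands: list[BandAnnotation]
) -> tuple[LaneImage, DeformationField]:
    """Warp a lane so every annotated band becomes exactly horizontal."""
    field = annotation_field(bands, lane.shape)
    return apply_deformation(lane, field), field


class AnnotationWarper(TransformerMixin, BaseEstimator):
    """Transformer wrapping the tracing-assistant warp.

    ``fit(X, y)`` takes the lane and its band annotations (``y`` is the
    list of :class:`~bandstraight.lane.BandAnnotation`) and stores the
    deformation field; ``transform`` applies it.
    """

    def fit(self, X: LaneImage, y: list[BandAnnotation] | None = None
            ) -> "AnnotationWarper":
        if not y:
            raise ValidationError("AnnotationWarper.fit needs band annotations")
        self.deformation_field_ = annotation_field(y, X.shape)
        return self

    def transform(self, X: LaneImage) -> LaneImage:
        check_is_fitted(self, "deformation_field_")
        return apply_deformation(X, self.deformation_field_)
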