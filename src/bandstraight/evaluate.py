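"""Quantitative evaluation of band straightening.

Band deformation is measured as the standard deviation (population, over
the integer columns of the band's extent) of the traced midline: a
horizontal band has SD 0.  Straightening quality is summarised by the
counts of bands whose SD exceeds thresholds t = 2, 3, 4, 5 px before and
after straightening, and by the ratios rho_t = num_before(t)/num_after(t).
Bands that were already essentially straight (SD <= 1 px before) are
excluded from the comparison — a 1-px deformation is both below tracing
variability and harmless to peak detection.

For band-free lanes the metric is the *introduced* deformation: the mean
over image rows of the per-row SD of the applied shift field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .lane import BandAnnotation, ValidationError
from .warp import DeformationField

DEFAULT_THRESHOLDS = (2.0, 3.0, 4.0, 5.0)

#: Bands straighter than this before straightening are left out of the
#: before/after comparison.
EXCLUDE_SD_BELOW = 1.0


def band_sd(band: BandAnnotation, field: DeformationField | None = None) -> float:
    """Population SD of a band midline, optionally after applying a field.

    With a field, the straightened midline is y(x) + DY(x, y(x)), the shift
    sampled by bilinear interpolation at the midline.
    """
    xs = band.columns()
    if xs.size < 2:
        raise ValidationError("band SD undefined on fewer than 2 columns")
    y = band.midline(xs)
    if field is not None:
        y = y + field.sample(xs.astype(float), y)
    return float(np.std(y))


def threshold_counts(
    sds, thresholds=DEFAULT_THRESHOLDS
) -> dict[float, int]:
    """Number of bands with SD strictly greater than each threshold."""
    sds = np.asarray(list(sds), dtype=float)
    return {float(t): int((sds > t).sum()) for t in thresholds}


def rho(num_before: int, num_after: int) -> float | None:
    """Deformed-band reduction ratio num_before / num_after.

    Returns +inf when every deformed band was straightened
    (num_after = 0, num_before > 0) and None (absent) for 0/0.
    """
    if num_before < 0 or num_after < 0:
        raise ValueError("counts must be non-negative")
    if num_after == 0:
        return float("inf") if num_before > 0 else None
    return num_before / num_after


def introduced_deformation(field: DeformationField) -> float:
    """Mean over rows of the per-row SD of the shift — the unnecessary
    deformation a straightener adds to a band-free lane."""
    return float(np.std(field.dy, axis=1).mean())


@dataclass
class EvaluationReport:
    """Per-band SDs plus the threshold/ratio summary.

    ``table`` has one row per band: sd_before, sd_after and whether the
    band enters the comparison.  ``rho`` maps threshold -> ratio (may be
    +inf, or None when 0/0).
    """

    table: pd.DataFrame
    num_before: dict[float, int]
    num_after: dict[float, int]
    rho: dict[float, float | None]
    mean_introduced_sd: float | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "threshold_px": t,
                "num_before": self.num_before[t],
                "num_after": self.num_after[t],
                "rho": self.rho[t],
            }
            for t in self.thresholds
        ]
        return pd.DataFrame(rows)

    def save(self, band_path: str | Path, summary_path: str | Path) -> None:
        self.table.to_csv(band_path, index=False)
        self.summary().to_csv(summary_path, index=False)


def build_report(
    sd_before,
    sd_after,
    labels=None,
    thresholds=DEFAULT_THRESHOLDS,
    exclude_below: float = EXCLUDE_SD_BELOW,
    mean_introduced_sd: float | None = None,
) -> EvaluationReport:
    """Assemble the evaluation report from paired per-band SDs.

    The exclusion rule uses sd_before only: pre-existing deformation below
    ``exclude_below`` px makes the comparison meaningless for that band.
    """
    sd_before = np.asarray(list(sd_before), dtype=float)
    sd_after = np.asarray(list(sd_after), dtype=float)
    if sd_before.shape != sd_after.shape:
        raise ValidationError("sd_before and sd_after differ in length")
    included = sd_before > exclude_below
    table = pd.DataFrame(
        {
            "band": labels if labels is not None else np.arange(sd_before.size),
            "sd_before": sd_before,
            "sd_after": sd_after,
            "included": included,
        }
    )
    thresholds = tuple(float(t) for t in thresholds)
    nb = threshold_counts(sd_before[included], thresholds)
    na = threshold_counts(sd_after[included], thresholds)
    rhos = {t: rho(nb[t], na[t]) for t in thresholds}
    return EvaluationReport(table, nb, na, rhos, mean_introduced_sd, thresholds)


def evaluate_straightening(
    bands: list[BandAnnotation],
    field: DeformationField,
    thresholds=DEFAULT_THRESHOLDS,
) -> EvaluationReport:
    """Report for one lane: SDs of its annotated bands before/after a field."""
    before = [band_sd(b) for b in bands]
    after = [band_sd(b, field) for b in bands]
    labels = [b.label or i for i, b in enumerate(bands)]
    return build_report(before, after, labels, thresholds)
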