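"""Synthetic IEF lane generator with ground-truth bands and deformations.

Lanes are generated in signal polarity (bands are peaks) at a raster
comparable to a real 600-dpi lane ROI.  Each lane is composed of:

* a smooth low-frequency background — a 1-D vertical profile built from a
  few broad Gaussians, replicated across columns and Gaussian-filtered (a
  procedural stand-in for real negative, band-free profiles; a hook
  accepts real profiles when available);
* 1-12 horizontal Gaussian-profile bands, count ~ DiscreteUniform{1..12},
  position uniform over the lane height, FWHM = 7 px + Exponential(mean
  7 px) (so min FWHM 7 px, mean 14 px), amplitude ~ LogUniform[8, 80]
  intensity units to cover faint-to-strong bands;
* a smooth random vertical deformation (per-pixel uniform noise smoothed
  by a large 2-D Gaussian kernel, rescaled to a requested peak shift);
* degradation: randomly placed missing-value disks emulating masked
  artifacts, and multiplicative speckle noise.

Ground truth travels with each lane: the applied field and the deformed
band midlines, ready for the SD-based evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .lane import BandAnnotation, LaneImage
from .warp import DeformationField, apply_deformation

# band-profile law
FWHM_MIN_PX = 7.0
FWHM_EXP_MEAN_PX = 7.0
BAND_COUNT_MIN, BAND_COUNT_MAX = 1, 12
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# unstated defaults, fixed once (see docs/methods.md)
DEFAULT_HEIGHT = 500
DEFAULT_WIDTH = 150
AMPLITUDE_RANGE = (8.0, 80.0)          # LogUniform, intensity units
DEFORM_AMPLITUDE_RANGE = (10.0, 40.0)  # Uniform, px (peak |shift| of the field)
DEFORM_SIGMA_RANGE = (30.0, 80.0)      # Uniform, px
ARTIFACT_MEAN = 3.0                    # Poisson mean disk count
ARTIFACT_RADIUS_RANGE = (2.0, 10.0)    # Uniform, px
SPECKLE_VAR = 0.01


@dataclass(frozen=True)
class SyntheticBand:
    """A horizontal Gaussian band: centre row, FWHM and peak amplitude."""

    position: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm < FWHM_MIN_PX:
            raise ValueError(f"band FWHM {self.fwhm} below the {FWHM_MIN_PX} px floor")
        if self.amplitude <= 0:
            raise ValueError("band amplitude must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA


@dataclass
class SyntheticLane:
    """A generated lane bundled with its ground truth."""

    lane: LaneImage                  # degraded, deformed lane (signal polarity)
    clean: LaneImage                 # pre-deformation, pre-degradation lane
    bands: list[SyntheticBand]
    truth_field: DeformationField    # the applied deformation
    truth_annotations: list[BandAnnotation]  # post-deformation midlines
    seed: int | None = None


def sample_bands(
    height: int,
    rng: np.random.Generator,
    n_bands: int | None = None,
    amplitude_range: tuple[float, float] = AMPLITUDE_RANGE,
) -> list[SyntheticBand]:
    """Draw a lane's band population from the generator's law."""
    if height <= 0:
        raise ValueError("lane height must be positive")
    if n_bands is None:
        n_bands = int(rng.integers(BAND_COUNT_MIN, BAND_COUNT_MAX + 1))
    lo, hi = amplitude_range
    bands = []
    for _ in range(n_bands):
        position = float(rng.uniform(0, height))
        fwhm = FWHM_MIN_PX + float(rng.exponential(FWHM_EXP_MEAN_PX))
        amplitude = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        bands.append(SyntheticBand(position, fwhm, amplitude))
    return bands


def _procedural_background(
    height: int, rng: np.random.Generator, smooth_sigma: float = 10.0
) -> np.ndarray:
    """Smooth 1-D vertical background profile: a few broad Gaussians."""
    n = int(rng.integers(3, 7))
    ys = np.arange(height, dtype=float)
    profile = np.zeros(height)
    for _ in range(n):
        amp = rng.uniform(5.0, 25.0)
        centre = rng.uniform(0, height)
        sigma = rng.uniform(height / 10.0, height / 3.0)
        profile += amp * np.exp(-((ys - centre) ** 2) / (2 * sigma**2))
    return gaussian_filter(profile, smooth_sigma, mode="nearest")


def render_lane(
    height: int,
    width: int,
    bands: list[SyntheticBand],
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> LaneImage:
    """Compose background and Gaussian band profiles into a clean lane.

    ``background`` may be a real negative (band-free) 1-D profile of length
    ``height``; by default a procedural profile is drawn from ``rng``.
    Band intensity is constant across columns (bands are horizontal before
    deformation).
    """
    if background is None:
        background = _procedural_background(height, rng)
    background = np.asarray(background, dtype=float)
    ys = np.arange(height, dtype=float)
    profile = background.copy()
    for b in bands:
        profile += b.amplitude * np.exp(
            -((ys - b.position) ** 2) / (2.0 * b.sigma**2)
        )
    return LaneImage(np.repeat(profile[:, None], width, axis=1))


def sample_deformation(
    height: int,
    width: int,
    amplitude_px: float,
    smoothing_sigma: float,
    rng: np.random.Generator,
) -> DeformationField:
    """Smooth random vertical shift field with peak magnitude amplitude_px.

    Independent per-pixel uniform shifts are smoothed by a large 2-D
    Gaussian kernel (emulating smooth non-uniform lane deformations) and
    rescaled so max |DY| equals the requested amplitude.
    """
    if amplitude_px < 0:
        raise ValueError("deformation amplitude must be >= 0")
    raw = rng.uniform(-1.0, 1.0, size=(height, width))
    if amplitude_px == 0:
        return DeformationField(np.zeros((height, width)))
    smooth = gaussian_filter(raw, smoothing_sigma, mode="nearest")
    peak = np.abs(smooth).max()
    if peak <= 0:
        return DeformationField(np.zeros((height, width)))
    return DeformationField(smooth * (amplitude_px / peak))


def degrade(
    lane: LaneImage,
    rng: np.random.Generator,
    artifact_count: int | None = None,
    radius_range: tuple[float, float] = ARTIFACT_RADIUS_RANGE,
    speckle_var: float = SPECKLE_VAR,
) -> LaneImage:
    """Add missing-value disks (masked artifacts) and speckle noise.

    Speckle is multiplicative with unit mean and variance ``speckle_var``,
    applied to non-missing pixels only.  ``artifact_count`` defaults to a
    Poisson draw with mean 3.
    """
    h, w = lane.shape
    intensity = lane.intensity.copy()
    missing = lane.missing.copy()
    if artifact_count is None:
        artifact_count = int(rng.poisson(ARTIFACT_MEAN))
    ys, xs = np.mgrid[0:h, 0:w]
    for _ in range(artifact_count):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        radius = rng.uniform(*radius_range)
        missing |= (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2
    if speckle_var > 0:
        noise = 1.0 + rng.normal(0.0, np.sqrt(speckle_var), size=(h, w))
        keep = ~missing
        intensity[keep] = intensity[keep] * noise[keep]
    intensity[missing] = 0.0
    return LaneImage(intensity, missing)


def generate(
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    height: int = DEFAULT_HEIGHT,
    width: int = DEFAULT_WIDTH,
    n_bands: int | None = None,
    deform_amplitude: float | None = None,
    smoothing_sigma: float | None = None,
    artifact_count: int | None = None,
    speckle_var: float = SPECKLE_VAR,
    background: np.ndarray | None = None,
) -> SyntheticLane:
    """Generate one synthetic lane with full ground truth.

    With only ``seed`` given, every unstated quantity is drawn from the
    generator's default laws: deformation amplitude ~ Uniform[2, 10] px,
    smoothing sigma ~ Uniform[30, 80] px, Poisson(3) artifact disks.
    ``n_bands=0`` produces a band-free lane for the introduced-deformation
    protocol.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bands = sample_bands(height, rng, n_bands=n_bands)
    clean = render_lane(height, width, bands, rng, background=background)
    if deform_amplitude is None:
        deform_amplitude = float(rng.uniform(*DEFORM_AMPLITUDE_RANGE))
    if smoothing_sigma is None:
        smoothing_sigma = float(rng.uniform(*DEFORM_SIGMA_RANGE))
    field = sample_deformation(height, width, deform_amplitude, smoothing_sigma, rng)
    deformed = apply_deformation(clean, field)
    degraded = degrade(
        deformed, rng, artifact_count=artifact_count, speckle_var=speckle_var
    )
    xs = np.arange(width, dtype=float)
    annotations = [
        BandAnnotation(
            xs,
            b.position + field.sample(xs, np.full(width, b.position)),
            label=f"band{i}",
        )
        for i, b in enumerate(bands)
    ]
    return SyntheticLane(degraded, clean, bands, field, annotations, seed)
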