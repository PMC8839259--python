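# Methods

This note documents the models, numerical choices and limitations behind
`bandstraight`.  It is written for a maintainer or reviewer who needs to
know *why* the code does what it does; user-facing usage lives in the
README.

## Problem setting

An IEF lane, after upstream segmentation and rectification, is a grayscale
raster I(x, y) with a boolean missing-value mask (empty borders from
rectification, artifact regions masked upstream).  Horizontal protein
bands are bent by a smooth vertical deformation that may be uniform (same
shift in every column) or non-uniform (shift varying with height).
Straightening estimates a per-pixel vertical shift field ΔY(x, y)
(positive = downward) and warps the lane by the forward model
I′(x, y + ΔY(x, y)) = I(x, y).

All processing after background removal happens in *signal polarity*:
bands are peaks.  Scanned membranes (dark bands on light background) are
inverted as signal = 255 − gray; the synthetic generator emits signal
polarity directly.

## Energy model

The estimated field minimises an external plus internal energy under a
per-row zero-mean constraint:

* **External energy** f(R̄), where R̄ is the mean of the valid off-diagonal
  pairwise Pearson correlations between the warped lane's columns.  Each
  pair is correlated only over rows where both columns are non-missing;
  pairs with fewer than `min_overlap` shared rows (default 10) or zero
  variance are excluded.  Negative correlations are clamped to zero before
  averaging — anti-correlated noise should not reward deformation.  The
  decreasing map is f(c) = (1 − c)^p with p = 1 by default, so f(0) = 1 and
  f(1) = 0.  Averaging (rather than summing) the correlations keeps f's
  domain at [0, 1] regardless of lane width.
* **Internal energy** wx·Σ|∂ΔY/∂x| + wy·Σ|∂ΔY/∂y| with forward
  differences: an L1 elastic regulariser on shear strain and normal
  strain.  Defaults wx = 0.05, wy = 0.025 per pixel of absolute
  derivative; inside the optimiser the weights are divided by the working
  raster's pixel count so the balance against the (size-independent)
  external term does not depend on image size.  The weights were calibrated
  on a dedicated training set of synthetic lanes (generator seeds disjoint
  from the evaluation seeds): band-free lanes keep a high column
  correlation through their shared background residual, so weights below
  ~0.01 let the optimiser harvest noise-level correlation gains and bend
  band-free lanes by several pixels, while weights above ~0.2 start to
  leave strongly bent bands under-corrected.  The chosen values hold the
  introduced deformation on band-free lanes near 1 px without measurable
  loss of recovery.  Both weights are exposed in the configuration.
* **Constraint**: the mean shift of every pixel row is zero.  This stops
  the optimiser from compressing band-free regions (low correlation) and
  dilating band-rich ones.

## Deformation grids and the balanced move

The field is built from moves on rectangular node grids (rg × cg, nodes on
all four borders, bilinear interpolation between nodes).  A move displaces
one node vertically by ±δ; the other nodes of the same grid row absorb the
displacement so the *interpolated field* keeps a zero mean in every pixel
row.  Because border node columns carry roughly half the interpolation
footprint of interior ones, the absorption is weighted by each node
column's sampled-hat weight u_i (the mean of its hat function over integer
pixel columns) rather than split equally: the partners move by
−s·δ·u_k / Σ_{i≠k} u_i, followed by removal of the ~10⁻¹⁶ floating-point
residue.  With two node columns this reduces to the familiar symmetric
(+δ, −δ) move.  The constraint then holds to machine precision for every
candidate field the optimiser ever evaluates (asserted in tests at
1e-6 px).

## Hierarchy and optimiser

Optimisation runs in four steps with (row, column) downsampling factors
(8,8), (4,8), (2,8), (1,4) — columns stay coarser because the column
correlation dominates the cost — and node shifts δ = 8, 4, 2, 1 px (full
resolution; divided by the row factor at the working scale).  Grid sizes
per step default to ⟨2,3⟩⟨3,3⟩ / ⟨3,5⟩⟨4,5⟩ / ⟨5,7⟩⟨6,9⟩ / ⟨8,9⟩⟨10,11⟩,
coarse to fine.  Downsampling is a block mean that ignores missing pixels
(a fully missing block stays missing).

For each grid, nodes are visited in a seeded random permutation; each
visit tries s = −1 then +1.  A candidate is accepted only if it strictly
lowers the energy at the working resolution; on acceptance the node's
in-grid 4-neighbours are appended to the queue (no de-duplication) and
half- and one-and-a-half-size variants of the shift are evaluated from the
same base state, keeping the lowest-energy of the three (ties to the
smaller shift).  A grid terminates after a full pass with no acceptance;
`max_passes` (default 100) is a safety valve only.  One seeded generator
drives all permutations, making results bit-reproducible.

Numerical details:

* The running field is kept at the working raster in full-resolution shift
  units; transfers between rasters use endpoint-aligned bilinear
  resampling followed by row re-centring (which restores the constraint
  exactly after interpolation drift).
* Warping resamples each column by linear interpolation of the inverse
  map, assuming the forward map y ↦ y + ΔY is monotone (|∂ΔY/∂y| < 1,
  true for all fields the optimiser and the simulator produce).  Warped
  pixels with no source support, or whose nearest source is missing, are
  missing.
* Energies at different steps are computed at different resolutions and
  are therefore compared only within a step; the accepted-move energy
  sequence is strictly decreasing within each step.
* After the final step the field is upsampled to full resolution and
  re-centred.  If (rarely, e.g. for an already-straight lane) the
  full-resolution energy of the result exceeds that of the zero field,
  the zero field is returned instead — doing nothing is always an
  admissible solution.

## Rolling-ellipsoid background

The background is the grayscale opening of the signal-polarity lane with
the non-flat ellipsoidal structuring function
b(dx, dy) = rz·(√(1 − (dx/rx)² − (dy/ry)²) − 1): the envelope an ellipsoid
traces when rolled under the intensity surface.  Defaults rx = 15 px,
ry = 300 px, rz = 40 intensity units: ry is an order of magnitude above
the widest band (~30 px FWHM) so the ellipsoid cannot enter the valleys
between bands (band peaks survive), while rx matches the scale of along-x
background irregularities so they are followed and removed.

Missing pixels are filled by nearest-neighbour inpainting before rolling
(an artifact hole must not dig a spurious valley) and re-masked after.
When a radius exceeds `max_halfwidth` (default 20) samples, the lane is
shrunk with a block-min filter, the ellipsoid rolled at coarse scale with
proportionally reduced radii, and the coarse background interpolated back
and clipped below the surface — the standard large-radius rolling-ball
economisation.  With shrink factors of 1 the computation is the exact
opening, and the brute-force equivalence tests run in that regime.

## Annotation-driven warp

Expert band annotations are polylines y_b(x), linearly interpolated
between control points.  The tracing-assistant warp maps every traced
midline to the horizontal line at its own mean height; between consecutive
midlines the shift is linearly interpolated in y, and held constant above
the top and below the bottom line.  Because the continuous shift map has a
kink at each midline, sampling it only at integer rows would smear the
kink under bilinear evaluation; the row just below each midline is
adjusted so that bilinear sampling at the midline reproduces its shift
exactly.  Annotated bands therefore have *exactly* zero SD after the warp
(to ~1e-12), provided midlines stay on the raster and are more than 1 px
apart (closer pairs would share a bracketing row; the later adjustment
then wins and exactness degrades gracefully).

## Synthetic lane generator

The generator is the package's study-condition definition, not a test
dial; its defaults are fixed once:

* **Raster** 500 × 150 px, chosen to match a real 600-dpi lane ROI (ten
  ~190-px lanes across a 1905-px membrane; the IgG migration zone spans a
  few hundred rows).
* **Background**: a smooth 1-D vertical profile — 3–6 broad Gaussians,
  amplitudes 5–25 units, widths height/10 – height/3, Gaussian-filtered —
  replicated across columns.  This is a procedural stand-in for real
  negative (band-free) profiles, which cannot be shipped; `render_lane`
  accepts a real profile through its `background` hook.
* **Bands**: count ~ DiscreteUniform{1..12}; position uniform over the
  height; FWHM = 7 px + Exponential(mean 7 px) so the minimum is 7 px and
  the mean 14 px; Gaussian profile with σ = FWHM/(2√(2 ln 2)); amplitude
  ~ LogUniform[8, 80] intensity units, covering faint tear-sample bands
  through strong CSF bands.
* **Deformation**: per-pixel Uniform(−1, 1) noise smoothed by an isotropic
  2-D Gaussian kernel (σ ~ Uniform[30, 80] px), rescaled so the *peak*
  |shift| equals the amplitude, drawn ~ Uniform[10, 40] px.  Under the
  peak normalisation a typical row's spread is only a few percent of the
  peak, so this amplitude range is what places the resulting band midline
  SDs across the 2–5 px evaluation thresholds (median ≈ 1.2 px, ~7% of
  bands above 5 px — comparable to the share of strongly deformed bands in
  real annotated datasets).
* **Degradation**: Poisson(3) missing-value disks with radius
  Uniform[2, 10] px, then multiplicative speckle noise with unit mean and
  variance 0.01 on non-missing pixels.

Ground truth accompanies every lane: the applied field and the deformed
band midlines y_b(x) = position_b + ΔY(x, position_b).

What the generator does *not* emulate: band-intensity variation along x,
curved lane edges (rectification is tested separately on constructed
geometries), spatially correlated scanner noise, band-lookalike ambiguous
artifacts, and chemistry-specific background textures.  Passing the
synthetic suite therefore demonstrates correct recovery of smooth vertical
deformations under masked artifacts and speckle — not robustness to every
failure mode of real membranes.

## Evaluation protocol

Band deformation is the population SD (divide by n; a midline is a fully
observed curve, not a sample) of the midline height over the integer
columns of its extent; after straightening the midline is
y(x) + ΔY(x, y(x)) with ΔY sampled bilinearly.  Bands with SD ≤ 1 px
before straightening are excluded from before/after comparisons (such
deformation is below tracing variability and harmless to peak detection);
the exclusion uses sd_before only.  Quality is summarised by counts of
bands with SD > t for t = 2, 3, 4, 5 px and ratios
ρt = num_before(t)/num_after(t) (∞ when everything above t was
straightened; absent for 0/0).  For band-free lanes the *introduced*
deformation is the mean over rows of the per-row SD of the field.

The default protocol sizes — 100 band lanes plus 20 band-free lanes, with
the generator and optimiser seeded per lane — keep the full suite fast
while giving ~650 annotated bands, enough for stable threshold counts.

## Known limitations

* The greedy accept/reject search is a local optimiser; the 0.5×/1.5×
  refinement can overshoot into a nearby local minimum on contrived tiny
  instances (the exhaustive-enumeration test bounds this gap by the
  refinement resolution).
* Deformations sharper than the coarsest grid spacing, or confined to a
  single band edge without support in neighbouring structure, are not
  corrected — by design, since such shapes violate the smoothness prior.
* The column-correlation energy needs at least two columns sharing
  `min_overlap` valid rows; lanes that are almost entirely masked fall
  back to the zero field.
* The shrink-path background is approximate near band flanks (exact
  within the block-min/interpolation error); the exact path is available
  by raising `max_halfwidth` at quadratic cost in the radii.
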