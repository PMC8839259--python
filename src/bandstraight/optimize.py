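"""Greedy hierarchical energy-minimising band straightening.

The optimiser walks the hierarchy schedule: at each step it downsamples the
(background-subtracted) lane, transfers the running deformation field to
the working raster, and for every enabled grid size visits the grid nodes
in a seeded random permutation.  Each visit tries shifting the node down
then up by the step's magnitude; a move is kept only if it strictly lowers
the total energy at the working resolution.  On acceptance the node's
4-neighbours are appended to the visit queue and half- and
one-and-a-half-size variants of the accepted shift are tested, keeping the
best of the three (ties resolved toward the smaller shift).  A grid is
abandoned after a full pass with no accepted move.

Every candidate field satisfies the per-row zero-mean constraint exactly:
moves are balanced within their grid row (see :mod:`bandstraight.grid`)
and cross-resolution transfers are re-centred row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .energy import EnergyParams, external_energy, total_energy
from .grid import DeformationGrid, balanced_row_delta, hat_matrix
from .hierarchy import HierarchySchedule, downsample_lane
from .lane import DimensionError, LaneImage
from .warp import DeformationField, apply_deformation, warp_columns


@dataclass
class StepTrace:
    """Energy bookkeeping for one hierarchical step (one fixed resolution)."""

    fr: int
    fc: int
    initial_energy: float
    accepted_energies: list[float] = dc_field(default_factory=list)


@dataclass
class OptimizeResult:
    field: DeformationField
    straightened: LaneImage
    traces: list[StepTrace]
    n_evaluations: int
    n_accepted: int
    fell_back_to_zero: bool


def _resample_raster(f: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of a field raster onto a new raster, endpoint-
    aligned in normalised lane coordinates."""
    h1, w1 = f.shape
    h2, w2 = shape
    ys = np.linspace(0.0, h1 - 1.0, h2)
    xs = np.linspace(0.0, w1 - 1.0, w2)
    tmp = np.empty((h2, w1))
    rows1 = np.arange(h1, dtype=float)
    for j in range(w1):
        tmp[:, j] = np.interp(ys, rows1, f[:, j])
    out = np.empty((h2, w2))
    cols1 = np.arange(w1, dtype=float)
    for i in range(h2):
        out[i] = np.interp(xs, cols1, tmp[i])
    return out


def optimize_detailed(
    lane: LaneImage,
    schedule: HierarchySchedule | None = None,
    params: EnergyParams | None = None,
    seed: int = 0,
    callback: Callable[[DeformationField], None] | None = None,
    max_passes: int = 100,
) -> OptimizeResult:
    """Run the full hierarchical optimisation and return rich diagnostics.

    ``lane`` should be background-subtracted (signal polarity).  ``seed``
    fixes the node-permutation stream, making the result bit-reproducible.
    ``callback``, if given, receives every candidate deformation field the
    optimiser evaluates (at the working resolution, working-pixel units).
    ``max_passes`` is a safety valve on the number of full node passes per
    grid; the strict-decrease acceptance rule terminates long before it in
    practice.
    """
    if schedule is None:
        schedule = HierarchySchedule.default()
    if params is None:
        params = EnergyParams()
    h, w = lane.shape
    if w < 2 or h < 2:
        raise DimensionError(f"lane {lane.shape} too small to straighten")

    rng = np.random.default_rng(seed)
    counter = {"nev": 0, "nacc": 0}
    traces: list[StepTrace] = []
    f_run: np.ndarray | None = None  # running field, full-res shift units

    for step in schedule.steps:
        ds = downsample_lane(lane, step.fr, step.fc)
        hd, wd = ds.shape
        if hd < 2 or wd < 2:
            raise DimensionError(
                f"lane {lane.shape} is shorter than the coarsest level "
                f"({step.fr}, {step.fc})"
            )
        if f_run is None:
            f_run = np.zeros((hd, wd))
        else:
            f_run = _resample_raster(f_run, (hd, wd))
            f_run -= f_run.mean(axis=1, keepdims=True)

        # energy at the working resolution; internal weights per pixel
        eff = params.scaled(1.0 / (hd * wd))

        def energy(f: np.ndarray) -> float:
            dy = f / step.fr
            if callback is not None:
                callback(DeformationField(dy))
            warped_i, warped_m = warp_columns(ds.intensity, ds.missing, dy)
            ext = external_energy(LaneImage(warped_i, warped_m), eff)
            e_x = np.abs(np.diff(dy, axis=1)).sum()
            e_y = np.abs(np.diff(dy, axis=0)).sum()
            counter["nev"] += 1
            return ext + eff.wx * e_x + eff.wy * e_y

        e_cur = energy(f_run)
        trace = StepTrace(step.fr, step.fc, e_cur)
        traces.append(trace)

        for rg, cg in step.moves:
            g = DeformationGrid.regular(rg, cg, (hd, wd))
            ay = hat_matrix(g.node_y, hd)
            ax = hat_matrix(g.node_x, wd)
            u = ax.mean(axis=0)
            n_nodes = rg * cg

            for _ in range(max_passes):
                queue = list(rng.permutation(n_nodes))
                accepted_any = False
                qi = 0
                while qi < len(queue):
                    r, c = divmod(int(queue[qi]), cg)
                    qi += 1
                    for s in (-1, 1):
                        dv = balanced_row_delta(cg, c, s * step.delta, u)
                        inc = np.outer(ay[:, r], ax @ dv)
                        f_1 = f_run + inc
                        e_1 = energy(f_1)
                        if not e_1 < e_cur:
                            continue
                        # refine: half and one-and-a-half shifts from the
                        # same base state; ties go to the smaller shift
                        cands = [(energy(f_run + 0.5 * inc), f_run + 0.5 * inc),
                                 (e_1, f_1),
                                 (energy(f_run + 1.5 * inc), f_run + 1.5 * inc)]
                        best = int(np.argmin([e for e, _ in cands]))
                        e_cur, f_run = cands[best][0], cands[best][1]
                        trace.accepted_energies.append(e_cur)
                        counter["nacc"] += 1
                        accepted_any = True
                        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < rg and 0 <= cc < cg:
                                queue.append(rr * cg + cc)
                if not accepted_any:
                    break

    # back to full resolution
    f_full = _resample_raster(f_run, (h, w))
    f_full -= f_full.mean(axis=1, keepdims=True)
    result_field = DeformationField(f_full)

    # the returned field must never be worse than doing nothing
    eff_full = params.scaled(1.0 / (h * w))
    fell_back = False
    zero = DeformationField.zero((h, w))
    if total_energy(lane, result_field, eff_full) > total_energy(lane, zero, eff_full):
        result_field = zero
        fell_back = True

    return OptimizeResult(
        field=result_field,
        straightened=apply_deformation(lane, result_field),
        traces=traces,
        n_evaluations=counter["nev"],
        n_accepted=counter["nacc"],
        fell_back_to_zero=fell_back,
    )


def optimize(
    lane: LaneImage,
    schedule: HierarchySchedule | None = None,
    params: EnergyParams | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[LaneImage, DeformationField]:
    """Straighten a lane; returns (straightened lane, deformation field)."""
    res = optimize_detailed(lane, schedule, params, seed=seed, **kwargs)
    return res.straightened, res.field


class BandStraightener(TransformerMixin, BaseEstimator):
    """Learn a band-straightening deformation field for a gel lane.

    ``fit`` runs the hierarchical energy minimisation on a
    background-subtracted :class:`~bandstraight.lane.LaneImage`;
    ``transform`` applies the learned field (typically to the same lane, or
    to a co-registered variant such as the un-subtracted original).

    Parameters
    ----------
    wx, wy : float
        Internal-energy weights (shear / normal strain), applied per pixel
        of the working raster.
    p : float
        Exponent of the correlation-to-energy map f(c) = (1 - c)^p.
    min_overlap : int
        Minimum shared non-missing rows for a column-pair correlation.
    schedule : HierarchySchedule or None
        Resolution/transformation hierarchy; None = the default 4-step
        schedule.
    random_state : int
        Seed of the node-permutation stream (bit-reproducible results).
    max_passes : int
        Safety cap on full node passes per grid.

    Attributes
    ----------
    deformation_field_ : DeformationField
        The learned full-resolution field.
    straightened_ : LaneImage
        The fitted lane warped by the field.
    traces_ : list of StepTrace
        Accepted-move energy sequences, one per hierarchical step.
    n_evaluations_, n_accepted_ : int
    fell_back_to_zero_ : bool
        True if the zero field beat the optimised field at full resolution
        (degenerate lanes); the zero field is then returned.
    """

    def __init__(
        self,
        wx: float = 5e-2,
        wy: float = 2.5e-2,
        p: float = 1.0,
        min_overlap: int = 10,
        schedule: HierarchySchedule | None = None,
        random_state: int = 0,
        max_passes: int = 100,
    ):
        self.wx = wx
        self.wy = wy
        self.p = p
        self.min_overlap = min_overlap
        self.schedule = schedule
        self.random_state = random_state
        self.max_passes = max_passes

    def fit(self, X: LaneImage, y=None) -> "BandStraightener":
        params = EnergyParams(self.wx, self.wy, self.p, self.min_overlap)
        res = optimize_detailed(
            X,
            self.schedule,
            params,
            seed=self.random_state,
            max_passes=self.max_passes,
        )
        self.deformation_field_ = res.field
        self.straightened_ = res.straightened
        self.traces_ = res.traces
        self.n_evaluations_ = res.n_evaluations
        self.n_accepted_ = res.n_accepted
        self.fell_back_to_zero_ = res.fell_back_to_zero
        return self

    def transform(self, X: LaneImage) -> LaneImage:
        check_is_fitted(self, "deformation_field_")
        return apply_deformation(X, self.deformation_field_)
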