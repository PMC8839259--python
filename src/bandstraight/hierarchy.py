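"""Hierarchical schedule coupling image resolution to transformation scale.

Optimisation proceeds in four steps.  Each step j works on a lane
downsampled by (fr_j, fc_j) (rows, columns), enables a list of deformation
grid sizes from coarse to fine, and uses a node shift magnitude delta_j
(full-resolution pixels) that shrinks from step to step.  Column factors
stay larger than row factors because the column-correlation computation
dominates the cost and scales super-linearly in the column count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lane import DimensionError, LaneImage

#: (fr, fc) per hierarchical step.
DEFAULT_SCALE_FACTORS = ((8, 8), (4, 8), (2, 8), (1, 4))
#: Node shift magnitude per step, in full-resolution pixels.
DEFAULT_DELTAS = (8.0, 4.0, 2.0, 1.0)
#: Grid sizes (rg, cg) enabled at each step, coarse to fine.
DEFAULT_MOVES = (
    ((2, 3), (3, 3)),
    ((3, 5), (4, 5)),
    ((5, 7), (6, 9)),
    ((8, 9), (10, 11)),
)


@dataclass(frozen=True)
class HierarchyStep:
    fr: int
    fc: int
    delta: float
    moves: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.fr < 1 or self.fc < 1:
            raise ValueError("scale factors must be >= 1")
        if self.delta <= 0:
            raise ValueError("node shift magnitude must be positive")
        for (r0, c0), (r1, c1) in zip(self.moves, self.moves[1:]):
            if r1 < r0 or c1 < c0:
                raise ValueError("grids within a step must only get finer")


@dataclass(frozen=True)
class HierarchySchedule:
    steps: tuple[HierarchyStep, ...]

    def __post_init__(self) -> None:
        deltas = [s.delta for s in self.steps]
        if any(b >= a for a, b in zip(deltas, deltas[1:])) and len(deltas) > 1:
            raise ValueError("node shifts must strictly decrease over steps")

    @classmethod
    def default(cls) -> "HierarchySchedule":
        return cls(
            tuple(
                HierarchyStep(fr, fc, d, m)
                for (fr, fc), d, m in zip(
                    DEFAULT_SCALE_FACTORS, DEFAULT_DELTAS, DEFAULT_MOVES
                )
            )
        )


def downsample_lane(lane: LaneImage, fr: int, fc: int) -> LaneImage:
    """Block-mean reduction over fr x fc blocks, ignoring missing pixels.

    A block with no valid pixel is missing in the output.  Partial blocks
    at the bottom/right edges are averaged over their valid content.
    """
    if fr < 1 or fc < 1:
        raise ValueError("downsampling factors must be >= 1")
    h, w = lane.shape
    if fr > h or fc > w:
        raise DimensionError(
            f"factors ({fr}, {fc}) exceed lane dimensions ({h}, {w})"
        )
    if fr == 1 and fc == 1:
        return lane.copy()
    pad_y = (-h) % fr
    pad_x = (-w) % fc
    valid = (~lane.missing).astype(float)
    x = np.pad(lane.intensity * valid, ((0, pad_y), (0, pad_x)))
    v = np.pad(valid, ((0, pad_y), (0, pad_x)))
    hb, wb = x.shape[0] // fr, x.shape[1] // fc
    sums = x.reshape(hb, fr, wb, fc).sum(axis=(1, 3))
    counts = v.reshape(hb, fr, wb, fc).sum(axis=(1, 3))
    missing = counts == 0
    out = np.zeros_like(sums)
    out[~missing] = sums[~missing] / counts[~missing]
    return LaneImage(out, missing)
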