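"""Deformation grids: coarse node lattices whose bilinear interpolation
yields a per-pixel deformation field.

A grid of rg x cg nodes spans the lane, nodes on all four borders.  A
*move* shifts one node vertically; to keep the interpolated field's mean
shift zero in every pixel row, the other nodes of the same grid row absorb
the move in proportion to their interpolation weight (border nodes carry
roughly half the weight of interior nodes when the node row is sampled at
the pixel columns, so the absorption is weight-aware rather than an equal
split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .warp import DeformationField


class CoverageError(ValueError):
    """Grid nodes do not span the requested raster."""


def hat_matrix(nodes: np.ndarray, size: int) -> np.ndarray:
    """(size x n_nodes) linear-interpolation weights at integer positions.

    ``nodes`` must be strictly increasing and cover [0, size-1].
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.size < 2 or not np.all(np.diff(nodes) > 0):
        raise ValueError("nodes must be strictly increasing, length >= 2")
    if nodes[0] > 0 or nodes[-1] < size - 1:
        raise CoverageError(
            f"nodes [{nodes[0]}, {nodes[-1]}] do not cover [0, {size - 1}]"
        )
    pos = np.arange(size, dtype=float)
    seg = np.clip(np.searchsorted(nodes, pos, side="right") - 1, 0, nodes.size - 2)
    frac = (pos - nodes[seg]) / (nodes[seg + 1] - nodes[seg])
    a = np.zeros((size, nodes.size))
    a[np.arange(size), seg] = 1.0 - frac
    a[np.arange(size), seg + 1] += frac
    return a


@dataclass
class DeformationGrid:
    """An rg x cg node lattice with vertical shifts at each node.

    ``node_y``/``node_x`` are node coordinates in the raster the grid
    spans; ``shifts`` holds one vertical displacement per node (pixels,
    positive = downward).
    """

    node_y: np.ndarray
    node_x: np.ndarray
    shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_y = np.asarray(self.node_y, dtype=float).ravel()
        self.node_x = np.asarray(self.node_x, dtype=float).ravel()
        if self.node_y.size < 2 or self.node_x.size < 2:
            raise ValueError("a deformation grid needs at least 2x2 nodes")
        if self.shifts is None:
            self.shifts = np.zeros((self.node_y.size, self.node_x.size))
        else:
            self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.shape != (self.node_y.size, self.node_x.size):
            raise ValueError(
                f"shifts shape {self.shifts.shape} != grid "
                f"({self.node_y.size}, {self.node_x.size})"
            )

    @classmethod
    def regular(
        cls, rg: int, cg: int, shape: tuple[int, int]
    ) -> "DeformationGrid":
        """Evenly spaced rg x cg grid spanning a (H, W) raster."""
        h, w = shape
        return cls(np.linspace(0, h - 1, rg), np.linspace(0, w - 1, cg))

    @property
    def rg(self) -> int:
        return self.node_y.size

    @property
    def cg(self) -> int:
        return self.node_x.size

    @property
    def width(self) -> int:
        """Width of the raster the node columns span."""
        return int(round(self.node_x[-1])) + 1

    def column_weights(self) -> np.ndarray:
        """Weight of each node column in the discrete row mean of the field.

        u[i] is the mean over integer pixel columns of node i's hat
        function; sum(u) = 1.  A grid-row shift vector v yields an
        interpolated field row with discrete mean u . v.
        """
        return hat_matrix(self.node_x, self.width).mean(axis=0)

    def copy(self) -> "DeformationGrid":
        return DeformationGrid(self.node_y.copy(), self.node_x.copy(),
                               self.shifts.copy())


def grid_to_field(grid: DeformationGrid, shape: tuple[int, int]) -> DeformationField:
    """Bilinear interpolation of node shifts over a (H, W) raster."""
    h, w = shape
    ay = hat_matrix(grid.node_y, h)
    ax = hat_matrix(grid.node_x, w)
    return DeformationField(ay @ grid.shifts @ ax.T)


def balanced_row_delta(
    n_cols: int, col: int, amount: float, weights: np.ndarray
) -> np.ndarray:
    """Shift vector for one grid row: ``amount`` at ``col``, absorbed by the
    other nodes so the weighted (= field-row) mean change is exactly zero."""
    if n_cols < 2:
        raise ValueError("degenerate grid: need at least 2 node columns")
    dv = np.zeros(n_cols)
    dv[col] = amount
    others = np.ones(n_cols, dtype=bool)
    others[col] = False
    dv[others] = -amount * weights[col] / weights[others].sum()
    # remove floating-point residue so the constraint holds to ~1e-16
    dv -= weights @ dv / weights.sum()
    return dv


def propose_move(
    grid: DeformationGrid, k: tuple[int, int] | int, s: int, delta: float
) -> DeformationGrid:
    """Candidate grid for the move "shift node k by s*delta".

    The other nodes of k's grid row move slightly in the opposite
    direction (weighted by their interpolation footprint) so the
    interpolated field keeps a zero mean shift in every row.
    """
    if grid.cg < 2:
        raise ValueError("degenerate grid: need at least 2 node columns")
    if isinstance(k, (int, np.integer)):
        k = divmod(int(k), grid.cg)
    r, c = k
    if not (0 <= r < grid.rg and 0 <= c < grid.cg):
        raise IndexError(f"node {k} outside a {grid.rg}x{grid.cg} grid")
    out = grid.copy()
    if delta != 0:
        u = grid.column_weights()
        out.shifts[r] += balanced_row_delta(grid.cg, c, s * delta, u)
    return out
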