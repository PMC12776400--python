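"""Macrocell discretization of a single 96-well-plate well.

The working fluid in one round well (diameter ~6.4 mm, fill height ~8-10 mm
for 200-250 uL) is represented by a 2-D vertical slice through the well
diameter: ``x`` is the lateral position across the diameter, ``x in [-R, R]``,
and ``z`` is the depth coordinate, ``z in [0, H]`` with ``z`` increasing
upward and the liquid surface at ``z = H``.  The slice is tiled by a regular
Cartesian grid of equal-volume "macrocells", each holding one concentration
value and exchanging solute with its face neighbors (up/down/left/right).
Out-of-plane recirculation is not resolved by the grid; it is represented by
a global relaxation term in :mod:`wellmix.dynamics`.

Cylinder curvature is ignored: every macrocell has the same volume, which
makes the exchange matrix symmetric and the variance metric an unweighted
average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

__all__ = ["WellGeometry", "MacrocellGrid", "build_grid"]


@dataclass(frozen=True)
class WellGeometry:
    """Dimensions and grid resolution of the discretized well.

    Parameters
    ----------
    radius:
        Inner well radius R in mm.  Default 3.2 (6.4 mm diameter well).
    fill_height:
        Working fluid height H in mm.  Default 8.0.
    n_x:
        Number of grid columns across the diameter.
    n_z:
        Number of grid rows over the fluid depth.
    """

    radius: float = 3.2
    fill_height: float = 8.0
    n_x: int = 16
    n_z: int = 16

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.fill_height > 0):
            raise InvalidGeometryError(
                f"well dimensions must be positive, got radius={self.radius}, "
                f"fill_height={self.fill_height}"
            )
        if self.n_x < 1 or self.n_z < 1:
            raise InvalidGeometryError(
                f"grid sizes must be >= 1, got n_x={self.n_x}, n_z={self.n_z}"
            )


@dataclass(frozen=True)
class MacrocellGrid:
    """A regular grid of macrocells tiling the vertical fluid slice.

    Cells are indexed row-major: cell ``i = row * n_x + col`` with row 0 at
    the bottom (``z ~ 0``) and column 0 at the left (``x ~ -R``).  ``cells``
    holds the (x, z) centers in mm, ``edges`` the unordered face-neighbor
    index pairs, and ``cell_volume`` the common volume per cell (slice volume
    ``2R * H`` times a unit out-of-plane thickness, divided by the number of
    cells).
    """

    geometry: WellGeometry
    cells: np.ndarray = field(repr=False)  # (N, 2) float, mm
    cell_volume: float
    edges: np.ndarray = field(repr=False)  # (E, 2) int

    @property
    def n_cells(self) -> int:
        return self.geometry.n_x * self.geometry.n_z

    @property
    def n_x(self) -> int:
        return self.geometry.n_x

    @property
    def n_z(self) -> int:
        return self.geometry.n_z

    def row_col(self, index: int) -> tuple[int, int]:
        """Return (row, col) of a flat cell index."""
        return divmod(index, self.n_x)[0], index % self.n_x


def build_grid(geometry: WellGeometry) -> MacrocellGrid:
    """Discretize the well slice into macrocells with face connectivity.

    Cell centers sit at the midpoints of a uniform ``n_x x n_z`` tiling of
    the rectangle ``x in [-R, R], z in [0, H]``.  The edge list contains one
    entry per shared face: ``n_x * (n_z - 1)`` vertical plus
    ``n_z * (n_x - 1)`` horizontal edges.
    """
    R, H = geometry.radius, geometry.fill_height
    n_x, n_z = geometry.n_x, geometry.n_z

    dx = 2.0 * R / n_x
    dz = H / n_z
    xs = -R + (np.arange(n_x) + 0.5) * dx
    zs = (np.arange(n_z) + 0.5) * dz
    X, Z = np.meshgrid(xs, zs)  # row-major: axis 0 is the z row
    cells = np.column_stack([X.ravel(), Z.ravel()])

    idx = np.arange(n_x * n_z).reshape(n_z, n_x)
    horizontal = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    vertical = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    edges = np.vstack([horizontal, vertical]).astype(np.intp)

    cell_volume = (2.0 * R) * H / (n_x * n_z)  # unit out-of-plane thickness
    return MacrocellGrid(
        geometry=geometry, cells=cells, cell_volume=cell_volume, edges=edges
    )
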