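"""Pipette jet geometry: axis and macrocell footprint.

A dispense stroke drives a jet of fluid along the pipette axis.  The axis is
the line through the tip point, tilted by the pipette angle from vertical;
macrocells whose centers lie within a perpendicular distance ``r_f * R`` of
that line form the *jet footprint*, inside which neighbor exchange is
enhanced during the stroke (see :mod:`wellmix.dynamics`).

Conventions: the tip sits at ``x = tip_offset * R`` (offset measured toward
``+x``) at depth ``z = tip_depth_frac * H``; tilt is toward ``+x``, the same
side as the offset.  The axis is treated as an infinite line: anchoring at a
mid-depth tip point keeps the swept band comparable across angles, whereas
anchoring at the surface entry point would push large tilts into a corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError
from .geometry import MacrocellGrid, WellGeometry

__all__ = ["PipetteConfig", "JetAxis", "JetFootprint", "jet_axis", "compute_footprint"]

#: Pinned fraction of the fill height at which the tip point sits.
DEFAULT_TIP_DEPTH_FRAC = 0.3


@dataclass(frozen=True)
class PipetteConfig:
    """Jet parameters of one pipetting protocol.

    Parameters
    ----------
    angle_deg:
        Pipette angle from vertical, degrees, in [0, 60] (0 = vertical,
        30-60 = moderate tilt).
    tip_offset:
        Lateral tip position as a fraction of the well radius, in [0, 1).
    footprint_radius:
        Half-width of the jet band as a fraction of R, > 0.
    jet_strength:
        Dimensionless jet strength S: footprint-internal edge rates are
        ``(1 + S)`` times the baseline exchange rate.
    tip_depth_frac:
        Depth of the tip point as a fraction of H (pinned default 0.3).
    cycled_volume_fraction:
        Fraction of the well volume aspirated per stroke.  Carried as
        protocol metadata only; the model does not remove and re-inject
        fluid parcels, so this value is never used numerically.
    """

    angle_deg: float = 0.0
    tip_offset: float = 0.0
    footprint_radius: float = 0.55
    jet_strength: float = 8.0
    tip_depth_frac: float = DEFAULT_TIP_DEPTH_FRAC
    cycled_volume_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 60.0):
            raise InvalidConfigError(
                f"angle_deg must be in [0, 60], got {self.angle_deg}"
            )
        if not (0.0 <= self.tip_offset < 1.0):
            raise InvalidConfigError(
                f"tip_offset must be in [0, 1), got {self.tip_offset}"
            )
        if not self.footprint_radius > 0:
            raise InvalidConfigError(
                f"footprint_radius must be > 0, got {self.footprint_radius}"
            )
        if not self.jet_strength > 0:
            raise InvalidConfigError(
                f"jet_strength must be > 0, got {self.jet_strength}"
            )
        if not (0.0 <= self.tip_depth_frac <= 1.0):
            raise InvalidConfigError(
                f"tip_depth_frac must be in [0, 1], got {self.tip_depth_frac}"
            )
        if self.cycled_volume_fraction is not None and not (
            0.0 < self.cycled_volume_fraction <= 1.0
        ):
            raise InvalidConfigError(
                "cycled_volume_fraction must be in (0, 1], got "
                f"{self.cycled_volume_fraction}"
            )


@dataclass(frozen=True)
class JetAxis:
    """An infinite line in the (x, z) slice: anchor point plus unit direction."""

    anchor: tuple[float, float]
    direction: tuple[float, float]


@dataclass(frozen=True)
class JetFootprint:
    """Set of macrocell indices inside the jet band and its grid fraction."""

    cell_indices: frozenset[int]
    fraction: float

    def mask(self, n_cells: int) -> np.ndarray:
        """Boolean membership mask over ``n_cells`` grid cells."""
        m = np.zeros(n_cells, dtype=bool)
        if self.cell_indices:
            m[np.fromiter(self.cell_indices, dtype=np.intp)] = True
        return m


def jet_axis(config: PipetteConfig, geometry: WellGeometry) -> JetAxis:
    """Return the pipette axis through the tip point.

    The tip point is ``(tip_offset * R, tip_depth_frac * H)``; the direction
    makes ``angle_deg`` with the vertical, tilted toward ``+x``, and is a
    unit vector ``(sin theta, cos theta)``.
    """
    theta = math.radians(config.angle_deg)
    anchor = (
        config.tip_offset * geometry.radius,
        config.tip_depth_frac * geometry.fill_height,
    )
    return JetAxis(anchor=anchor, direction=(math.sin(theta), math.cos(theta)))


def compute_footprint(
    grid: MacrocellGrid, axis: JetAxis, footprint_radius: float
) -> JetFootprint:
    """Select the macrocells within ``footprint_radius * R`` of the axis.

    The perpendicular distance from each cell center to the infinite axis
    line is compared against the band half-width; an empty footprint is a
    valid result and simply means no enhancement anywhere.
    """
    ax, az = axis.anchor
    dx, dz = axis.direction
    px = grid.cells[:, 0] - ax
    pz = grid.cells[:, 1] - az
    # |cross(p - a, d)| for unit d is the point-to-line distance
    dist = np.abs(px * dz - pz * dx)
    inside = dist <= footprint_radius * grid.geometry.radius
    indices = frozenset(int(i) for i in np.nonzero(inside)[0])
    return JetFootprint(cell_indices=indices, fraction=len(indices) / grid.n_cells)
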