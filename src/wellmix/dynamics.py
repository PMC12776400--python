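"""Exchange-rate matrix, per-cycle mixing operator, and cycle iteration.

Solute transport between macrocells follows the linear compartment system

    dc/dtau = K c,

in dimensionless time ``tau = k0 t``, where the off-diagonal entries of the
rate matrix ``K`` are the pairwise exchange rates in units of the baseline
rate ``k0`` (so un-enhanced edges carry rate 1, footprint-internal edges
rate ``1 + S``) and the diagonal enforces zero column sums, i.e. exact mass
conservation.  With equal cell volumes ``K`` is the negated weighted graph
Laplacian of the grid and is symmetric.

One aspirate-dispense stroke is modeled as a single application of the
linear mixing operator ``M = exp(tau_c K)`` — the square-wave jet schedule
(jet on during dispense, off otherwise) is aggregated into one jet-on
exponential per cycle, with the effective per-stroke duration ``tau_c``
absorbing the aspiration/rest phases — followed by a weak global
recirculation step that relaxes every cell toward the well mean, standing in
for the bulk 3-D recirculating flow the 2-D slice cannot resolve.  ``M`` is
symmetric, entrywise non-negative and doubly stochastic, so the spatial
variance of the concentration field contracts every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .geometry import MacrocellGrid, WellGeometry, build_grid
from .jet import JetFootprint, PipetteConfig, compute_footprint, jet_axis
from .metrics import phi

__all__ = [
    "RateMatrix",
    "CalibrationConstants",
    "Trajectory",
    "build_rate_matrix",
    "cycle_operator",
    "recirculation_coefficient",
    "apply_recirculation",
    "initial_condition",
    "simulate",
]

#: Pinned cap on the per-cycle recirculation coefficient.
DEFAULT_GAMMA_MAX = 0.5


@dataclass(frozen=True)
class RateMatrix:
    """Conservative exchange-rate matrix over the macrocell grid.

    ``matrix`` is dense ``(N, N)``: off-diagonal entries are the edge rates
    (0 off the grid edges), the diagonal is minus the column sum of the
    off-diagonals.  ``enhanced_edges`` records which grid edges received the
    jet enhancement.
    """

    matrix: np.ndarray = field(repr=False)
    enhanced_edges: frozenset[tuple[int, int]] = frozenset()

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CalibrationConstants:
    """The model's two free constants plus the recirculation cap.

    ``tau_c`` is the dimensionless effective duration of one stroke
    (``k0 * delta-tau`` aggregated over the jet-on phase); ``gamma0`` scales
    the global recirculation coefficient; ``gamma_max`` caps it (pinned 0.5).
    """

    tau_c: float
    gamma0: float
    gamma_max: float = DEFAULT_GAMMA_MAX

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise InvalidParameterError(f"tau_c must be > 0, got {self.tau_c}")
        if self.gamma0 < 0:
            raise InvalidParameterError(f"gamma0 must be >= 0, got {self.gamma0}")
        if not (0.0 <= self.gamma_max <= 1.0):
            raise InvalidParameterError(
                f"gamma_max must be in [0, 1], got {self.gamma_max}"
            )


@dataclass(frozen=True)
class Trajectory:
    """Per-cycle concentration fields and mixing metric.

    ``concentrations`` has shape ``(n_cycles + 1, n_cells)`` with row 0 the
    initial field; ``phi_series`` the matching normalized variance values,
    starting at 1.
    """

    concentrations: np.ndarray = field(repr=False)
    phi_series: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.phi_series) - 1

    @property
    def final_phi(self) -> float:
        return float(self.phi_series[-1])


def build_rate_matrix(
    grid: MacrocellGrid, footprint: JetFootprint, jet_strength: float
) -> RateMatrix:
    """Assemble K with baseline rate 1 and rate ``1 + S`` on jet edges.

    An edge is enhanced only when *both* endpoints lie inside the footprint,
    keeping the enhanced subgraph interior to the jet band.
    """
    if not jet_strength > 0:
        raise InvalidParameterError(f"jet_strength must be > 0, got {jet_strength}")
    N = grid.n_cells
    mask = footprint.mask(N)
    a, b = grid.edges[:, 0], grid.edges[:, 1]
    rates = np.where(mask[a] & mask[b], 1.0 + jet_strength, 1.0)

    K = np.zeros((N, N))
    K[a, b] = rates
    K[b, a] = rates
    K[np.diag_indices(N)] = -K.sum(axis=0)
    enhanced = frozenset(
        (int(i), int(j)) for i, j, r in zip(a, b, rates) if r > 1.0
    )
    return RateMatrix(matrix=K, enhanced_edges=enhanced)


def cycle_operator(rate_matrix: RateMatrix, tau_c: float) -> np.ndarray:
    """Matrix exponential ``M = exp(tau_c K)`` for one stroke.

    Computed through the eigendecomposition of the symmetric K, which keeps
    M exactly symmetric; ``tau_c = 0`` returns the identity.
    """
    if tau_c < 0:
        raise InvalidParameterError(f"tau_c must be >= 0, got {tau_c}")
    K = rate_matrix.matrix
    if tau_c == 0:
        return np.eye(K.shape[0])
    w, V = np.linalg.eigh(K)
    M = (V * np.exp(tau_c * w)) @ V.T
    return (M + M.T) / 2.0


def recirculation_coefficient(
    gamma0: float,
    jet_strength: float,
    footprint_fraction: float,
    gamma_max: float = DEFAULT_GAMMA_MAX,
) -> float:
    """Per-cycle recirculation coefficient ``min(gamma_max, gamma0 * S * f)``.

    Recirculation grows with jet strength and footprint size — a stronger,
    broader jet drives more bulk recirculation — and is capped at
    ``gamma_max``.
    """
    if gamma0 < 0 or jet_strength < 0 or footprint_fraction < 0 or gamma_max < 0:
        raise InvalidParameterError("recirculation inputs must be non-negative")
    return min(gamma_max, gamma0 * jet_strength * footprint_fraction)


def apply_recirculation(c: np.ndarray, gamma: float) -> np.ndarray:
    """Relax the field toward its mean: ``c' = (1 - gamma) c + gamma mean(c)``.

    Preserves the mean exactly and multiplies the spatial variance by
    ``(1 - gamma)^2``.
    """
    if not (0.0 <= gamma <= 1.0):
        raise InvalidParameterError(f"gamma must be in [0, 1], got {gamma}")
    return (1.0 - gamma) * c + gamma * float(np.mean(c))


def initial_condition(grid: MacrocellGrid) -> np.ndarray:
    """Biphasic start: upper half of the well at c = 1, lower half at 0.

    The upper ``n_z // 2`` rows are set to 1.  For odd ``n_z`` the extra
    middle row joins the lower block (tie-break), so the mean is 0.5 only
    for even ``n_z``.
    """
    c = np.zeros(grid.n_cells)
    first_high_row = grid.n_z - grid.n_z // 2  # odd n_z: middle row stays low
    c[first_high_row * grid.n_x :] = 1.0
    return c


def simulate(
    geometry: WellGeometry,
    config: PipetteConfig,
    constants: CalibrationConstants,
    n_cycles: int = 12,
) -> Trajectory:
    """Run ``n_cycles`` aspirate-dispense cycles from the biphasic start.

    Each cycle applies the mixing operator and then the recirculation
    relaxation; the concentration field and the normalized variance are
    recorded after every full cycle.
    """
    if n_cycles < 0:
        raise InvalidParameterError(f"n_cycles must be >= 0, got {n_cycles}")
    grid = build_grid(geometry)
    axis = jet_axis(config, geometry)
    footprint = compute_footprint(grid, axis, config.footprint_radius)
    K = build_rate_matrix(grid, footprint, config.jet_strength)
    M = cycle_operator(K, constants.tau_c)
    gamma = recirculation_coefficient(
        constants.gamma0, config.jet_strength, footprint.fraction, constants.gamma_max
    )

    c0 = initial_condition(grid)
    fields = [c0]
    phis = [1.0]
    c = c0
    for _ in range(n_cycles):
        c = apply_recirculation(M @ c, gamma)
        fields.append(c)
        phis.append(phi(c, c0))
    return Trajectory(
        concentrations=np.asarray(fields), phi_series=np.asarray(phis)
    )
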