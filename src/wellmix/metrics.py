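"""Mixing metric and threshold-crossing statistics.

Mixedness is quantified by the normalized concentration variance

    Phi(tau) = Var c_i(tau) / Var c_i(0),

the population (divide-by-N) spatial variance of the field relative to the
initial field; with equal cell volumes the volume-weighted mean reduces to
the plain mean.  Phi = 1 is the unmixed start and Phi -> 0 the perfectly
mixed state; operational thresholds are Phi <= 0.05 ("well mixed") and
Phi <= 0.01 ("highly mixed").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedNormalizationError

__all__ = ["MixingResult", "phi", "cycles_to_threshold", "NOT_REACHED"]

#: Sentinel for a threshold not reached within the simulated window.
NOT_REACHED = None


@dataclass(frozen=True)
class MixingResult:
    """Threshold crossings and final mixedness of one simulated protocol.

    ``cycles_to_05`` / ``cycles_to_01`` are the first cycle indices with
    Phi <= 0.05 / 0.01, or ``None`` when not reached within the window
    (serialized as ``">N"``); ``final_phi`` is Phi after the last cycle.
    """

    cycles_to_05: int | None
    cycles_to_01: int | None
    final_phi: float
    n_cycles: int = 12

    def serialize_cycles(self, value: int | None) -> str:
        return f">{self.n_cycles}" if value is NOT_REACHED else str(value)


def phi(c: np.ndarray, reference: np.ndarray) -> float:
    """Normalized concentration variance of ``c`` against the reference field.

    Both variances are population variances; a uniform reference makes the
    normalization undefined and raises.
    """
    c = np.asarray(c, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if c.shape != reference.shape:
        raise ValueError(
            f"field shapes differ: {c.shape} vs {reference.shape}"
        )
    var0 = float(np.var(reference))
    if var0 == 0.0:
        raise UndefinedNormalizationError(
            "reference field is uniform; Phi is undefined"
        )
    return float(np.var(c)) / var0


def cycles_to_threshold(
    phi_series: Sequence[float], threshold: float
) -> int | None:
    """Smallest cycle index n with ``phi_series[n] <= threshold``.

    The comparison is inclusive; returns ``None`` (not reached) when no
    entry qualifies.
    """
    series = np.asarray(phi_series, dtype=float)
    if series.size == 0:
        raise ValueError("phi_series must be non-empty")
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    hits = np.nonzero(series <= threshold)[0]
    return int(hits[0]) if hits.size else NOT_REACHED
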