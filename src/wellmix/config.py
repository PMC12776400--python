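"""Run configuration schema and YAML parsing.

A run configuration groups the well geometry, the pipette/jet parameters,
the two calibration constants (given directly or resolved by a ``calibrate``
directive), the run window, and output paths.  Parsing validates every block
and reports *all* violations at once.

Schema (YAML or JSON; every block optional except ``pipette`` fields have
usable defaults too)::

    geometry:  {radius: 3.2, fill_height: 8.0, n_x: 16, n_z: 16}
    pipette:   {angle_deg: 0, tip_offset: 0, footprint_radius: 0.55,
                jet_strength: 8.0, tip_depth_frac: 0.3}
    constants: {tau_c: ..., gamma0: ..., gamma_max: 0.5}   # or:
    calibrate: {}        # use the packaged anchors (default when neither given)
    run:       {n_cycles: 12, thresholds: [0.05, 0.01]}
    output:    {directory: ".", prefix: "wellmix"}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import CalibrationConstants
from .errors import InvalidConfigError, WellmixError
from .geometry import WellGeometry
from .jet import PipetteConfig
from .scenarios import calibrate

__all__ = ["RunConfig", "parse_config"]

_KNOWN_BLOCKS = {"geometry", "pipette", "constants", "calibrate", "run", "output"}
_BLOCK_KEYS = {
    "geometry": {"radius", "fill_height", "n_x", "n_z"},
    "pipette": {
        "angle_deg",
        "tip_offset",
        "footprint_radius",
        "jet_strength",
        "tip_depth_frac",
        "cycled_volume_fraction",
    },
    "constants": {"tau_c", "gamma0", "gamma_max"},
    "calibrate": set(),
    "run": {"n_cycles", "thresholds"},
    "output": {"directory", "prefix"},
}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated simulation configuration."""

    geometry: WellGeometry
    pipette: PipetteConfig
    constants: CalibrationConstants | None  # None -> resolve by calibration
    n_cycles: int = 12
    thresholds: tuple[float, ...] = (0.05, 0.01)
    output_directory: Path = Path(".")
    output_prefix: str = "wellmix"

    def resolve_constants(self) -> CalibrationConstants:
        """Return the constants, running the default calibration if needed."""
        return self.constants if self.constants is not None else calibrate()


def _check_keys(block: str, data: dict, errors: list[str]) -> None:
    unknown = set(data) - _BLOCK_KEYS[block]
    if unknown:
        errors.append(f"{block}: unknown keys {sorted(unknown)}")


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file.

    Defaults: 16x16 grid of a 3.2 mm x 8.0 mm well, vertical centered
    aggressive/large pipette, thresholds [0.05, 0.01], 12 cycles, constants
    resolved by calibration.  All constraint violations are collected and
    reported together.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError(f"{path}: top level must be a mapping")

    errors: list[str] = []
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        errors.append(f"unknown blocks {sorted(unknown)}")

    def build(block: str, factory, data: dict):
        _check_keys(block, data, errors)
        clean = {k: v for k, v in data.items() if k in _BLOCK_KEYS[block]}
        try:
            return factory(**clean)
        except (WellmixError, TypeError) as exc:
            errors.append(f"{block}: {exc}")
            return None

    geometry = build("geometry", WellGeometry, raw.get("geometry", {}))
    pipette = build("pipette", PipetteConfig, raw.get("pipette", {}))

    constants = None
    if "constants" in raw and "calibrate" in raw:
        errors.append("give either a constants block or a calibrate directive")
    elif "constants" in raw:
        constants = build("constants", CalibrationConstants, raw["constants"])

    run = raw.get("run", {})
    _check_keys("run", run, errors)
    n_cycles = run.get("n_cycles", 12)
    thresholds = tuple(run.get("thresholds", (0.05, 0.01)))
    if not (isinstance(n_cycles, int) and n_cycles >= 0):
        errors.append(f"run: n_cycles must be a non-negative integer, got {n_cycles}")
    if any(not t > 0 for t in thresholds):
        errors.append(f"run: thresholds must be positive, got {list(thresholds)}")
    elif list(thresholds) != sorted(thresholds, reverse=True):
        errors.append(f"run: thresholds must be sorted descending, got {list(thresholds)}")

    out = raw.get("output", {})
    _check_keys("output", out, errors)

    if errors:
        raise InvalidConfigError(
            f"{path}: invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    assert geometry is not None and pipette is not None
    return RunConfig(
        geometry=geometry,
        pipette=pipette,
        constants=constants,
        n_cycles=n_cycles,
        thresholds=thresholds,
        output_directory=Path(out.get("directory", ".")),
        output_prefix=str(out.get("prefix", "wellmix")),
    )
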