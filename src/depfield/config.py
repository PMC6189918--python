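"""YAML run-configuration parsing with explicit unit suffixes.

Internally everything is SI.  Config values may be plain numbers (taken as
SI) or strings with a unit suffix, e.g. ``"150 um"``, ``"0.5 V"``,
``"1e-3 S/m"``.  The accepted fields and their units are documented in
``docs/config.schema.json``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import (
    ChannelGeometry,
    DriveCondition,
    MediumProperties,
    ParticleProperties,
    VoltagePattern,
)
from .validation import ROISpec

__all__ = ["RunConfig", "ConfigError", "parse_quantity", "load_config"]

_UNIT_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    "v": 1.0,
    "mv": 1e-3,
    "kv": 1e3,
    "s": 1.0,
    "ms": 1e-3,
    "us": 1e-6,
    "s/m": 1.0,
    "ms/m": 1e-3,
    "rad/s": 1.0,
    "hz": 2 * 3.141592653589793,  # frequency in Hz -> angular rad/s
    "khz": 2e3 * 3.141592653589793,
    "mhz": 2e6 * 3.141592653589793,
    "pa.s": 1.0,
    "mpa.s": 1e-3,
    "kg/m3": 1.0,
    "deg": 1.0,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ./0-9]*)\s*$")


class ConfigError(ValueError):
    """Raised for malformed or incomplete run configurations."""


def parse_quantity(value) -> float:
    """Convert a number (SI) or a ``"<number> <unit>"`` string to SI units."""
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise ConfigError(f"cannot parse quantity from {value!r}")
    m = _QTY_RE.match(value)
    if not m:
        raise ConfigError(f"malformed quantity {value!r}")
    number, unit = m.groups()
    try:
        x = float(number)
    except ValueError as exc:
        raise ConfigError(f"malformed number in {value!r}") from exc
    if not unit:
        return x
    factor = _UNIT_FACTORS.get(unit.lower())
    if factor is None:
        raise ConfigError(f"unknown unit {unit!r} in {value!r}")
    return x * factor


@dataclass
class RunConfig:
    """Resolved configuration for one CLI run (all fields SI)."""

    geometry: ChannelGeometry
    medium: MediumProperties
    particle: ParticleProperties | None
    drive: DriveCondition | None
    voltages: VoltagePattern | None
    truncation_P: int | None = None
    spacing: float = 0.5e-6
    roi: ROISpec = field(default_factory=ROISpec)
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)


def _section(data: dict, name: str, required: bool = True) -> dict | None:
    sec = data.get(name)
    if sec is None:
        if required:
            raise ConfigError(f"missing required config section {name!r}")
        return None
    if not isinstance(sec, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    return sec


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    g = _section(data, "geometry")
    try:
        geometry = ChannelGeometry(
            width_L=parse_quantity(g["width"]),
            height_h=parse_quantity(g["height"]),
            n_top=int(g["n_top"]),
            n_bottom=int(g["n_bottom"]),
        )
    except KeyError as exc:
        raise ConfigError(f"geometry section missing key {exc}") from exc

    m = _section(data, "medium", required=False) or {}
    medium = MediumProperties(
        rel_permittivity_em=float(m.get("rel_permittivity", 78.0)),
        conductivity_sm=parse_quantity(m.get("conductivity", 0.0)),
        wall_rel_permittivity_ew=float(m.get("wall_rel_permittivity", 4.0)),
    )

    p = _section(data, "particle", required=False)
    particle = (
        ParticleProperties(
            radius_r=parse_quantity(p["radius"]),
            rel_permittivity_ep=float(p.get("rel_permittivity", 2.5)),
            conductivity_sp=parse_quantity(p.get("conductivity", 0.0)),
        )
        if p
        else None
    )

    d = _section(data, "drive", required=False)
    drive = None
    if d:
        drive = DriveCondition(
            angular_frequency_v=(
                parse_quantity(d["frequency"]) if "frequency" in d else None
            ),
            cm_real_override=(
                float(d["cm_real"]) if "cm_real" in d else None
            ),
        )

    v = _section(data, "voltages", required=False)
    voltages = None
    if v:
        try:
            voltages = VoltagePattern(u_top=v["top"], u_bottom=v["bottom"])
        except KeyError as exc:
            raise ConfigError(f"voltages section missing key {exc}") from exc
        voltages.check_geometry(geometry)

    model = _section(data, "model", required=False) or {}
    solver = _section(data, "solver", required=False) or {}
    roi_sec = _section(data, "roi", required=False)
    roi = (
        ROISpec(
            y_range=tuple(float(x) for x in roi_sec["y"]),
            z_range=tuple(float(x) for x in roi_sec["z"]),
        )
        if roi_sec
        else ROISpec()
    )

    return RunConfig(
        geometry=geometry,
        medium=medium,
        particle=particle,
        drive=drive,
        voltages=voltages,
        truncation_P=(
            int(model["p_harmonics"]) if "p_harmonics" in model else None
        ),
        spacing=parse_quantity(solver.get("spacing", 0.5e-6)),
        roi=roi,
        seed=int(data.get("seed", 0)),
        raw=data,
    )
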