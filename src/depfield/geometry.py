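"""Channel geometry, material and drive descriptions.

All quantities are stored internally in SI units (metres, volts, seconds,
siemens per metre).  The config loader (:mod:`depfield.config`) accepts
micrometre-suffixed strings and converts on load, so scale bugs involving
the vacuum permittivity cannot creep in here.

Coordinate conventions
----------------------
* ``y`` runs across the channel, ``y ∈ [0, L]``.
* Single-array frame: ``z ∈ [0, h]`` with the electrode plane at ``z = 0``
  and a grounded plane at ``z = h``.
* Dual-array frame: ``z ∈ [−h/2, +h/2]`` with the top array at ``z = +h/2``
  and the bottom array at ``z = −h/2``.  The affine maps between frames are
  ``ζ_top = h/2 − z`` and ``ζ_bottom = h/2 + z`` (distance from the
  respective electrode plane).
* Both arrays index their electrodes left to right (increasing ``y``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelGeometry",
    "MediumProperties",
    "ParticleProperties",
    "DriveCondition",
    "VoltagePattern",
    "InvalidGeometryError",
    "electrode_pitch",
    "electrode_span",
    "reflection_coefficient",
]


class InvalidGeometryError(ValueError):
    """Raised for non-physical channel or electrode-array descriptions."""


def electrode_pitch(width_L: float, n_electrodes: int) -> float:
    """Electrode pitch λ = L / (2N − 1).

    Electrode strips of width λ alternate with gaps of the same width, so
    N electrodes and N − 1 gaps tile ``[0, L]`` exactly.

    Parameters
    ----------
    width_L:
        Channel width L in metres.
    n_electrodes:
        Number of electrodes N on the array (≥ 1).
    """
    if width_L <= 0:
        raise InvalidGeometryError(f"channel width must be positive, got {width_L}")
    if n_electrodes < 1:
        raise InvalidGeometryError(f"need at least one electrode, got {n_electrodes}")
    return width_L / (2 * n_electrodes - 1)


@dataclass(frozen=True)
class ChannelGeometry:
    """Cross-section of the sorting channel and its two electrode arrays.

    Attributes
    ----------
    width_L, height_h:
        Channel width and height in metres.
    n_top, n_bottom:
        Electrode counts N⁺ (top wall) and N⁻ (bottom wall).  Each array
        needs at least two electrodes so that first, middle and last
        electrodes are distinct.
    """

    width_L: float
    height_h: float
    n_top: int
    n_bottom: int

    def __post_init__(self) -> None:
        if self.width_L <= 0 or self.height_h <= 0:
            raise InvalidGeometryError(
                f"channel dimensions must be positive, got L={self.width_L}, h={self.height_h}"
            )
        for name, n in (("n_top", self.n_top), ("n_bottom", self.n_bottom)):
            if int(n) != n or n < 2:
                raise InvalidGeometryError(f"{name} must be an integer >= 2, got {n}")

    @property
    def pitch_top(self) -> float:
        """Pitch λ⁺ of the top array (m)."""
        return electrode_pitch(self.width_L, self.n_top)

    @property
    def pitch_bottom(self) -> float:
        """Pitch λ⁻ of the bottom array (m)."""
        return electrode_pitch(self.width_L, self.n_bottom)

    def n_electrodes(self, which_array: str) -> int:
        if which_array == "top":
            return self.n_top
        if which_array == "bottom":
            return self.n_bottom
        raise ValueError(f"which_array must be 'top' or 'bottom', got {which_array!r}")


def electrode_span(
    geometry: ChannelGeometry, n: int, which_array: str = "bottom"
) -> tuple[float, float]:
    """y-interval ``[2nλ, (2n+1)λ]`` covered by electrode ``n``.

    Gaps occupy ``[(2n+1)λ, (2n+2)λ]``.  The last electrode's right edge is
    exactly ``L`` since (2N − 1)λ = L.
    """
    count = geometry.n_electrodes(which_array)
    if not 0 <= n <= count - 1:
        raise IndexError(f"electrode index {n} out of range for N={count}")
    lam = electrode_pitch(geometry.width_L, count)
    return (2 * n * lam, (2 * n + 1) * lam)


@dataclass(frozen=True)
class MediumProperties:
    """Suspending-medium dielectric properties (relative permittivity εm,
    conductivity σm in S/m) plus the channel-wall relative permittivity εw
    used to justify the mirror-symmetry lateral boundary condition."""

    rel_permittivity_em: float = 78.0
    conductivity_sm: float = 0.0
    wall_rel_permittivity_ew: float = 4.0

    def __post_init__(self) -> None:
        if self.rel_permittivity_em <= 0 or self.wall_rel_permittivity_ew <= 0:
            raise ValueError("relative permittivities must be positive")
        if self.conductivity_sm < 0:
            raise ValueError("conductivity must be non-negative")


def reflection_coefficient(medium: MediumProperties) -> float:
    """Dielectric reflection coefficient (εm − εw)/(εm + εw).

    A value close to 1 means the lateral channel walls act as near-perfect
    mirrors for the electric field, which is what licenses replacing the
    zero-flux wall condition by an even-symmetry condition on the
    potential.  For water (εm = 78) against SU-8 walls (εw = 4) it is 0.9.
    """
    denom = medium.rel_permittivity_em + medium.wall_rel_permittivity_ew
    if denom <= 0:
        raise ValueError("permittivity sum must be positive")
    return (medium.rel_permittivity_em - medium.wall_rel_permittivity_ew) / denom


@dataclass(frozen=True)
class ParticleProperties:
    """Spherical particle: radius (m), relative permittivity εp, conductivity σp (S/m)."""

    radius_r: float
    rel_permittivity_ep: float = 2.5
    conductivity_sp: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_r <= 0:
            raise ValueError("particle radius must be positive")
        if self.rel_permittivity_ep <= 0:
            raise ValueError("particle permittivity must be positive")
        if self.conductivity_sp < 0:
            raise ValueError("particle conductivity must be non-negative")


@dataclass(frozen=True)
class DriveCondition:
    """Electric drive: angular frequency υ (rad/s) of the applied field.

    ``cm_real_override`` short-circuits the Clausius–Mossotti computation
    with a prescribed real part Re(β) ∈ [−0.5, 1.0]; the common validation
    setting is Re(β) = −0.5 (strongly negative DEP).
    """

    angular_frequency_v: float | None = None
    cm_real_override: float | None = None

    def __post_init__(self) -> None:
        if self.cm_real_override is None:
            if self.angular_frequency_v is None or self.angular_frequency_v <= 0:
                raise ValueError(
                    "angular frequency must be positive when no Re(beta) override is given"
                )
        elif not -0.5 <= self.cm_real_override <= 1.0:
            raise ValueError(
                f"Re(beta) override must lie in [-0.5, 1.0], got {self.cm_real_override}"
            )


@dataclass(frozen=True)
class VoltagePattern:
    """Per-electrode voltages U for the top and bottom arrays (volts)."""

    u_top: tuple[float, ...]
    u_bottom: tuple[float, ...]

    def __init__(self, u_top: Sequence[float], u_bottom: Sequence[float]):
        ut = tuple(float(v) for v in u_top)
        ub = tuple(float(v) for v in u_bottom)
        if not all(math.isfinite(v) for v in ut + ub):
            raise ValueError("all voltages must be finite")
        object.__setattr__(self, "u_top", ut)
        object.__setattr__(self, "u_bottom", ub)

    def check_geometry(self, geometry: ChannelGeometry) -> None:
        if len(self.u_top) != geometry.n_top or len(self.u_bottom) != geometry.n_bottom:
            raise ValueError(
                f"voltage pattern ({len(self.u_top)} top, {len(self.u_bottom)} bottom) "
                f"does not match geometry (N+={geometry.n_top}, N-={geometry.n_bottom})"
            )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.u_top, dtype=float), np.asarray(self.u_bottom, dtype=float)
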