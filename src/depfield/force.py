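"""Dielectrophoretic force from the electric-field derivatives.

The time-averaged DEP force on a small spherical particle (dipole
approximation, radius much smaller than the field's length scale) is

    F_DEP = 2π ε0 εm r³ Re(β) ∇(∇φ)²,

with β the Clausius–Mossotti polarization factor comparing the complex
permittivities of particle and medium, ε* = ε − iσ/υ.  Since β is a ratio,
the relative (not absolute) permittivities are used and the common ε0
factor cancels; ε0 appears exactly once, in the force prefactor.
Re(β) < 0 (negative DEP) pushes particles toward field-intensity minima,
away from the electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import FieldSample, FourierModel, evaluate_field
from .geometry import DriveCondition, MediumProperties, ParticleProperties, VoltagePattern

__all__ = [
    "VACUUM_PERMITTIVITY",
    "PolarizationFactor",
    "ForceVector",
    "SingularPolarizationError",
    "clausius_mossotti",
    "grad_E2",
    "dep_force_prefactor",
    "dep_force",
    "force_field",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m


class SingularPolarizationError(ZeroDivisionError):
    """Raised when εp* + 2εm* vanishes and β is undefined."""


@dataclass(frozen=True)
class PolarizationFactor:
    """Clausius–Mossotti factor β (complex) and its real part.

    Re(β) is bounded: −0.5 (particle far less polarisable than the medium,
    e.g. the void limit εp* → 0) to 1.0 (far more polarisable).
    """

    beta: complex

    @property
    def re_beta(self) -> float:
        return float(self.beta.real)


@dataclass(frozen=True)
class ForceVector:
    """In-plane DEP force components (newtons)."""

    f_y: float
    f_z: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.f_y, self.f_z))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.f_z, self.f_y)))


def clausius_mossotti(
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
) -> PolarizationFactor:
    """Clausius–Mossotti factor β = (εp* − εm*)/(εp* + 2εm*).

    β is a ratio of complex permittivities ε* = ε − iσ/υ, so the common
    ε0 scale cancels; working with relative permittivities, the loss term
    becomes σ/(ε0 υ) (dividing the absolute ε* through by ε0).  The
    Maxwell–Wagner crossover frequency υ ≈ σ/(ε0 εr) is thereby preserved.
    If the drive carries a ``cm_real_override``, that value is used as a
    purely real β (the common validation shortcut Re(β) = −0.5).
    """
    if drive.cm_real_override is not None:
        return PolarizationFactor(beta=complex(drive.cm_real_override, 0.0))
    v = drive.angular_frequency_v
    scale = VACUUM_PERMITTIVITY * v
    eps_p = particle.rel_permittivity_ep - 1j * particle.conductivity_sp / scale
    eps_m = medium.rel_permittivity_em - 1j * medium.conductivity_sm / scale
    denom = eps_p + 2 * eps_m
    if abs(denom) == 0.0:
        raise SingularPolarizationError("eps_p* + 2 eps_m* vanishes; beta undefined")
    return PolarizationFactor(beta=(eps_p - eps_m) / denom)


def grad_E2(sample: FieldSample) -> np.ndarray:
    """Gradient of the squared field intensity, ∇(∇φ)² (V²/m³).

    Componentwise 2·(φ_yy φ_y + φ_yz φ_z, φ_yz φ_y + φ_zz φ_z).  Quadratic
    in the voltages; identically zero for a uniform field.
    """
    phi_y, phi_z = sample.d_phi
    phi_yy, phi_yz, phi_zz = sample.dd_phi
    return 2.0 * np.array(
        [phi_yy * phi_y + phi_yz * phi_z, phi_yz * phi_y + phi_zz * phi_z]
    )


def dep_force_prefactor(
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
) -> float:
    """Scalar prefactor 2π ε0 εm r³ Re(β) of the DEP force (N·m³/V²)."""
    beta = clausius_mossotti(particle, medium, drive)
    return (
        2.0
        * np.pi
        * VACUUM_PERMITTIVITY
        * medium.rel_permittivity_em
        * particle.radius_r**3
        * beta.re_beta
    )


def dep_force(
    y: float,
    z: float,
    model: FourierModel,
    voltages: VoltagePattern,
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
) -> ForceVector:
    """DEP force on a particle at (y, z) in the dual-array frame (newtons)."""
    from .fourier import field_sample

    sample = field_sample(y, z, model, voltages)
    pref = dep_force_prefactor(particle, medium, drive)
    g = grad_E2(sample)
    return ForceVector(f_y=float(pref * g[0]), f_z=float(pref * g[1]))


def force_field(
    model: FourierModel,
    voltages: VoltagePattern,
    y: np.ndarray,
    z: np.ndarray,
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised DEP force components over broadcastable position arrays."""
    f = evaluate_field(model, voltages, y, z, order=2)
    pref = dep_force_prefactor(particle, medium, drive)
    fy = 2.0 * pref * (f["yy"] * f["y"] + f["yz"] * f["z"])
    fz = 2.0 * pref * (f["yz"] * f["y"] + f["zz"] * f["z"])
    return fy, fz
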