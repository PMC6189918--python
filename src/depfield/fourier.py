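"""Fourier-series solution of the electric potential above electrode arrays.

The potential in the channel cross-section factors into three independent
pieces,

    φ(y, z, U) = te(y, z) · A · U,

where ``A`` is a geometry-only matrix of Fourier coefficients (a pure
function of the electrode count N, precomputable once per chip), ``U`` is
the vector of electrode voltages (the control input), and ``te(y, z)`` is a
vector of harmonic basis terms evaluated at the point of interest.  Because
the position enters only through ``te``, the potential and all its spatial
derivatives at a single point cost one short dot product — no whole-field
solve — which is what makes the model usable inside a real-time control
loop.

The boundary conditions encoded by ``A`` are the *approximated* ones:
prescribed voltages on the electrode strips, linear interpolation across
the gaps, even mirror symmetry at the lateral walls (the dielectric
reflection coefficient of a water/SU-8 interface is ≈ 0.9, close enough to
a perfect mirror), and a grounded plane at height ``h`` above the array.
The even 2L-periodic extension makes every harmonic a cosine, so the whole
computation is real.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import ChannelGeometry, VoltagePattern, electrode_pitch

__all__ = [
    "FourierModel",
    "FieldSample",
    "wavenumber",
    "fourier_coefficient",
    "build_coefficient_matrix",
    "boundary_potential",
    "z_profile",
    "basis_vector_single",
    "basis_vector_dual",
    "basis_derivatives",
    "potential_single",
    "potential",
    "field_sample",
    "evaluate_field",
]

# Arguments of the decaying exponentials stay non-positive in the sinh-ratio
# form, so the basis never overflows regardless of the truncation order.


def wavenumber(p: int, width_L: float) -> float:
    """Angular spatial frequency ωₚ = pπ/L of harmonic ``p`` (rad/m).

    The boundary potential is even and 2L-periodic, so its harmonics live
    on the half-integer grid π/L.  Odd in ``p``.
    """
    if width_L <= 0:
        raise ValueError(f"channel width must be positive, got {width_L}")
    return p * np.pi / width_L


def fourier_coefficient(p: int, n: int, n_electrodes: int) -> float:
    """Fourier coefficient a_{p,n} of the elementary potential of electrode n.

    These are the closed-form Fourier coefficients of the unit "tent"
    boundary profile of electrode ``n``: one on the strip, ramping linearly
    to zero across the adjacent gaps, evenly mirrored at the lateral walls.
    With γₚ = pπ/(2N−1):

    * p = 0: 3/2 · 1/(2N−1) for the first and last electrode, 2/(2N−1) for
      middle electrodes (the edge electrodes have only one adjacent gap in
      ``[0, L]`` but gain half a strip from the mirror image).
    * p ≠ 0, n = 0:      (2N−1)/(p²π²) · (cos γₚ − cos 2γₚ)
    * p ≠ 0, middle n:   (2N−1)/(p²π²) · (−cos(2n−1)γₚ + cos 2nγₚ
                                          + cos(2n+1)γₚ − cos(2n+2)γₚ)
    * p ≠ 0, n = N−1:    (−1)ᵖ × the n = 0 value (mirror image about L/2).

    All entries are even in ``p``.
    """
    N = n_electrodes
    if N < 2:
        raise ValueError(f"coefficient table requires N >= 2, got {N}")
    if not 0 <= n <= N - 1:
        raise IndexError(f"electrode index {n} out of range for N={N}")
    if p == 0:
        return (1.5 if n in (0, N - 1) else 2.0) / (2 * N - 1)
    gamma = p * np.pi / (2 * N - 1)
    scale = (2 * N - 1) / (p * p * np.pi**2)
    edge = scale * (np.cos(gamma) - np.cos(2 * gamma))
    if n == 0:
        return edge
    if n == N - 1:
        return (-1) ** p * edge
    return scale * (
        -np.cos((2 * n - 1) * gamma)
        + np.cos(2 * n * gamma)
        + np.cos((2 * n + 1) * gamma)
        - np.cos((2 * n + 2) * gamma)
    )


@lru_cache(maxsize=64)
def _coefficient_matrix_cached(n_electrodes: int, truncation_P: int) -> np.ndarray:
    N, P = n_electrodes, truncation_P
    p_idx = np.arange(-P, P + 1)
    A = np.empty((2 * P + 1, N))
    for i, p in enumerate(p_idx):
        for n in range(N):
            A[i, n] = fourier_coefficient(int(p), n, N)
    A.setflags(write=False)
    return A


def build_coefficient_matrix(n_electrodes: int, truncation_P: int) -> np.ndarray:
    """Geometry matrix A of shape (2P+1, N), rows ordered p = −P..P.

    Pure function of (N, P); cached, since for a given chip it is computed
    once and reused for every force evaluation.  Row p = 0 sums to 1 and
    every other row sums to 0 (constant boundary data is reconstructed
    exactly), and rows p and −p coincide.  The returned array is read-only.
    """
    if n_electrodes < 2:
        raise ValueError(f"model construction requires N >= 2, got {n_electrodes}")
    if truncation_P < 1:
        raise ValueError(f"truncation order must be >= 1, got {truncation_P}")
    return _coefficient_matrix_cached(int(n_electrodes), int(truncation_P))


def boundary_potential(
    y: np.ndarray | float,
    voltages: "np.ndarray | list[float] | tuple[float, ...]",
    geometry: ChannelGeometry,
    which_array: str = "bottom",
) -> np.ndarray | float:
    """Approximated boundary potential on the electrode plane.

    Piecewise profile: ``uₙ`` on electrode ``n``'s strip, linear
    interpolation across the gaps, extended to all ``y`` by even reflection
    at ``y = 0`` and ``y = L`` (period 2L).  Vectorised in ``y``.
    """
    u = np.asarray(voltages, dtype=float)
    N = geometry.n_electrodes(which_array)
    if u.shape != (N,):
        raise ValueError(f"expected {N} voltages, got shape {u.shape}")
    L = geometry.width_L
    lam = electrode_pitch(L, N)
    y_arr = np.asarray(y, dtype=float)
    scalar = y_arr.ndim == 0
    y_arr = np.atleast_1d(y_arr)
    # fold onto [0, L] using the even 2L-periodic extension
    yf = np.abs(np.mod(y_arr + L, 2 * L) - L)
    k = np.clip((yf // lam).astype(int), 0, 2 * N - 2)
    n = k // 2
    out = np.empty_like(yf)
    on_electrode = k % 2 == 0
    out[on_electrode] = u[n[on_electrode]]
    gap = ~on_electrode
    ng = n[gap]
    frac = (yf[gap] - (2 * ng + 1) * lam) / lam
    out[gap] = u[ng] + (u[ng + 1] - u[ng]) * frac
    return float(out[0]) if scalar else out


def _z_profile_blocks(
    w: np.ndarray, zeta: np.ndarray, h: float, order: int
) -> tuple[np.ndarray, ...]:
    """Vertical profiles Z, Z', Z'' for non-negative wavenumbers ``w``.

    ``zeta`` is the distance coordinate measured from the electrode plane
    (the array sits at ζ = 0, the grounded plane at ζ = h).  For w = 0 the
    profile is the linear ramp (h − ζ)/h; otherwise

        Z(ζ) = sinh(w (h − ζ)) / sinh(w h),

    evaluated as exp(−wζ)·(1 − e^{−2w(h−ζ)})/(1 − e^{−2wh}) so that every
    exponential argument is ≤ 0 and nothing overflows at high truncation
    orders.  Z(0) = 1, Z(h) = 0.  Z'' = w²Z, so each harmonic is exactly
    Laplace-harmonic.

    Returns (Z,) for order 0, (Z, Z') for order 1, (Z, Z', Z'') for order 2.
    Shapes broadcast as ``zeta[..., None] × w[None, :]`` → (..., n_w).
    """
    w = np.asarray(w, dtype=float)
    zeta = np.asarray(zeta, dtype=float)[..., None]
    wz = w * zeta  # (..., n_w)
    zero = w == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        e_den = -np.expm1(-2 * w * h)  # 1 - exp(-2wh)
        e_num = -np.expm1(-2 * w * (h - zeta))  # 1 - exp(-2w(h-zeta))
        c_num = 2 - e_num  # 1 + exp(-2w(h-zeta))
        decay = np.exp(-wz)
        Z = np.where(zero, (h - zeta) / h, decay * e_num / np.where(zero, 1.0, e_den))
    out = [Z]
    if order >= 1:
        dZ = np.where(zero, -1.0 / h, -w * decay * c_num / np.where(zero, 1.0, e_den))
        out.append(dZ)
    if order >= 2:
        ddZ = np.where(zero, 0.0, w * w * Z)
        out.append(ddZ)
    return tuple(out)


def z_profile(p: int, z: np.ndarray | float, height_h: float, width_L: float | None = None):
    """Vertical decay profile Z_p(z) of harmonic ``p`` in the single-array frame.

    ``width_L`` defaults to ``height_h`` only in the sense that ``p`` is
    interpreted through ωₚ = pπ/L; pass the channel width used by the model.
    """
    if width_L is None:
        raise TypeError("width_L is required to form the wavenumber")
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < -1e-15) or np.any(z_arr > height_h * (1 + 1e-12)):
        raise ValueError("z outside [0, h]")
    w = np.array([abs(wavenumber(p, width_L))])
    (Z,) = _z_profile_blocks(w, z_arr, height_h, order=0)
    res = Z[..., 0]
    return float(res) if np.ndim(z) == 0 else res


def _basis_blocks(y, zeta, L: float, h: float, P: int, order: int) -> dict[str, np.ndarray]:
    """Harmonic basis entries and derivatives w.r.t. (y, ζ) in one frame.

    Entry for harmonic p is cos(ωₚ y) · Z_p(ζ); since the coefficient rows
    are even in p this real cosine form reproduces the complex-exponential
    sum over p = −P..P exactly.  Keys: 'phi', and (order permitting) 'y',
    'z', 'yy', 'yz', 'zz'.  Output shape (..., 2P+1).
    """
    p_idx = np.arange(-P, P + 1)
    w = np.abs(p_idx) * np.pi / L
    y = np.asarray(y, dtype=float)[..., None]
    cos = np.cos(w * y)
    profs = _z_profile_blocks(w, zeta, h, order)
    Z = profs[0]
    out = {"phi": cos * Z}
    if order >= 1:
        sin = np.sin(w * y)
        dZ = profs[1]
        out["y"] = -w * sin * Z
        out["z"] = cos * dZ
    if order >= 2:
        ddZ = profs[2]
        out["yy"] = -w * w * cos * Z
        out["yz"] = -w * sin * dZ
        out["zz"] = cos * ddZ
    return out


def basis_vector_single(
    y: float, z: float, geometry: ChannelGeometry, truncation_P: int
) -> np.ndarray:
    """Position basis te(y, z) in the single-array frame (length 2P+1).

    The potential of a single bottom array is ``te · A · U`` with the
    grounded plane at z = h.  All entries vanish at z = h; the p = 0 entry
    is 1 on the electrode plane.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < -1e-15) or np.any(z_arr > geometry.height_h * (1 + 1e-12)):
        raise ValueError("point outside the single-array frame domain z in [0, h]")
    return _basis_blocks(y, z_arr, geometry.width_L, geometry.height_h, truncation_P, 0)["phi"]


def basis_vector_dual(
    y: float, z: float, geometry: ChannelGeometry, truncation_P: int
) -> np.ndarray:
    """Position basis in the dual-array frame (length 2(2P+1)).

    Concatenation of the top-array block (single-array basis at distance
    ζ = h/2 − z from the top plane) and the bottom-array block (ζ = h/2 + z).
    Each block's own electrode plane is its ζ = 0, the opposite wall its
    grounded plane; the p = 0 entries are the linear ramps 1/2 ± z/h.
    """
    h = geometry.height_h
    z_arr = np.asarray(z, dtype=float)
    if np.any(np.abs(z_arr) > h / 2 * (1 + 1e-12)):
        raise ValueError("point outside the dual-array frame domain z in [-h/2, h/2]")
    top = _basis_blocks(y, h / 2 - z_arr, geometry.width_L, h, truncation_P, 0)["phi"]
    bot = _basis_blocks(y, h / 2 + z_arr, geometry.width_L, h, truncation_P, 0)["phi"]
    return np.concatenate([top, bot], axis=-1)


def basis_derivatives(
    y: float,
    z: float,
    geometry: ChannelGeometry,
    truncation_P: int,
    order: int = 1,
    frame: str = "dual",
) -> dict[str, np.ndarray]:
    """Analytic derivatives of the basis vector with respect to (y, z).

    Returns a dict with keys 'phi', 'y', 'z' and, for ``order == 2``,
    'yy', 'yz', 'zz'.  In the dual frame the chain rule through
    ζ_top = h/2 − z flips the sign of every odd z-derivative of the top
    block.  Term by term, ∂²/∂y² = −ωₚ²·(entry) and ∂²/∂z² = +ωₚ²·(entry)
    for p ≠ 0, so harmonicity holds harmonic-by-harmonic.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    L, h = geometry.width_L, geometry.height_h
    if frame == "single":
        return _basis_blocks(y, np.asarray(z, dtype=float), L, h, truncation_P, order)
    if frame != "dual":
        raise ValueError(f"frame must be 'single' or 'dual', got {frame!r}")
    z_arr = np.asarray(z, dtype=float)
    top = _basis_blocks(y, h / 2 - z_arr, L, h, truncation_P, order)
    bot = _basis_blocks(y, h / 2 + z_arr, L, h, truncation_P, order)
    sign = {"phi": 1, "y": 1, "z": -1, "yy": 1, "yz": -1, "zz": 1}
    return {
        key: np.concatenate([sign[key] * top[key], bot[key]], axis=-1) for key in top
    }


@dataclass(frozen=True)
class FieldSample:
    """Potential and spatial derivatives at one point of the cross-section.

    ``d_phi`` is (∂φ/∂y, ∂φ/∂z) in V/m; ``dd_phi`` is (∂²φ/∂y², ∂²φ/∂y∂z,
    ∂²φ/∂z²) in V/m².  Interior samples satisfy the Laplace equation
    ∂²φ/∂y² + ∂²φ/∂z² = 0 up to truncation/discretisation error.
    """

    y: float
    z: float
    phi: float
    d_phi: tuple[float, float]
    dd_phi: tuple[float, float, float]


class FourierModel:
    """Precomputed analytical field model for a two-array chip.

    Holds the truncation order P, the harmonic wavenumbers, and the
    geometry matrices A⁺ (top array) and A⁻ (bottom array).  Construction
    is the only O(N·P) step; every subsequent field evaluation is a dot
    product with the position basis.

    Parameters
    ----------
    geometry:
        Channel cross-section; both arrays must have N ≥ 2 electrodes.
    truncation_P:
        Number of positive harmonics retained (the stored matrices have
        2P+1 rows for p = −P..P).  Defaults to 2·max(N⁺, N⁻): beyond that
        the force-orientation accuracy of the model plateaus.
    """

    def __init__(self, geometry: ChannelGeometry, truncation_P: int | None = None):
        self.geometry = geometry
        if truncation_P is None:
            truncation_P = 2 * max(geometry.n_top, geometry.n_bottom)
        if truncation_P < 1:
            raise ValueError(f"truncation order must be >= 1, got {truncation_P}")
        self.truncation_P = int(truncation_P)
        self.wavenumbers = (
            np.arange(-self.truncation_P, self.truncation_P + 1) * np.pi / geometry.width_L
        )
        self.coeff_top = build_coefficient_matrix(geometry.n_top, self.truncation_P)
        self.coeff_bottom = build_coefficient_matrix(geometry.n_bottom, self.truncation_P)

    def __repr__(self) -> str:  # pragma: no cover
        g = self.geometry
        return (
            f"FourierModel(L={g.width_L:.3g} m, h={g.height_h:.3g} m, "
            f"N+={g.n_top}, N-={g.n_bottom}, P={self.truncation_P})"
        )

    def _weights(self, voltages: VoltagePattern) -> tuple[np.ndarray, np.ndarray]:
        voltages.check_geometry(self.geometry)
        u_top, u_bottom = voltages.as_arrays()
        return self.coeff_top @ u_top, self.coeff_bottom @ u_bottom


def evaluate_field(
    model: FourierModel,
    voltages: VoltagePattern,
    y: np.ndarray | float,
    z: np.ndarray | float,
    order: int = 2,
) -> dict[str, np.ndarray]:
    """Vectorised field evaluation in the dual-array frame.

    Returns a dict of arrays broadcast over ``y``/``z`` with keys 'phi' and
    (per ``order``) 'y', 'z', 'yy', 'yz', 'zz'.  Linear in the voltages.
    """
    g = model.geometry
    y_arr, z_arr = np.broadcast_arrays(
        np.asarray(y, dtype=float), np.asarray(z, dtype=float)
    )
    if np.any(np.abs(z_arr) > g.height_h / 2 * (1 + 1e-12)):
        raise ValueError("z outside the dual-array frame domain [-h/2, h/2]")
    b_top, b_bot = model._weights(voltages)
    h = g.height_h
    top = _basis_blocks(y_arr, h / 2 - z_arr, g.width_L, h, model.truncation_P, order)
    bot = _basis_blocks(y_arr, h / 2 + z_arr, g.width_L, h, model.truncation_P, order)
    sign = {"phi": 1, "y": 1, "z": -1, "yy": 1, "yz": -1, "zz": 1}
    return {
        key: sign[key] * (top[key] @ b_top) + bot[key] @ b_bot for key in top
    }


def potential(
    y: np.ndarray | float,
    z: np.ndarray | float,
    model: FourierModel,
    voltages: VoltagePattern,
) -> np.ndarray | float:
    """Electric potential φ(y, z, U) of the two-array chip (volts)."""
    res = evaluate_field(model, voltages, y, z, order=0)["phi"]
    return float(res) if np.ndim(res) == 0 else res


def field_sample(
    y: float, z: float, model: FourierModel, voltages: VoltagePattern
) -> FieldSample:
    """Potential plus first and second derivatives at a single point."""
    f = evaluate_field(model, voltages, y, z, order=2)
    return FieldSample(
        y=float(y),
        z=float(z),
        phi=float(f["phi"]),
        d_phi=(float(f["y"]), float(f["z"])),
        dd_phi=(float(f["yy"]), float(f["yz"]), float(f["zz"])),
    )


def potential_single(
    y: np.ndarray | float,
    z: np.ndarray | float,
    geometry: ChannelGeometry,
    voltages_bottom: "np.ndarray | list[float] | tuple[float, ...]",
    truncation_P: int,
    order: int = 0,
):
    """Potential of the bottom array alone in the single-array frame.

    ``z ∈ [0, h]`` with electrodes at z = 0 and a grounded plane at z = h.
    With ``order > 0`` returns the dict of derivative arrays instead.
    """
    u = np.asarray(voltages_bottom, dtype=float)
    A = build_coefficient_matrix(geometry.n_bottom, truncation_P)
    b = A @ u
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < -1e-15) or np.any(z_arr > geometry.height_h * (1 + 1e-12)):
        raise ValueError("z outside [0, h]")
    blocks = _basis_blocks(
        np.asarray(y, dtype=float), z_arr, geometry.width_L, geometry.height_h,
        truncation_P, order,
    )
    if order == 0:
        res = blocks["phi"] @ b
        return float(res) if np.ndim(res) == 0 else res
    return {key: val @ b for key, val in blocks.items()}


def _potential_single_complex(
    y: float,
    z: float,
    geometry: ChannelGeometry,
    voltages_bottom,
    truncation_P: int,
) -> complex:
    """Reference complex-exponential evaluation (testing only).

    Sums a_{p,n} e^{iωₚy} Z_p(z) over p = −P..P literally; the production
    cosine path must match its real part and the imaginary part must
    vanish to rounding.
    """
    u = np.asarray(voltages_bottom, dtype=float)
    A = build_coefficient_matrix(geometry.n_bottom, truncation_P)
    b = A @ u
    L, h = geometry.width_L, geometry.height_h
    total = 0.0 + 0.0j
    for i, p in enumerate(range(-truncation_P, truncation_P + 1)):
        w = p * np.pi / L
        if p == 0:
            Zp = (h - z) / h
        else:
            aw = abs(w)
            Zp = np.sinh(aw * (h - z)) / np.sinh(aw * h)
        total += b[i] * np.exp(1j * w * y) * Zp
    return total
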