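"""Finite-difference oracle for the exact boundary-value problem.

The analytical Fourier model rests on two approximations: linear potential
across the inter-electrode gaps and mirror symmetry at the lateral walls.
This module solves the *exact* electrostatic problem instead — Dirichlet
voltages on the electrode strips, zero normal flux (no charge
accumulation) on the gaps and on the lateral walls — with a second-order
five-point finite-difference scheme, and serves as the independent
numerical reference the analytical model is validated against.

Discretisation notes:

* Neumann boundaries are imposed with mirror ghost nodes, keeping the
  scheme second order up to the walls.
* Electrode edges that fall between grid nodes snap to the nearest node;
  the default 0.5 µm spacing makes 10 µm features exact multiples.  A node
  exactly on an electrode edge counts as electrode (Dirichlet wins).
* The system matrix depends only on the geometry, spacing and boundary
  layout — not on the voltage values — so it is LU-factorised once and
  re-used across voltage patterns (the validation studies solve the same
  chip for hundreds of patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import splu

from .fourier import FieldSample, boundary_potential
from .geometry import ChannelGeometry, VoltagePattern, electrode_pitch

__all__ = [
    "ReferenceSolution",
    "LaplaceSolver",
    "solve_laplace_fd",
    "reference_field_sample",
    "reference_field_arrays",
]


def _electrode_node_map(n_nodes: int, spacing: float, L: float, N: int) -> np.ndarray:
    """Map each boundary node to an electrode index, or −1 for gap nodes."""
    lam = electrode_pitch(L, N)
    owner = np.full(n_nodes, -1, dtype=int)
    for n in range(N):
        j0 = int(round(2 * n * lam / spacing))
        j1 = int(round((2 * n + 1) * lam / spacing))
        owner[j0 : j1 + 1] = n
    return owner


@dataclass
class ReferenceSolution:
    """Gridded numerical solution of the exact boundary-value problem.

    ``grid_phi`` has shape (nz, ny) over the dual-frame axes ``z_axis``
    (from −h/2 to +h/2) and ``y_axis`` (0 to L).  Derivative grids are
    computed lazily by central differences and cached.
    """

    grid_spacing: float
    y_axis: np.ndarray
    z_axis: np.ndarray
    grid_phi: np.ndarray
    geometry: ChannelGeometry
    voltages: VoltagePattern
    frame: str = "dual"
    _derivs: dict = field(default_factory=dict, repr=False)

    def derivative_grids(self) -> dict[str, np.ndarray]:
        """Central-difference first and second derivative grids of φ."""
        if not self._derivs:
            d = self.grid_spacing
            phi = self.grid_phi
            phi_y = np.gradient(phi, d, axis=1)
            phi_z = np.gradient(phi, d, axis=0)
            phi_yy = np.empty_like(phi)
            phi_yy[:, 1:-1] = (phi[:, 2:] - 2 * phi[:, 1:-1] + phi[:, :-2]) / d**2
            phi_yy[:, 0], phi_yy[:, -1] = phi_yy[:, 1], phi_yy[:, -2]
            phi_zz = np.empty_like(phi)
            phi_zz[1:-1, :] = (phi[2:, :] - 2 * phi[1:-1, :] + phi[:-2, :]) / d**2
            phi_zz[0, :], phi_zz[-1, :] = phi_zz[1, :], phi_zz[-2, :]
            phi_yz = np.gradient(phi_y, d, axis=0)
            self._derivs = {
                "phi": phi,
                "y": phi_y,
                "z": phi_z,
                "yy": phi_yy,
                "yz": phi_yz,
                "zz": phi_zz,
            }
        return self._derivs


class LaplaceSolver:
    """Reusable five-point Laplace solver for one chip at one spacing.

    Parameters
    ----------
    geometry:
        Channel cross-section.
    spacing:
        Grid spacing in metres (default 0.5 µm; must resolve the electrode
        pitch, i.e. be no coarser than 1 µm for 10 µm features).
    frame:
        ``"dual"`` — electrodes plus Neumann gaps on both walls (the full
        chip); ``"single"`` — bottom array only, the entire top wall held
        at ground (the configuration whose analytical solution is the
        single-array Fourier series).
    gap_bc:
        ``"neumann"`` — zero normal flux on the gaps (the exact, default
        condition); ``"linear"`` — Dirichlet linear interpolation across
        the gaps (the analytical model's approximated boundary, useful for
        convergence self-tests).
    """

    def __init__(
        self,
        geometry: ChannelGeometry,
        spacing: float = 0.5e-6,
        frame: str = "dual",
        gap_bc: str = "neumann",
    ):
        if spacing <= 0 or spacing > 1.0e-6:
            raise ValueError(f"spacing must be in (0, 1 um], got {spacing}")
        if frame not in ("dual", "single"):
            raise ValueError(f"frame must be 'dual' or 'single', got {frame!r}")
        if gap_bc not in ("neumann", "linear"):
            raise ValueError(f"gap_bc must be 'neumann' or 'linear', got {gap_bc!r}")
        self.geometry = geometry
        self.frame = frame
        self.gap_bc = gap_bc
        L, h = geometry.width_L, geometry.height_h
        self.ny = int(round(L / spacing)) + 1
        self.nz = int(round(h / spacing)) + 1
        # the 5-point stencil assumes one isotropic spacing, so it must
        # divide both channel dimensions essentially exactly
        if abs((self.ny - 1) * spacing - L) > 1e-9 * L or abs(
            (self.nz - 1) * spacing - h
        ) > 1e-9 * h:
            raise ValueError(
                f"spacing {spacing} must divide both L={L} and h={h} exactly"
            )
        self.spacing = spacing
        self.y_axis = np.linspace(0.0, L, self.ny)
        if frame == "dual":
            self.z_axis = np.linspace(-h / 2, h / 2, self.nz)
        else:
            self.z_axis = np.linspace(0.0, h, self.nz)
        self._bottom_owner = _electrode_node_map(self.ny, spacing, L, geometry.n_bottom)
        self._top_owner = _electrode_node_map(self.ny, spacing, L, geometry.n_top)
        self._build()

    # -- assembly ---------------------------------------------------------

    def _dirichlet_mask(self) -> np.ndarray:
        """(nz, ny) boolean mask of nodes with prescribed potential."""
        mask = np.zeros((self.nz, self.ny), dtype=bool)
        if self.gap_bc == "linear":
            mask[0, :] = True
            mask[-1, :] = True
            return mask
        mask[0, :] = self._bottom_owner >= 0
        if self.frame == "dual":
            mask[-1, :] = self._top_owner >= 0
        else:
            mask[-1, :] = True
        return mask

    def _build(self) -> None:
        nz, ny = self.nz, self.ny
        n_nodes = nz * ny
        dirichlet = self._dirichlet_mask()
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def idx(iz: int, iy: int) -> int:
            return iz * ny + iy

        for iz in range(nz):
            for iy in range(ny):
                k = idx(iz, iy)
                if dirichlet[iz, iy]:
                    rows.append(k)
                    cols.append(k)
                    vals.append(1.0)
                    continue
                # mirror ghost nodes across Neumann boundaries
                neighbours = [
                    (iz, iy - 1 if iy > 0 else iy + 1),
                    (iz, iy + 1 if iy < ny - 1 else iy - 1),
                    (iz - 1 if iz > 0 else iz + 1, iy),
                    (iz + 1 if iz < nz - 1 else iz - 1, iy),
                ]
                rows.append(k)
                cols.append(k)
                vals.append(-4.0)
                for jz, jy in neighbours:
                    rows.append(k)
                    cols.append(idx(jz, jy))
                    vals.append(1.0)
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsc()
        self._dirichlet = dirichlet
        self._lu = splu(A)

    def _boundary_values(self, voltages: VoltagePattern) -> tuple[np.ndarray, np.ndarray]:
        """Prescribed potentials on the bottom and top boundary rows."""
        u_top, u_bottom = voltages.as_arrays()
        g = self.geometry
        if self.gap_bc == "linear":
            bottom = boundary_potential(self.y_axis, u_bottom, g, "bottom")
            if self.frame == "dual":
                top = boundary_potential(self.y_axis, u_top, g, "top")
            else:
                top = np.zeros(self.ny)
            return np.asarray(bottom), np.asarray(top)
        bottom = np.zeros(self.ny)
        sel = self._bottom_owner >= 0
        bottom[sel] = u_bottom[self._bottom_owner[sel]]
        top = np.zeros(self.ny)
        if self.frame == "dual":
            sel = self._top_owner >= 0
            top[sel] = u_top[self._top_owner[sel]]
        return bottom, top

    # -- solving ----------------------------------------------------------

    def solve(self, voltages: VoltagePattern) -> ReferenceSolution:
        """Solve for one voltage pattern, re-using the cached factorisation."""
        voltages.check_geometry(self.geometry)
        bottom, top = self._boundary_values(voltages)
        rhs = np.zeros(self.nz * self.ny)
        dir_bottom = self._dirichlet[0, :]
        dir_top = self._dirichlet[-1, :]
        rhs[: self.ny][dir_bottom] = bottom[dir_bottom]
        rhs[(self.nz - 1) * self.ny :][dir_top] = top[dir_top]
        phi = self._lu.solve(rhs).reshape(self.nz, self.ny)
        max_u = max(np.max(np.abs(np.concatenate(voltages.as_arrays()))), 1.0)
        residual = self._interior_residual(phi)
        if residual > 1e-10 * max_u:
            raise RuntimeError(
                f"Laplace solve failed: interior residual {residual:.3e} "
                f"exceeds 1e-10 x max|u| = {1e-10 * max_u:.3e}"
            )
        return ReferenceSolution(
            grid_spacing=self.spacing,
            y_axis=self.y_axis,
            z_axis=self.z_axis,
            grid_phi=phi,
            geometry=self.geometry,
            voltages=voltages,
            frame=self.frame,
        )

    def _interior_residual(self, phi: np.ndarray) -> float:
        lap = (
            phi[1:-1, 2:] + phi[1:-1, :-2] + phi[2:, 1:-1] + phi[:-2, 1:-1]
            - 4 * phi[1:-1, 1:-1]
        )
        return float(np.max(np.abs(lap)))


def solve_laplace_fd(
    geometry: ChannelGeometry,
    voltages: VoltagePattern,
    spacing: float = 0.5e-6,
    frame: str = "dual",
    gap_bc: str = "neumann",
) -> ReferenceSolution:
    """One-shot solve of the exact boundary-value problem.

    Convenience wrapper over :class:`LaplaceSolver`; build the solver
    directly when solving the same chip for many voltage patterns.
    """
    return LaplaceSolver(geometry, spacing, frame=frame, gap_bc=gap_bc).solve(voltages)


def _check_interior(sol: ReferenceSolution, y: np.ndarray, z: np.ndarray) -> None:
    d = sol.grid_spacing
    if (
        np.any(y < sol.y_axis[0] + 2 * d - 1e-15)
        or np.any(y > sol.y_axis[-1] - 2 * d + 1e-15)
        or np.any(z < sol.z_axis[0] + 2 * d - 1e-15)
        or np.any(z > sol.z_axis[-1] - 2 * d + 1e-15)
    ):
        raise ValueError("sample point closer than 2 cells to a boundary")


def reference_field_arrays(
    sol: ReferenceSolution, y: np.ndarray, z: np.ndarray
) -> dict[str, np.ndarray]:
    """Bilinear interpolation of φ and its difference-derivative grids.

    Points must be at least two cells away from every boundary so the
    central-difference stencils underneath are trustworthy.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_interior(sol, y, z)
    grids = sol.derivative_grids()
    yb, zb = np.broadcast_arrays(y, z)
    pts = np.stack([zb.ravel(), yb.ravel()], axis=-1)
    out = {}
    for key, grid in grids.items():
        interp = RegularGridInterpolator((sol.z_axis, sol.y_axis), grid, method="linear")
        out[key] = interp(pts).reshape(yb.shape)
    return out


def reference_field_sample(sol: ReferenceSolution, y: float, z: float) -> FieldSample:
    """FieldSample from the numerical reference, usable by the force formula."""
    f = reference_field_arrays(sol, np.asarray(y), np.asarray(z))
    return FieldSample(
        y=float(y),
        z=float(z),
        phi=float(f["phi"]),
        d_phi=(float(f["y"]), float(f["z"])),
        dd_phi=(float(f["yy"]), float(f["yz"]), float(f["zz"])),
    )
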