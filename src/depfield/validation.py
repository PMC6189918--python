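"""Validation studies: analytical model versus the numerical reference.

Four studies mirror how such an analytical field model is qualified
against a full numerical solution:

* :func:`boundary_convergence_study` — how fast the truncated series
  approaches the (approximated) boundary potential as the truncation order
  P grows.
* :func:`error_maps` — pointwise force-magnitude, component and
  orientation errors over a region of interest (ROI) in the channel
  centre, against the exact-boundary finite-difference solution.
* :func:`orientation_error_study` / :func:`orientation_error_table` — the
  mean RMS force-orientation discrepancy over many random voltage
  patterns, as a function of the electrode count N and truncation P.
* :func:`height_scan` — the ‖F‖ ∝ h⁻³ power law when the cross-section is
  scaled uniformly (h/L fixed).

The ROI defaults to the central half of the channel in both axes
(y ∈ [L/4, 3L/4], z ∈ [−h/4, +h/4] in the dual frame): near the
electrodes the linear-gap approximation degrades and the dipole force
formula itself stops being valid, and negative-DEP particles do not go
there anyway.

Two orientation statistics coexist, because they answer different
questions:

* The pointwise error maps use quadrant-aware ``arctan2`` angles with the
  difference wrapped to (−180°, 180°] — the faithful geometric error of
  the force direction.
* The aggregate orientation studies default to the arctangent of the
  component ratio F_z/F_y, confined to (−90°, 90°).  Under this
  convention a force that is nearly vertical registers a near-180°
  discrepancy whenever the two models disagree on the tiny lateral
  component's sign, so the RMS is dominated by isolated outliers along
  the F_y ≈ 0 bands and sits far above the typical pointwise error.
  This is the convention under which the published electrode-array
  orientation benchmarks (tens of degrees for an otherwise
  few-degree-accurate model) were computed, so it is what a replication
  must use; pass ``statistic="atan2"`` for the geometric alternative.

Points where the reference force is below a 1e−20 N floor are excluded
from relative-magnitude and orientation statistics (the angle of a null
vector is meaningless and the relative error diverges) but kept in
absolute-error statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .force import dep_force_prefactor, force_field
from .fourier import (
    FourierModel,
    boundary_potential,
    build_coefficient_matrix,
    evaluate_field,
)
from .geometry import (
    ChannelGeometry,
    DriveCondition,
    MediumProperties,
    ParticleProperties,
    VoltagePattern,
)
from .reference import LaplaceSolver, ReferenceSolution, reference_field_arrays

__all__ = [
    "ROISpec",
    "ErrorSummary",
    "ZERO_FORCE_FLOOR",
    "random_voltage_patterns",
    "boundary_convergence_study",
    "error_maps",
    "orientation_error_study",
    "orientation_error_table",
    "height_scan",
    "wrap_angle_deg",
]

ZERO_FORCE_FLOOR = 1e-20  # N; below this the reference force is treated as null


@dataclass(frozen=True)
class ROISpec:
    """Region of interest as fractions of the channel dimensions.

    ``y_range`` is a fraction of [0, L] (both ends strictly inside (0, 1));
    ``z_range`` is a fraction of the height in the dual frame (strictly
    inside (−1/2, 1/2)).
    """

    y_range: tuple[float, float] = (0.25, 0.75)
    z_range: tuple[float, float] = (-0.25, 0.25)

    def __post_init__(self) -> None:
        y0, y1 = self.y_range
        z0, z1 = self.z_range
        if not (0.0 < y0 < y1 < 1.0):
            raise ValueError(f"y_range must be strictly inside (0, 1), got {self.y_range}")
        if not (-0.5 < z0 < z1 < 0.5):
            raise ValueError(
                f"z_range must be strictly inside (-1/2, 1/2), got {self.z_range}"
            )

    def grid_on_solution(
        self, sol: ReferenceSolution, grid_step: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """ROI grid snapped to reference-solution nodes (meshgrid arrays).

        Snapping removes interpolation error from the comparison: both
        force fields are evaluated exactly on finite-difference nodes.
        """
        L = sol.geometry.width_L
        h = sol.geometry.height_h
        stride = max(1, int(round(grid_step / sol.grid_spacing)))
        ysel = np.where(
            (sol.y_axis >= self.y_range[0] * L) & (sol.y_axis <= self.y_range[1] * L)
        )[0][::stride]
        zsel = np.where(
            (sol.z_axis >= self.z_range[0] * h) & (sol.z_axis <= self.z_range[1] * h)
        )[0][::stride]
        return np.meshgrid(sol.y_axis[ysel], sol.z_axis[zsel])


DEFAULT_ROI = ROISpec()


@dataclass
class ErrorSummary:
    """Per-point error grids plus summary statistics of one comparison.

    Relative magnitude errors are percentages of the reference magnitude;
    component errors are newtons; orientation errors are degrees wrapped
    to (−180°, 180°].  ``valid`` flags points above the zero-force floor.
    """

    y: np.ndarray
    z: np.ndarray
    rel_mag_error: np.ndarray
    abs_error_y: np.ndarray
    abs_error_z: np.ndarray
    orientation_error: np.ndarray
    valid: np.ndarray

    @property
    def median_rel_mag_error(self) -> float:
        """Median |ΔF|/|F_ref| over valid points (%)."""
        return float(np.median(self.rel_mag_error[self.valid]))

    @property
    def median_abs_orientation_error(self) -> float:
        """Median |Δθ| over valid points (degrees)."""
        return float(np.median(np.abs(self.orientation_error[self.valid])))

    @property
    def rms_orientation_error(self) -> float:
        """RMS of wrapped Δθ over valid points (degrees)."""
        return float(np.sqrt(np.mean(self.orientation_error[self.valid] ** 2)))

    def quantiles_rel_mag(self, q=(0.25, 0.5, 0.75)) -> np.ndarray:
        return np.quantile(self.rel_mag_error[self.valid], q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y": self.y.ravel(),
                "z": self.z.ravel(),
                "rel_mag_error_pct": self.rel_mag_error.ravel(),
                "abs_error_y_N": self.abs_error_y.ravel(),
                "abs_error_z_N": self.abs_error_z.ravel(),
                "orientation_error_deg": self.orientation_error.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def wrap_angle_deg(angle: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (−180°, 180°]."""
    return -(-(np.asarray(angle) + 180.0) % 360.0 - 180.0)


def random_voltage_patterns(
    n_draws: int,
    geometry: ChannelGeometry,
    amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> list[VoltagePattern]:
    """Independent uniform voltage draws on [−amplitude, +amplitude].

    Emulates the validation protocol of applying arbitrary per-electrode
    potentials.  Orientation and relative-error metrics are invariant to
    the amplitude (force direction is unchanged under U → cU), so only the
    distribution shape matters; uniform is the least-informative choice.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [
        VoltagePattern(
            u_top=rng.uniform(-amplitude, amplitude, geometry.n_top),
            u_bottom=rng.uniform(-amplitude, amplitude, geometry.n_bottom),
        )
        for _ in range(n_draws)
    ]


def boundary_convergence_study(
    geometry: ChannelGeometry,
    voltages: VoltagePattern,
    P_list: "list[int] | tuple[int, ...]",
    n_points: int = 2001,
) -> pd.DataFrame:
    """Relative RMS error of the truncated series on the electrode plane.

    For each truncation order P, the bottom-array series evaluated at
    z = 0 of the single-array frame is compared with the piecewise-linear
    boundary potential on ``n_points`` uniformly spaced y positions.
    Because truncation is an L² projection, the error is non-increasing
    in P, and it vanishes for constant voltage patterns at any P (row-sum
    identity).  Returns a DataFrame with columns ``P`` and
    ``rel_rms_error_pct``.
    """
    if list(P_list) != sorted(P_list) or min(P_list) < 1:
        raise ValueError("P_list must be positive and increasing")
    u = np.asarray(voltages.u_bottom, dtype=float)
    y = np.linspace(0.0, geometry.width_L, n_points)
    target = boundary_potential(y, u, geometry, "bottom")
    scale = np.sqrt(np.mean(np.asarray(target) ** 2))
    rows = []
    for P in P_list:
        A = build_coefficient_matrix(geometry.n_bottom, int(P))
        b = A @ u
        w = np.abs(np.arange(-P, P + 1)) * np.pi / geometry.width_L
        series = np.cos(np.asarray(y)[:, None] * w) @ b
        err = np.sqrt(np.mean((series - target) ** 2))
        rows.append({"P": int(P), "rel_rms_error_pct": 100.0 * err / scale})
    return pd.DataFrame(rows)


def _angles_deg(fy: np.ndarray, fz: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(fz, fy))


def error_maps(
    geometry: ChannelGeometry,
    voltages: VoltagePattern,
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
    truncation_P: int | None = None,
    roi: ROISpec = DEFAULT_ROI,
    grid_step: float = 2.0e-6,
    spacing: float = 0.5e-6,
    solver: LaplaceSolver | None = None,
    reference: ReferenceSolution | None = None,
) -> ErrorSummary:
    """Pointwise force-error maps over the ROI against the FD reference.

    Pass a prebuilt ``solver`` (or ``reference`` solution) to amortise the
    factorisation over many voltage patterns.
    """
    if reference is None:
        if solver is None:
            solver = LaplaceSolver(geometry, spacing)
        reference = solver.solve(voltages)
    model = FourierModel(geometry, truncation_P)
    Y, Z = roi.grid_on_solution(reference, grid_step)
    fy_a, fz_a = force_field(model, voltages, Y, Z, particle, medium, drive)
    ref = reference_field_arrays(reference, Y, Z)
    pref = dep_force_prefactor(particle, medium, drive)
    fy_r = 2.0 * pref * (ref["yy"] * ref["y"] + ref["yz"] * ref["z"])
    fz_r = 2.0 * pref * (ref["yz"] * ref["y"] + ref["zz"] * ref["z"])
    mag_r = np.hypot(fy_r, fz_r)
    mag_d = np.hypot(fy_a - fy_r, fz_a - fz_r)
    valid = mag_r > ZERO_FORCE_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(valid, 100.0 * mag_d / np.where(valid, mag_r, 1.0), np.nan)
    dtheta = wrap_angle_deg(_angles_deg(fy_a, fz_a) - _angles_deg(fy_r, fz_r))
    return ErrorSummary(
        y=Y,
        z=Z,
        rel_mag_error=rel,
        abs_error_y=fy_a - fy_r,
        abs_error_z=fz_a - fz_r,
        orientation_error=np.where(valid, dtheta, np.nan),
        valid=valid,
    )


def _orientation_rms_per_draw(
    solver: LaplaceSolver,
    models: dict[int, FourierModel],
    draws: list[VoltagePattern],
    roi: ROISpec,
    grid_step: float,
    statistic: str = "ratio_atan",
) -> dict[int, list[float]]:
    """RMS orientation difference per draw, for several truncation orders.

    The FD solution (and its force angles) is computed once per draw and
    shared across the truncation orders; only the cheap analytical side is
    re-evaluated.  Orientation is voltage-scale-free, so no physical force
    prefactor is needed — the angle of ∇(∇φ)² is used directly.

    ``statistic`` selects the angle convention: ``"ratio_atan"`` takes
    arctan(F_z/F_y) per point (differences bounded by 180° and dominated
    by sign flips of small F_y); ``"atan2"`` takes the full-quadrant angle
    with the difference wrapped to (−180°, 180°].
    """
    if statistic not in ("ratio_atan", "atan2"):
        raise ValueError(f"unknown orientation statistic {statistic!r}")
    out: dict[int, list[float]] = {P: [] for P in models}
    grid = None
    for voltages in draws:
        sol = solver.solve(voltages)
        if grid is None:
            grid = roi.grid_on_solution(sol, grid_step)
        Y, Z = grid
        ref = reference_field_arrays(sol, Y, Z)
        gy_r = ref["yy"] * ref["y"] + ref["yz"] * ref["z"]
        gz_r = ref["yz"] * ref["y"] + ref["zz"] * ref["z"]
        valid = np.hypot(gy_r, gz_r) > 0.0
        for P, model in models.items():
            fld = evaluate_field(model, voltages, Y, Z, order=2)
            gy_a = fld["yy"] * fld["y"] + fld["yz"] * fld["z"]
            gz_a = fld["yz"] * fld["y"] + fld["zz"] * fld["z"]
            if statistic == "ratio_atan":
                with np.errstate(divide="ignore", invalid="ignore"):
                    dtheta = np.degrees(np.arctan(gz_a / gy_a)) - np.degrees(
                        np.arctan(gz_r / gy_r)
                    )
            else:
                dtheta = wrap_angle_deg(
                    _angles_deg(gy_a, gz_a) - _angles_deg(gy_r, gz_r)
                )
            out[P].append(float(np.sqrt(np.mean(dtheta[valid] ** 2))))
    return out


def orientation_error_study(
    n_electrodes: int,
    truncation_P: int,
    n_draws: int = 50,
    roi: ROISpec = DEFAULT_ROI,
    seed: int = 0,
    width_L: float = 150e-6,
    height_h: float = 80e-6,
    spacing: float = 0.5e-6,
    grid_step: float = 2.0e-6,
    amplitude: float = 1.0,
    solver: LaplaceSolver | None = None,
    statistic: str = "ratio_atan",
) -> float:
    """Mean over draws of the RMS force-orientation difference (degrees).

    For each random voltage pattern the exact boundary-value problem is
    solved numerically, force orientations are compared with the
    analytical model on the ROI grid, the per-point angle differences are
    RMS-averaged over the grid, and the per-draw RMS values are averaged.
    The statistic decreases as P grows from N to 2N and plateaus beyond.
    See the module docstring for the two angle conventions.
    """
    geometry = ChannelGeometry(width_L, height_h, n_electrodes, n_electrodes)
    if solver is None:
        solver = LaplaceSolver(geometry, spacing)
    draws = random_voltage_patterns(n_draws, geometry, amplitude, seed)
    models = {truncation_P: FourierModel(geometry, truncation_P)}
    per_draw = _orientation_rms_per_draw(
        solver, models, draws, roi, grid_step, statistic
    )
    return float(np.mean(per_draw[truncation_P]))


def orientation_error_table(
    n_values: "tuple[int, ...]" = (5, 9, 15),
    p_multipliers: "tuple[int, ...]" = (1, 2, 4),
    n_draws: int = 50,
    roi: ROISpec = DEFAULT_ROI,
    seed: int = 0,
    width_L: float = 150e-6,
    height_h: float = 80e-6,
    spacing: float = 0.5e-6,
    grid_step: float = 2.0e-6,
    statistic: str = "ratio_atan",
) -> pd.DataFrame:
    """Orientation-error table over electrode counts and truncation orders.

    Rows are truncation multipliers (P = k·N), columns electrode counts;
    entries are the mean RMS orientation difference in degrees.  One FD
    solve per (N, draw) is shared across all P values.
    """
    data: dict[int, dict[int, float]] = {}
    for N in n_values:
        geometry = ChannelGeometry(width_L, height_h, N, N)
        solver = LaplaceSolver(geometry, spacing)
        draws = random_voltage_patterns(n_draws, geometry, 1.0, seed)
        models = {k * N: FourierModel(geometry, k * N) for k in p_multipliers}
        per_draw = _orientation_rms_per_draw(
            solver, models, draws, roi, grid_step, statistic
        )
        data[N] = {k: float(np.mean(per_draw[k * N])) for k in p_multipliers}
    table = pd.DataFrame(
        {N: [data[N][k] for k in p_multipliers] for N in n_values},
        index=[f"P={k}N" for k in p_multipliers],
    )
    table.index.name = "truncation"
    return table


def height_scan(
    geometry_template: ChannelGeometry,
    heights: np.ndarray,
    voltages: VoltagePattern,
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
    truncation_P: int | None = None,
    n_points: int = 201,
) -> tuple[pd.DataFrame, float]:
    """Mean force magnitude versus channel height at fixed aspect ratio.

    For each height ``h`` the whole cross-section is scaled uniformly
    (L = h, per the template's aspect ratio of 1) and the mean ‖F‖ is
    taken over ``n_points`` on the mid-height segment y ∈ [L/3, 2L/3],
    z = 0.  Returns the table of (h, mean ‖F‖) and the least-squares slope
    of log ‖F‖ versus log h; dimensional analysis of the field model makes
    the slope exactly −3 (potential values are scale-invariant, so each
    spatial derivative contributes one inverse power of length and
    ∇(∇φ)² three).
    """
    rows = []
    for h in np.asarray(heights, dtype=float):
        geometry = ChannelGeometry(
            width_L=h, height_h=h,
            n_top=geometry_template.n_top, n_bottom=geometry_template.n_bottom,
        )
        model = FourierModel(geometry, truncation_P)
        y = np.linspace(h / 3, 2 * h / 3, n_points)
        z = np.zeros_like(y)
        fy, fz = force_field(model, voltages, y, z, particle, medium, drive)
        rows.append({"height_m": h, "mean_force_N": float(np.mean(np.hypot(fy, fz)))})
    table = pd.DataFrame(rows)
    slope = float(
        np.polyfit(np.log(table["height_m"]), np.log(table["mean_force_N"]), 1)[0]
    )
    return table, slope
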