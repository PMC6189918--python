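import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import depfield as df
from depfield.fourier import _potential_single_complex


def numerical_fourier_coefficient(p, u, geometry):
    """Independent oracle: quadrature of the boundary profile against e^{-i w y}.

    The p-th Fourier coefficient of the even 2L-periodic piecewise-linear
    boundary potential must equal sum_n u_n a_{p,n}.
    """
    L = geometry.width_L
    y = np.linspace(-L, L, 400001)
    f = df.boundary_potential(y, u, geometry, "bottom")
    w = p * np.pi / L
    return np.trapezoid(f * np.exp(-1j * w * y), y) / (2 * L)


class TestCoefficients:
    @pytest.mark.parametrize(
        "p, n, N, expected",
        [
            (0, 0, 8, 0.1),  # (3/2)/(2N-1)
            (0, 7, 8, 0.1),
            (0, 3, 8, 2.0 / 15.0),
        ],
    )
    def test_dc_entries(self, p, n, N, expected):
        assert df.fourier_coefficient(p, n, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N", [3, 5, 8])
    @pytest.mark.parametrize("p", [0, 1, 2, 5, 9])
    def test_match_quadrature_oracle(self, p, N, rng):
        geometry = df.ChannelGeometry(150e-6, 80e-6, N, N)
        u = rng.uniform(-1, 1, N)
        oracle = numerical_fourier_coefficient(p, u, geometry)
        table = sum(u[n] * df.fourier_coefficient(p, n, N) for n in range(N))
        assert table == pytest.approx(oracle.real, abs=5e-9)
        assert abs(oracle.imag) < 1e-12  # even boundary -> real coefficients

    def test_row_sums(self):
        """Constant boundary data is reconstructed exactly: rows sum to delta_p0."""
        for N in (2, 8, 17, 32):
            A = df.build_coefficient_matrix(N, 4 * N)
            sums = A.sum(axis=1)
            assert sums[4 * N] == pytest.approx(1.0, abs=1e-12)
            sums[4 * N] = 0.0
            assert np.max(np.abs(sums)) < 1e-12

    def test_rows_even_in_p(self):
        A = df.build_coefficient_matrix(8, 16)
        assert np.array_equal(A, A[::-1, :])

    def test_matrix_cached_and_readonly(self):
        A1 = df.build_coefficient_matrix(8, 16)
        A2 = df.build_coefficient_matrix(8, 16)
        assert A1 is A2
        with pytest.raises(ValueError):
            A1[0, 0] = 1.0

    def test_construction_preconditions(self):
        with pytest.raises(ValueError):
            df.build_coefficient_matrix(1, 8)
        with pytest.raises(ValueError):
            df.build_coefficient_matrix(8, 0)
        with pytest.raises(IndexError):
            df.fourier_coefficient(1, 8, 8)


class TestWavenumber:
    def test_values_and_symmetry(self):
        assert df.wavenumber(0, 1.0) == 0.0
        assert df.wavenumber(1, 150e-6) == pytest.approx(np.pi / 150e-6)
        for p in (1, 3, 10):
            assert df.wavenumber(-p, 2.0) == -df.wavenumber(p, 2.0)


class TestBoundaryPotential:
    def test_electrode_and_gap_midpoints(self, chip, rng):
        u = rng.uniform(-1, 1, 8)
        lam = chip.pitch_bottom
        for n in range(8):
            mid = (2 * n + 0.5) * lam
            assert df.boundary_potential(mid, u, chip) == pytest.approx(u[n])
        for n in range(7):
            gap_mid = (2 * n + 1.5) * lam
            assert df.boundary_potential(gap_mid, u, chip) == pytest.approx(
                0.5 * (u[n] + u[n + 1])
            )

    def test_even_and_periodic_extension(self, chip, rng):
        u = rng.uniform(-1, 1, 8)
        y = rng.uniform(0, chip.width_L, 50)
        L = chip.width_L
        np.testing.assert_allclose(
            df.boundary_potential(-y, u, chip), df.boundary_potential(y, u, chip)
        )
        np.testing.assert_allclose(
            df.boundary_potential(2 * L - y, u, chip),
            df.boundary_potential(y, u, chip),
        )


class TestZProfile:
    def test_endpoint_values(self, chip):
        for p in (0, 1, 7):
            assert df.z_profile(p, 0.0, chip.height_h, chip.width_L) == pytest.approx(1.0)
            assert df.z_profile(p, chip.height_h, chip.height_h, chip.width_L) == (
                pytest.approx(0.0, abs=1e-15)
            )

    def test_sinh_form_matches_exponential_ratio(self, chip):
        """The overflow-safe sinh ratio equals the raw exponential-ratio form."""
        h, L = chip.height_h, chip.width_L
        z = np.linspace(0, h, 33)
        for p in (1, 3, 11):
            w = p * np.pi / L
            raw = (np.exp(w * (2 * h - z)) - np.exp(w * z)) / (np.exp(2 * w * h) - 1)
            safe = df.z_profile(p, z, h, L)
            np.testing.assert_allclose(safe, raw, atol=1e-12)

    def test_out_of_domain(self, chip):
        with pytest.raises(ValueError):
            df.z_profile(1, -1e-6, chip.height_h, chip.width_L)


class TestBasis:
    def test_single_basis_boundary_values(self, chip):
        P = 16
        at_ground = df.basis_vector_single(40e-6, chip.height_h, chip, P)
        np.testing.assert_allclose(at_ground, 0.0, atol=1e-15)
        at_plane = df.basis_vector_single(0.0, 0.0, chip, P)
        assert at_plane[P] == pytest.approx(1.0)  # p = 0 entry

    def test_dual_basis_block_structure(self, chip):
        P = 8
        h = chip.height_h
        i_top0, i_bot0 = P, (2 * P + 1) + P  # p = 0 entries of each block
        top_wall = df.basis_vector_dual(50e-6, +h / 2, chip, P)
        assert top_wall[i_top0] == pytest.approx(1.0)
        assert top_wall[i_bot0] == pytest.approx(0.0, abs=1e-15)
        bottom_wall = df.basis_vector_dual(50e-6, -h / 2, chip, P)
        assert bottom_wall[i_top0] == pytest.approx(0.0, abs=1e-15)
        assert bottom_wall[i_bot0] == pytest.approx(1.0)
        centre = df.basis_vector_dual(50e-6, 0.0, chip, P)
        assert centre[i_top0] == pytest.approx(0.5)
        assert centre[i_bot0] == pytest.approx(0.5)

    def test_dual_reduces_to_single_with_grounded_top(self, chip, rng):
        """u_top = 0 collapses the two-array field to the bottom-array series."""
        u_bottom = rng.uniform(-1, 1, 8)
        model = df.FourierModel(chip, 16)
        volts = df.VoltagePattern([0.0] * 8, u_bottom)
        z_dual = rng.uniform(-chip.height_h / 2, chip.height_h / 2, 40)
        y = rng.uniform(0, chip.width_L, 40)
        dual = df.potential(y, z_dual, model, volts)
        single = df.potential_single(y, chip.height_h / 2 + z_dual, chip, u_bottom, 16)
        np.testing.assert_allclose(dual, single, atol=1e-14)

    def test_complex_and_cosine_paths_agree(self, chip, rng):
        u = rng.uniform(-1, 1, 8)
        for _ in range(5):
            y = rng.uniform(0, chip.width_L)
            z = rng.uniform(0, chip.height_h)
            c = _potential_single_complex(y, z, chip, u, 16)
            r = df.potential_single(y, z, chip, u, 16)
            assert abs(c.real - r) < 1e-12
            assert abs(c.imag) < 1e-12


class TestDerivatives:
    def test_richardson_check_against_finite_differences(self, chip, random_pattern, rng):
        """Analytic derivatives match central differences of the potential."""
        model = df.FourierModel(chip, 16)
        step = 1e-9
        for _ in range(5):
            y = rng.uniform(0.1, 0.9) * chip.width_L
            z = rng.uniform(-0.4, 0.4) * chip.height_h
            s = df.field_sample(y, z, model, random_pattern)

            def phi(yy, zz):
                return df.potential(yy, zz, model, random_pattern)

            fd_y = (phi(y + step, z) - phi(y - step, z)) / (2 * step)
            fd_z = (phi(y, z + step) - phi(y, z - step)) / (2 * step)
            fd_yy = (phi(y + step, z) - 2 * s.phi + phi(y - step, z)) / step**2
            fd_zz = (phi(y, z + step) - 2 * s.phi + phi(y, z - step)) / step**2
            fd_yz = (
                phi(y + step, z + step)
                - phi(y + step, z - step)
                - phi(y - step, z + step)
                + phi(y - step, z - step)
            ) / (4 * step**2)
            assert s.d_phi[0] == pytest.approx(fd_y, rel=1e-5)
            assert s.d_phi[1] == pytest.approx(fd_z, rel=1e-5)
            assert s.dd_phi[0] == pytest.approx(fd_yy, rel=1e-3)
            assert s.dd_phi[1] == pytest.approx(fd_yz, rel=1e-3)
            assert s.dd_phi[2] == pytest.approx(fd_zz, rel=1e-3)

    def test_harmonicity_termwise(self, chip):
        blocks = df.basis_derivatives(55e-6, 13e-6, chip, 12, order=2)
        np.testing.assert_allclose(
            blocks["yy"] + blocks["zz"], 0.0, atol=1e-4 * np.max(np.abs(blocks["yy"]))
        )

    def test_uniform_single_array_gradient(self, chip):
        """All electrodes at u: d(phi)/dz = -u/h everywhere (pure ramp)."""
        u = 0.8
        res = df.potential_single(
            np.array([30e-6, 75e-6]), np.array([10e-6, 60e-6]), chip,
            [u] * 8, 16, order=1,
        )
        np.testing.assert_allclose(res["z"], -u / chip.height_h, rtol=1e-10)
        np.testing.assert_allclose(res["y"], 0.0, atol=1e-10 * abs(u / chip.height_h))

    def test_order_validation(self, chip):
        with pytest.raises(ValueError):
            df.basis_derivatives(1e-6, 0.0, chip, 8, order=3)


class TestPotential:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(-3.0, 3.0),
        seed=st.integers(0, 2**16),
    )
    def test_linearity_in_voltages(self, chip, scale, seed):
        """phi(U1 + c U2) = phi(U1) + c phi(U2): superposition of electrodes."""
        r = np.random.default_rng(seed)
        model = df.FourierModel(chip, 8)
        u1 = df.VoltagePattern(r.uniform(-1, 1, 8), r.uniform(-1, 1, 8))
        u2 = df.VoltagePattern(r.uniform(-1, 1, 8), r.uniform(-1, 1, 8))
        combined = df.VoltagePattern(
            np.asarray(u1.u_top) + scale * np.asarray(u2.u_top),
            np.asarray(u1.u_bottom) + scale * np.asarray(u2.u_bottom),
        )
        y, z = 62e-6, -17e-6
        lhs = df.potential(y, z, model, combined)
        rhs = df.potential(y, z, model, u1) + scale * df.potential(y, z, model, u2)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_zero_voltages_zero_field(self, chip):
        model = df.FourierModel(chip, 16)
        zeros = df.VoltagePattern([0.0] * 8, [0.0] * 8)
        assert df.potential(75e-6, 0.0, model, zeros) == 0.0

    def test_shape_mismatch_raises(self, chip):
        model = df.FourierModel(chip, 16)
        with pytest.raises(ValueError):
            df.potential(75e-6, 0.0, model, df.VoltagePattern([0.0] * 5, [0.0] * 8))

    def test_reflection_extension_beyond_channel(self, chip, random_pattern):
        """The series extends evenly across the lateral walls (mirror images)."""
        model = df.FourierModel(chip, 16)
        L = chip.width_L
        t = np.linspace(1e-6, 20e-6, 7)
        np.testing.assert_allclose(
            df.potential(-t, 0.0, model, random_pattern),
            df.potential(t, 0.0, model, random_pattern),
            atol=1e-14,
        )
        np.testing.assert_allclose(
            df.potential(L + t, 5e-6, model, random_pattern),
            df.potential(L - t, 5e-6, model, random_pattern),
            atol=1e-14,
        )

    def test_electrode_midpoints_reproduced(self, chip, rng):
        """At P = 4N the series recovers each electrode's voltage at its midpoint
        to within 2% of the drive scale max|u|."""
        u = rng.uniform(-1, 1, 8)
        lam = chip.pitch_bottom
        scale = np.max(np.abs(u))
        mids = (2 * np.arange(8) + 0.5) * lam
        series = df.potential_single(mids, np.zeros(8), chip, u, 32)
        assert np.max(np.abs(series - u)) < 0.02 * scale

    def test_boundary_rms_error_nonincreasing_in_truncation(self, chip, rng):
        u = df.VoltagePattern(rng.uniform(-1, 1, 8), rng.uniform(-1, 1, 8))
        table = df.boundary_convergence_study(chip, u, [8, 16, 32, 64])
        errs = table["rel_rms_error_pct"].to_numpy()
        assert np.all(np.diff(errs) <= 1e-12)
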