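"""Width propagation, excitation transport and Herring couplings."""

import numpy as np
import pytest

from tunspec import workflows as wf
from tunspec.instanton import (
    InstantonField,
    effective_barrier,
    momentum_profile,
    tm_element_fundamental,
    tm_element_numeric,
    tm_sensitivity,
)
from tunspec.pathfinder import MinimumActionPath, optimize_map, spline_fields
from tunspec.potentials import CallablePES, characterize_minimum

W1 = np.sqrt(1.6 / 3.5)
W2 = np.sqrt(4.0 / 3.5)


def _global_harmonic(omega=(0.8, 1.3), x0=2.5):
    """Globally quadratic surface with two 'well' anchors on the x axis.

    A strictly harmonic surface has a single minimum; for fixed-point tests
    the path is laid down by hand between two anchor points and only the
    transport equations are exercised on it.
    """
    om = np.asarray(omega)

    def energy(x):
        x = np.asarray(x, float)
        return 0.5 * np.sum(om ** 2 * x ** 2, axis=-1)

    def gradient(x):
        return om ** 2 * np.asarray(x, float)

    return CallablePES(energy, gradient, dimension=2)


class TestMomentumProfile:
    def test_zero_at_minimum(self, path_sym):
        p0 = momentum_profile(path_sym, "L")
        assert p0(0.0) == pytest.approx(0.0, abs=1e-8)

    def test_1d_harmonic_linear_profile(self):
        """V = omega^2 S^2/2 gives p0(S) = omega S."""
        omega = 1.1

        def energy(x):
            x = np.asarray(x, float)
            return 0.5 * omega ** 2 * x[..., 0] ** 2

        def gradient(x):
            x = np.asarray(x, float)
            g = np.zeros_like(x)
            g[..., 0] = omega ** 2 * x[..., 0]
            return g

        pes = CallablePES(energy, gradient, dimension=2)
        n = 51
        beads = np.zeros((n, 2))
        beads[:, 0] = np.linspace(0, 2, n)
        path = MinimumActionPath(beads=beads, arc_lengths=np.zeros(n), d=0.0,
                                 cp_index=n // 2, residual=0.0, n_iter=0,
                                 action_history=np.array([]))
        spline_fields(path, pes, compute_hessians=False)
        p0 = momentum_profile(path, "L")
        # natural-spline end conditions leave an O(h^2) edge error in V(S),
        # so probe a few bead spacings away from the endpoints
        S = np.linspace(0.2, 1.8, 9)
        assert np.allclose(p0(S), omega * S, rtol=1e-4)

    def test_integral_equals_jacobi_action(self, path_sym, fields_sym):
        """Cross-module consistency: Int p0 dS = W0 of the side."""
        from tunspec.pathfinder import jacobi_action

        fL, _ = fields_sym
        assert fL.W0(path_sym.S_cp) == pytest.approx(
            jacobi_action(path_sym, "L"), rel=1e-6)


class TestWidthPropagation:
    def test_harmonic_fixed_point(self):
        """On a globally quadratic surface A(S) stays at A0 = H0^(1/2)."""
        pes = _global_harmonic()
        n = 101
        beads = np.zeros((n, 2))
        beads[:, 0] = np.linspace(0.0, 3.0, n)
        path = MinimumActionPath(beads=beads, arc_lengths=np.zeros(n), d=0.0,
                                 cp_index=n // 2, residual=0.0, n_iter=0,
                                 action_history=np.array([]))
        spline_fields(path, pes)
        well = characterize_minimum(pes, [0.0, 0.0])
        # lay the 'left' field along the path by hand
        f = InstantonField(path, well, "L", epsilon=0.1)
        for S in np.linspace(0.2, 2.8, 9):
            assert np.abs(f.A(S) - well.A0).max() < 1e-6

    def test_A_symmetric_and_matches_A0_at_eps(self, fields_sym, model_sym):
        fL, _ = fields_sym
        _, wellL, _ = model_sym
        for S in np.linspace(0.1, 3.6, 8):
            A = fL.A(S)
            assert np.abs(A - A.T).max() < 1e-8
        assert np.abs(fL.A(0.1) - wellL.A0).max() < 0.05  # O(eps) agreement

    def test_left_right_mirror_at_cp(self, fields_sym, path_sym):
        """A^L(S_cp) is the mirror image of A^R(S_cp) for the symmetric
        surface (mirror = flip of the x-parallel component)."""
        fL, fR = fields_sym
        M = np.diag([-1.0, 1.0])
        AL = fL.A(path_sym.S_cp)
        AR = fR.A(path_sym.S_cp)
        assert np.abs(AL - M @ AR @ M).max() < 1e-6

    def test_rk4_step_refinement(self, model_sym, path_sym):
        """Halving the integration step barely moves A(S_cp)."""
        _, wellL, _ = model_sym
        f1 = InstantonField(path_sym, wellL, "L", substeps=10)
        f2 = InstantonField(path_sym, wellL, "L", substeps=20)
        assert np.abs(f1.A(path_sym.S_cp) - f2.A(path_sym.S_cp)).max() < 1e-7


class TestExcitationTransport:
    def test_U_initial_condition(self, fields_sym, model_sym):
        fL, _ = fields_sym
        _, wellL, _ = model_sym
        exc = fL.excitation(1)
        U_eps = exc.U(0.1)
        U0 = wellL.normal_modes[:, 1]
        assert np.abs(U_eps - U0).max() < 1e-3

    def test_transverse_mode_on_separable_surface_keeps_F_zero(self, separable_model):
        """theta = 0: the transverse mode is orthogonal to the path, so its
        amplitude F vanishes identically and U stays the transverse mode."""
        pes, wl, wr = separable_model
        path = optimize_map(pes, wl, wr, n_beads=151, tol=1e-6)
        f = InstantonField(path, wl, "L")
        exc = f.excitation(1)  # transverse (y) mode
        assert exc.F_eps == 0.0
        for S in np.linspace(0.2, path.S_cp, 5):
            assert abs(exc.F(f, S)) == 0.0
            U = exc.U(S)
            assert abs(U[0]) < 1e-6  # no longitudinal admixture

    def test_longitudinal_F_matches_1d_wkb_on_harmonic_surface(self):
        """1D harmonic oracle: with the energy carried by the transport
        equation, F(S) = S exactly reproduces the first excited state."""
        pes = _global_harmonic(omega=(0.9, 1.7))
        n = 101
        beads = np.zeros((n, 2))
        beads[:, 0] = np.linspace(0.0, 3.0, n)
        path = MinimumActionPath(beads=beads, arc_lengths=np.zeros(n), d=0.0,
                                 cp_index=n // 2, residual=0.0, n_iter=0,
                                 action_history=np.array([]))
        spline_fields(path, pes)
        well = characterize_minimum(pes, [0.0, 0.0])
        f = InstantonField(path, well, "L", epsilon=0.1)
        exc = f.excitation(0)  # longitudinal mode along x
        for S in np.linspace(0.3, 2.5, 6):
            assert exc.F(f, S) == pytest.approx(S, rel=1e-4)


class TestEffectiveBarrier:
    def test_printed_values_of_symmetric_model(self, path_sym, fields_sym):
        """Ground 1.221, longitudinal 0.545, transversal 0.976."""
        fL, _ = fields_sym
        assert effective_barrier(path_sym, fL, (0, 0)) == pytest.approx(1.221, abs=0.005)
        assert effective_barrier(path_sym, fL, (1, 0)) == pytest.approx(0.545, abs=0.005)
        assert effective_barrier(path_sym, fL, (0, 1)) == pytest.approx(0.976, abs=0.005)

    def test_longitudinal_quantum_lowers_barrier_by_omega1(self, path_sym, fields_sym):
        fL, _ = fields_sym
        g = effective_barrier(path_sym, fL, (0, 0))
        e1 = effective_barrier(path_sym, fL, (1, 0))
        assert g - e1 == pytest.approx(W1, abs=1e-9)


class TestHerringElements:
    def test_gs_splitting_vs_exact(self, path_sym, fields_sym, dvr_sym):
        """2|h| reproduces the exact ground-state splitting to a few %."""
        fL, fR = fields_sym
        h = tm_element_fundamental(fL, fR, path_sym)
        ev = dvr_sym[0]
        exact = ev[1] - ev[0]
        assert h < 0  # sign convention: positive well wavefunctions
        assert 2 * abs(h) == pytest.approx(exact, rel=0.05)

    def test_transverse_splitting_vs_exact(self, path_sym, fields_sym, dvr_sym):
        fL, fR = fields_sym
        h = tm_element_fundamental(fL, fR, path_sym, state_L=(0, 1), state_R=(0, 1))
        ev = dvr_sym[0]
        exact = ev[5] - ev[4]
        assert 2 * abs(h) == pytest.approx(exact, rel=0.10)

    def test_longitudinal_splitting_overestimates(self, path_sym, fields_sym, dvr_sym):
        """Longitudinal excitation lowers the effective barrier; the
        semiclassical coupling then overshoots the exact splitting."""
        fL, fR = fields_sym
        h = tm_element_fundamental(fL, fR, path_sym, state_L=(1, 0), state_R=(1, 0))
        ev = dvr_sym[0]
        exact = ev[3] - ev[2]
        assert 2 * abs(h) > exact
        assert 2 * abs(h) == pytest.approx(exact, rel=0.25)

    def test_symmetry_zero_on_separable_surface(self, separable_model):
        """theta = 0: coupling between GS and the transverse-excited state
        vanishes exactly (odd integrand)."""
        pes, wl, wr = separable_model
        path = optimize_map(pes, wl, wr, n_beads=151, tol=1e-6)
        fL = InstantonField(path, wl, "L")
        fR = InstantonField(path, wr, "R")
        h00 = tm_element_fundamental(fL, fR, path)
        h_cross = tm_element_fundamental(fL, fR, path, state_L=None, state_R=(0, 1))
        assert abs(h_cross) < 1e-12 * abs(h00)

    def test_numeric_matches_fundamental(self, path_sym, fields_sym):
        """Quadrature route vs closed form, < 0.1% on all nu <= 1 pairs."""
        fL, fR = fields_sym
        for sl in (None, (1, 0), (0, 1)):
            for sr in (None, (1, 0), (0, 1)):
                hf = tm_element_fundamental(fL, fR, path_sym, state_L=sl, state_R=sr)
                hn = tm_element_numeric(fL, fR, path_sym, state_L=sl, state_R=sr)
                assert hn == pytest.approx(hf, rel=1e-3), (sl, sr)

    def test_numeric_quadrature_converged(self, path_sym, fields_sym):
        fL, fR = fields_sym
        h1 = tm_element_numeric(fL, fR, path_sym, state_L=(1, 0), state_R=(0, 1), order=20)
        h2 = tm_element_numeric(fL, fR, path_sym, state_L=(1, 0), state_R=(0, 1), order=40)
        assert h2 == pytest.approx(h1, rel=1e-4)

    def test_double_excitation_element_finite(self, path_sym, fields_sym):
        """nu = 2 elements only exist through the quadrature route."""
        fL, fR = fields_sym
        with pytest.raises(ValueError):
            tm_element_fundamental(fL, fR, path_sym, state_L=(2, 0), state_R=(0, 0))
        h22 = tm_element_numeric(fL, fR, path_sym, state_L=(0, 2), state_R=(0, 2))
        assert np.isfinite(h22) and h22 != 0.0


class TestSensitivity:
    def test_resonant_invariance_vs_off_resonant_drift(self, path_sym, fields_sym):
        """Degenerate states: the element is S_cp-invariant up to the
        curvature-order residual of the theory; detuned wells drift
        measurably."""
        fL, fR = fields_sym
        m, s, _, _ = tm_sensitivity(fL, fR, path_sym)
        assert s / abs(m) < 5e-3
        pes2, wl2, wr2 = wf.build_model(d=0.2)
        path2 = optimize_map(pes2, wl2, wr2, n_beads=301, tol=1e-6, d=0.2)
        fL2 = InstantonField(path2, wl2, "L")
        fR2 = InstantonField(path2, wr2, "R")
        m2, s2, _, _ = tm_sensitivity(fL2, fR2, path2)
        assert s2 / abs(m2) > 20 * (s / abs(m))

    def test_straight_path_invariance_is_tight(self, separable_model):
        """Without path curvature the resonant invariance is numerically
        exact (the analytic invariance identity holds term by term)."""
        pes, wl, wr = separable_model
        path = optimize_map(pes, wl, wr, n_beads=301, tol=1e-6)
        fL = InstantonField(path, wl, "L")
        fR = InstantonField(path, wr, "R")
        m, s, _, _ = tm_sensitivity(fL, fR, path)
        assert s / abs(m) < 1e-8

    def test_cp_range_touching_well_rejected(self, path_sym, fields_sym):
        fL, fR = fields_sym
        with pytest.raises(ValueError):
            tm_sensitivity(fL, fR, path_sym,
                           cp_range=(0.3, path_sym.total_length / 2))
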