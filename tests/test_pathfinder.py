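"""String-method path optimization and the Jacobi action."""

import numpy as np
import pytest

from tunspec import workflows as wf
from tunspec.pathfinder import (
    jacobi_action,
    load_path_csv,
    optimize_map,
    save_path_csv,
    spline_fields,
)
from tunspec.potentials import CallablePES, Well, characterize_minimum


def _harmonic_double_well_1d_energy(a=2.0, v0=1.0):
    """Separable surface: quartic double well in x, harmonic in y."""

    def energy(x):
        x = np.asarray(x, float)
        return (v0 * (x[..., 0] ** 2 - a ** 2) ** 2 / a ** 4
                + 0.5 * 2.0 * x[..., 1] ** 2)

    def gradient(x):
        x = np.asarray(x, float)
        g = np.zeros_like(x)
        g[..., 0] = 4 * v0 * x[..., 0] * (x[..., 0] ** 2 - a ** 2) / a ** 4
        g[..., 1] = 2.0 * x[..., 1]
        return g

    return CallablePES(energy, gradient, dimension=2)


class TestOptimizeMap:
    def test_separable_surface_gives_straight_line(self):
        """For double-well (x) x harmonic (y) the transverse gradient vanishes
        on the x axis, so the optimal path is the straight segment."""
        pes = _harmonic_double_well_1d_energy()
        wl = characterize_minimum(pes, [-2.0, 0.0])
        wr = characterize_minimum(pes, [2.0, 0.0])
        path = optimize_map(pes, wl, wr, n_beads=101, tol=1e-8)
        assert np.abs(path.beads[:, 1]).max() < 1e-6

    def test_symmetric_model_path_mirror_symmetric(self, path_sym):
        """The converged path maps onto itself under the L-R mirror."""
        mirrored = path_sym.beads[::-1] * np.array([-1.0, 1.0])
        assert np.abs(mirrored - path_sym.beads).max() < 1e-5

    def test_convergence_residual_below_threshold(self, path_sym):
        assert path_sym.residual <= 1e-6

    def test_beads_equally_spaced(self, path_sym):
        seg = np.diff(path_sym.arc_lengths)
        assert seg.std() / seg.mean() < 1e-3

    def test_action_final_not_above_initial(self, path_sym):
        hist = path_sym.action_history
        assert hist[-1] <= hist[0]
        # and the large-scale trend is non-increasing (small reparameterization
        # transients allowed)
        assert hist[-1] <= hist.min() * (1 + 1e-6)

    def test_action_stable_under_bead_count(self, model_sym, path_sym):
        pes, wl, wr = model_sym
        p2 = optimize_map(pes, wl, wr, n_beads=201, tol=1e-6)
        W1 = jacobi_action(path_sym, "L") + jacobi_action(path_sym, "R")
        W2 = jacobi_action(p2, "L") + jacobi_action(p2, "R")
        assert abs(W1 - W2) / W1 < 1e-4

    def test_cp_at_potential_maximum_for_symmetric_model(self, path_sym):
        S_max, _ = path_sym.potential_maximum()
        spacing = path_sym.total_length / (path_sym.n_beads - 1)
        assert abs(S_max - path_sym.S_cp) <= spacing

    def test_too_few_beads_rejected(self, model_sym):
        pes, wl, wr = model_sym
        with pytest.raises(ValueError):
            optimize_map(pes, wl, wr, n_beads=11)


class TestModifiedSurface:
    def test_d_zero_identical_and_endpoints_balanced(self, model_sym, path_sym):
        pes, *_ = model_sym
        from tunspec.pathfinder import build_modified_pes

        vt = build_modified_pes(pes, 0.0, path_sym)
        x = path_sym.beads[10]
        assert vt(10, x) == pytest.approx(float(pes.energy(x)), abs=1e-15)

    def test_heaviside_shift_by_side(self):
        pes, wl, wr = wf.build_model(d=0.5)
        path = optimize_map(pes, wl, wr, n_beads=101, tol=1e-5, d=0.5)
        from tunspec.pathfinder import build_modified_pes

        vt = build_modified_pes(pes, 0.5, path)
        before = path.cp_index - 5
        after = path.cp_index + 5
        xb, xa = path.beads[before], path.beads[after]
        assert vt(before, xb) == pytest.approx(float(pes.energy(xb)), abs=1e-15)
        assert vt(after, xa) == pytest.approx(float(pes.energy(xa)) - 0.5, abs=1e-15)
        # both endpoints sit at equal modified potential
        assert vt(0, path.beads[0]) == pytest.approx(
            vt(path.n_beads - 1, path.beads[-1]), abs=1e-8)


class TestJacobiAction:
    def test_zero_length_segment(self, path_sym):
        assert jacobi_action(path_sym, "L", S_from=1.0, S_to=1.0) == 0.0

    def test_1d_harmonic_closed_form(self):
        """On V = omega^2 S^2 / 2 the action from 0 to S is omega S^2 / 2."""
        omega = 1.3

        def energy(x):
            x = np.asarray(x, float)
            return 0.5 * omega ** 2 * (x[..., 0] ** 2 + 0.0 * x[..., 1])

        def gradient(x):
            x = np.asarray(x, float)
            g = np.zeros_like(x)
            g[..., 0] = omega ** 2 * x[..., 0]
            return g

        pes = CallablePES(energy, gradient, dimension=2)
        from tunspec.pathfinder import MinimumActionPath

        n = 101
        beads = np.zeros((n, 2))
        beads[:, 0] = np.linspace(0, 2.0, n)
        path = MinimumActionPath(beads=beads, arc_lengths=np.zeros(n), d=0.0,
                                 cp_index=n // 2, residual=0.0, n_iter=0,
                                 action_history=np.array([]))
        spline_fields(path, pes, compute_hessians=False)
        W = jacobi_action(path, "L", S_from=0.0, S_to=2.0)
        # natural-spline end conditions leave an O(h^2) edge error in V(S)
        assert W == pytest.approx(omega * 2.0 ** 2 / 2, rel=1e-4)

    def test_matches_independent_quadrature_oracle(self, path_sym):
        """Side action equals dense-trapezoid quadrature of sqrt(2 V(S))."""
        S = np.linspace(0.0, path_sym.S_cp, 40001)
        p = np.sqrt(2.0 * np.maximum(path_sym.v_spline(S), 0.0))
        W_ref = np.trapezoid(p, S)
        W = jacobi_action(path_sym, "L")
        assert W == pytest.approx(W_ref, rel=1e-6)

    def test_additive_over_segments(self, path_sym):
        a = jacobi_action(path_sym, "L", S_from=0.0, S_to=1.0)
        b = jacobi_action(path_sym, "L", S_from=1.0, S_to=2.5)
        c = jacobi_action(path_sym, "L", S_from=0.0, S_to=2.5)
        assert a + b == pytest.approx(c, rel=1e-9)


class TestSplineFields:
    def test_nodal_reproduction(self, model_sym, path_sym):
        pes, *_ = model_sym
        V = pes.energy(path_sym.beads)
        assert np.allclose(path_sym.v_spline(path_sym.arc_lengths), V, atol=1e-12)
        H = pes.hessian(path_sym.beads[7])
        assert np.allclose(path_sym.h_spline(path_sym.arc_lengths[7]), H, atol=1e-12)

    def test_natural_boundary_conditions(self, path_sym):
        s = path_sym.arc_lengths
        assert abs(path_sym.v_spline(s[0], 2)) < 1e-8
        assert abs(path_sym.v_spline(s[-1], 2)) < 1e-8

    def test_interpolated_potential_stable_under_refinement(self, model_sym):
        """Doubling the sampling density of the same converged path moves the
        interpolated V(S) at midpoints by less than 1e-6."""
        from scipy.interpolate import CubicSpline

        pes, wl, wr = model_sym
        p2 = optimize_map(pes, wl, wr, n_beads=601, tol=1e-6)
        V = pes.energy(p2.beads)
        coarse = CubicSpline(p2.arc_lengths[::2], V[::2], bc_type="natural")
        mid = 0.5 * (p2.arc_lengths[:-1:2] + p2.arc_lengths[2::2])
        interior = mid[(mid > 0.3) & (mid < p2.total_length - 0.3)]
        assert np.abs(coarse(interior) - p2.v_spline(interior)).max() < 1e-6

    def test_non_monotonic_beads_rejected(self, model_sym):
        pes, *_ = model_sym
        from tunspec.pathfinder import MinimumActionPath

        beads = np.zeros((5, 2))
        beads[:, 0] = [0.0, 1.0, 1.0, 2.0, 3.0]
        path = MinimumActionPath(beads=beads, arc_lengths=np.zeros(5), d=0.0,
                                 cp_index=2, residual=0.0, n_iter=0,
                                 action_history=np.array([]))
        with pytest.raises(ValueError):
            spline_fields(path, pes)


def test_checkpoint_roundtrip(tmp_path, model_sym, path_sym):
    pes, *_ = model_sym
    f = tmp_path / "path.csv"
    save_path_csv(path_sym, pes, f)
    back = load_path_csv(f, pes)
    assert np.abs(back.beads - path_sym.beads).max() < 1e-14
    assert back.cp_index == path_sym.cp_index
    assert back.total_length == pytest.approx(path_sym.total_length, rel=1e-12)
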