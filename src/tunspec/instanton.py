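"""Semiclassical (Jacobi-field) instanton wavefunctions and Herring couplings.

For each side of the minimum action path the semiclassical wavefunction of a
local state with ``nu`` quanta in the normal mode of harmonic frequency
``omega_e`` is, in the local frame (S, dx) of the path,

    phi(S, dx) ~ N (F(S) + U(S)^T dx)^nu
                 exp( -W0(S) - W1(S) - p0 tau^T dx - dx^T A(S) dx / 2 )

with the ingredients obtained by integrating, along the zero-energy
characteristic on the inverted surface (d tau = dS / p0),

* ``p0(S) = sqrt(2 (V - V_min))``        classical momentum,
* ``W0(S) = Int p0 dS``                  Hamilton-Jacobi (Jacobi) action,
* ``dA/dtau = H(S) - A^2``               Riccati equation for the Gaussian
  width matrix, initial value ``A0 = H0^(1/2)`` at the minimum,
* ``dW1/dtau = Tr(A - A0) / 2``          amplitude transport,
* ``dU/dtau = (omega_e - A) U``          nodal-vector transport, ``U(0)``
  the excited normal mode, and ``F(S) = F(eps) exp(omega_e tau(S))`` with
  ``F(eps) = U0^T (x(eps) - x_min)`` fixed by matching to the harmonic
  oscillator at a small arc distance ``eps`` from the minimum.

The propagation starts with a jump to ``S = eps`` (0.1 for the model
surface, 0.25 for molecules) where the surface is still harmonic, avoiding
the p0 -> 0 singularity.  Width matrices are saved at every bead and
interpolated with natural cubic splines; the spline is what the F/U
transport and all couplings consume.

The coupling between local states of different wells is the Herring surface
integral over the dividing plane through the connection point,

    h = -(p0_L + p0_R)/2 * Int_plane phi_L phi_R dSigma,

evaluated either in closed form (:func:`tm_element_fundamental`, one
quantum at most on each side) or by Gauss-Hermite quadrature on the plane
(:func:`tm_element_numeric`, arbitrary multi-mode excitations).  Both use
the same semiclassical wavefunctions, so they agree to quadrature accuracy
where their domains overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.interpolate import CubicSpline

from .pathfinder import MinimumActionPath
from .potentials import Well

__all__ = [
    "InstantonField",
    "momentum_profile",
    "propagate_widths",
    "propagate_excitation",
    "effective_barrier",
    "tm_element_fundamental",
    "tm_element_numeric",
    "tm_sensitivity",
    "tm_report",
]

#: relative eigenvalue threshold below which det' counts an eigenvalue as zero
DETP_ZERO_TOL = 1e-8


def momentum_profile(path: MinimumActionPath, side: str):
    """Return ``p0(S) = sqrt(2 (V(S) - floor))`` for one side of the path.

    The floor is the side's minimum on the modified surface (0 for L, ``d``
    for R), so ``p0`` vanishes exactly at the side's own minimum.  A
    negative radicand beyond 1e-8 aborts.
    """
    floor = path.side_floor(side)

    def p0(S):
        v = path.v_spline(S) - floor
        if np.any(np.asarray(v) < -1e-8):
            raise ValueError(f"negative radicand on side {side}: V-floor={np.min(v):g}")
        return np.sqrt(2.0 * np.maximum(v, 0.0))

    return p0


def _rk4(f, y0, grid):
    y = np.array(y0, float)
    out = np.empty((len(grid),) + y.shape)
    out[0] = y
    for i in range(len(grid) - 1):
        t, h = grid[i], grid[i + 1] - grid[i]
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
    return out


@dataclass
class _Excitation:
    mode_index: int
    omega_e: float
    F_eps: float
    U_spline: CubicSpline

    def F(self, field: "InstantonField", S):
        return self.F_eps * np.exp(self.omega_e * field.tau(S))

    def U(self, S):
        return self.U_spline(S)


class InstantonField:
    """Per-side semiclassical data along the path (widths, action, transport).

    Construction propagates ``A`` and ``W1`` from the side's minimum (after
    the ``eps`` jump) across the whole usable range of the path, so Herring
    elements can afterwards be evaluated at any connection point inside the
    barrier without re-propagating.  Excitation transports (F, U) are
    computed lazily per mode and cached.
    """

    def __init__(self, path: MinimumActionPath, well: Well, side: str, *,
                 epsilon: float = 0.1, substeps: int = 10):
        if side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        self.path = path
        self.well = well
        self.side = side
        self.epsilon = float(epsilon)
        self.p0 = momentum_profile(path, side)
        self.A0 = well.A0
        self.omega = well.frequencies
        self.modes = well.normal_modes
        self.E0 = 0.5 * float(np.sum(self.omega))
        s = path.arc_lengths
        Stot = path.total_length
        floor = path.side_floor(side)
        _, V_max = path.potential_maximum()
        # the far end of the propagation range stops before this side's
        # classical turning point (for unequal wells V - floor goes negative
        # inside the other well); widths diverge at a caustic there anyway
        v_cut = floor + max(1e-6, 1e-3 * (V_max - floor))
        S_max = path.potential_maximum()[0]
        # clip only on the far side of the barrier top: approaching the other
        # side's well V - floor can go negative and widths hit a caustic
        too_low = path.v_spline(s) <= v_cut
        if side == "L":
            start, far = self.epsilon, Stot - self.epsilon
            sel = (s > start + 1e-12) & (s <= far)
            bad = np.where(too_low & (s > S_max))[0]
            if len(bad):
                sel &= s < s[bad[0]]
            grid = np.concatenate([[start], s[sel]])
            self.x_min = path.x_spline(0.0)
        else:
            start, far = Stot - self.epsilon, self.epsilon
            sel = (s < start - 1e-12) & (s >= far)
            bad = np.where(too_low & (s < S_max))[0]
            if len(bad):
                sel &= s > s[bad[-1]]
            grid = np.concatenate([[start], s[sel][::-1]])
            self.x_min = path.x_spline(Stot)
        self._grid = grid
        nd = len(self.x_min)

        def clamped_p0(S):
            return np.sqrt(2.0 * np.maximum(path.v_spline(S) - floor, 0.0))

        self._p0c = clamped_p0

        def rhs(S, y):
            A = y[: nd * nd].reshape(nd, nd)
            p = max(clamped_p0(S), 1e-12)
            dA = (path.h_spline(S) - A @ A) / p
            dW1 = 0.5 * np.trace(A - self.A0) / p
            sgn = 1.0 if side == "L" else -1.0
            return sgn * np.concatenate([dA.ravel(), [dW1]])

        fine = _refine_grid(grid, substeps)
        ys = _rk4(rhs, np.concatenate([self.A0.ravel(), [0.0]]), fine)
        keep = np.arange(len(grid)) * substeps
        A_nodes = ys[keep, : nd * nd].reshape(-1, nd, nd)
        A_nodes = 0.5 * (A_nodes + np.swapaxes(A_nodes, 1, 2))
        self._check_widths(A_nodes, grid)
        order = np.argsort(grid)
        self._A = CubicSpline(grid[order], A_nodes[order], axis=0, bc_type="natural")
        self._W1 = CubicSpline(grid[order], ys[keep, -1][order], bc_type="natural")
        # cumulative action and tau on a fine grid (from the side's minimum)
        self._W0, self._tau = self._cumulatives()
        self._exc: dict[int, _Excitation] = {}

    # -- elementary accessors ---------------------------------------------
    def A(self, S):
        """Gaussian width matrix at arc length S (spline through bead values)."""
        return self._A(S)

    def W1(self, S):
        return float(self._W1(S))

    def W0(self, S):
        """Accumulated Jacobi action from this side's minimum up to S."""
        return float(self._W0(S))

    def tau(self, S):
        """Imaginary time measured from the eps jump point."""
        return self._tau(S)

    @property
    def S_range(self):
        g = self._grid
        return (min(g[0], g[-1]), max(g[0], g[-1]))

    def _cumulatives(self):
        Stot = self.path.total_length
        fine = np.linspace(0.0, Stot, 20 * self.path.n_beads)
        p = self._p0c(fine)
        if self.side == "L":
            w0 = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(fine))])
        else:
            rev = np.cumsum((0.5 * (p[1:] + p[:-1]) * np.diff(fine))[::-1])[::-1]
            w0 = np.concatenate([rev, [0.0]])
        W0 = CubicSpline(fine, w0)
        a, b = self.S_range
        tgrid = np.linspace(a, b, 20 * self.path.n_beads)
        invp = 1.0 / np.maximum(self._p0c(tgrid), 1e-12)
        ct = np.concatenate([[0.0], np.cumsum(0.5 * (invp[1:] + invp[:-1]) * np.diff(tgrid))])
        if self.side == "R":
            ct = ct[-1] - ct
        tau = CubicSpline(tgrid, ct)
        return W0, tau

    def _check_widths(self, A_nodes, grid):
        # transverse widths must stay positive; the tangential eigenvalue
        # (~ dp0/dS) legitimately changes sign past the barrier top, so the
        # local tangent is projected out before the check (as are trans/rot)
        nd = A_nodes.shape[-1]
        for k, S in enumerate(grid):
            t = self.path.tangent(S, self.side)
            P = np.eye(nd) - np.outer(t, t)
            ev = np.linalg.eigvalsh(P @ A_nodes[k] @ P)
            # the structural zeros (tangent + trans/rot) sit at ~0, so any
            # clearly negative eigenvalue is a collapsing transverse width
            if ev[0] < -1e-6:
                raise RuntimeError(
                    f"transverse width lost positivity at S={S:.4f} "
                    f"(eigenvalues {ev})"
                )

    # -- excitation transport ---------------------------------------------
    def excitation(self, mode_index: int) -> _Excitation:
        """Transport (F, U) for one quantum in ``mode_index`` (cached)."""
        if mode_index in self._exc:
            return self._exc[mode_index]
        if not 0 <= mode_index < len(self.omega):
            raise IndexError(f"mode_index {mode_index} out of range")
        we = float(self.omega[mode_index])
        U0 = self.modes[:, mode_index]
        grid = self._grid
        sgn = 1.0 if self.side == "L" else -1.0

        def rhs(S, U):
            return sgn * (we * U - self._A(S) @ U) / max(self._p0c(S), 1e-12)

        fine = _refine_grid(grid, 10)
        Us = _rk4(rhs, U0, fine)
        keep = np.arange(len(grid)) * 10
        order = np.argsort(grid)
        Uspl = CubicSpline(grid[order], Us[keep][order], axis=0, bc_type="natural")
        x_eps = self.path.x_spline(grid[0])
        F_eps = float(U0 @ (x_eps - self.x_min))
        tangent = self.path.tangent(grid[0], self.side)
        if abs(float(U0 @ tangent)) < 1e-10 and abs(F_eps) > 1e-6:
            # transverse mode should start with F ~ 0
            F_eps = 0.0
        exc = _Excitation(mode_index, we, F_eps, Uspl)
        self._exc[mode_index] = exc
        return exc


def _refine_grid(grid, substeps):
    out = [np.array([grid[0]])]
    for a, b in zip(grid[:-1], grid[1:]):
        out.append(np.linspace(a, b, substeps + 1)[1:])
    fine = np.concatenate(out)
    return fine


def propagate_widths(path: MinimumActionPath, well: Well, side: str, *,
                     epsilon: float = 0.1, substeps: int = 10) -> InstantonField:
    """Convenience constructor for :class:`InstantonField` (widths + W1)."""
    return InstantonField(path, well, side, epsilon=epsilon, substeps=substeps)


def propagate_excitation(field: InstantonField, mode_index: int):
    """Return ``(F(S) callable, U(S) callable, omega_e)`` for one quantum."""
    exc = field.excitation(mode_index)
    return (lambda S: exc.F(field, S)), exc.U, exc.omega_e


# ---------------------------------------------------------------------------
# effective barrier diagnostic


def effective_barrier(path: MinimumActionPath, field: InstantonField,
                      quanta=None) -> float:
    """Zero-point-corrected barrier for a local state of ``field``'s well.

    ``V_eff = V_max + sum_t (nu_t + 1/2) lambda_t - E_state`` where the
    ``lambda_t`` are the nonzero eigenvalues of the width matrix at the
    potential maximum with the path tangent projected out, the transverse
    quanta ``nu_t`` are matched to them in ascending frequency order, and
    ``E_state`` is the state's local harmonic energy.  The longitudinal
    mode (the one the path enters the minimum along) contributes to
    ``E_state`` but not to the barrier-top zero point.
    """
    quanta = np.zeros(len(field.omega), int) if quanta is None else np.asarray(quanta, int)
    S_max, V_max = path.potential_maximum()
    A = field.A(S_max)
    t = path.tangent(S_max)
    P = np.eye(len(t)) - np.outer(t, t)
    w = np.linalg.eigvalsh(P @ A @ P)
    lam = np.sort(w[np.abs(w) > DETP_ZERO_TOL * max(np.abs(w).max(), 1.0)])
    # identify the longitudinal mode at the minimum
    t_min = path.tangent(field.S_range[0], field.side)
    overlaps = np.abs(field.modes.T @ t_min)
    i_long = int(np.argmax(overlaps))
    trans_modes = [i for i in range(len(field.omega)) if i != i_long]
    if len(lam) != len(trans_modes):
        raise RuntimeError("transverse eigenvalue count mismatch at the barrier")
    zp_barrier = float(np.sum((quanta[trans_modes] + 0.5) * lam))
    E_state = float(np.sum((quanta + 0.5) * field.omega))
    return float(V_max + zp_barrier - E_state)


# ---------------------------------------------------------------------------
# Herring couplings


def _normalize_state(spec, n_modes):
    """State spec -> per-mode quanta tuple. None/'GS' means ground state."""
    if spec is None or spec == "GS":
        return tuple([0] * n_modes)
    spec = tuple(int(q) for q in spec)
    if len(spec) != n_modes:
        raise ValueError("state spec length must equal mode count")
    return spec


def _plane_basis(field_L, field_R, path, S_cp):
    """Common geometric data on the dividing plane at ``S_cp``."""
    nd = len(field_L.x_min)
    tl = path.tangent(S_cp, "L")
    tr = path.tangent(S_cp, "R")
    nvec = tl + tr
    nvec = nvec / np.linalg.norm(nvec)
    pL = float(field_L.p0(S_cp))
    pR = float(field_R.p0(S_cp))
    AL = field_L.A(S_cp)
    AR = field_R.A(S_cp)
    b = pL * tl - pR * tr
    P = np.eye(nd) - np.outer(nvec, nvec)
    b_perp = P @ b
    Abar = P @ (AL + AR) @ P
    w, U = np.linalg.eigh(Abar)
    scale = max(np.abs(w).max(), 1.0)
    nz = w > DETP_ZERO_TOL * scale
    n_zero_expected = 1 + field_L.well.n_zero  # plane normal + trans/rot
    if int((~nz).sum()) != n_zero_expected:
        raise RuntimeError(
            "det' zero-eigenvalue count mismatch on the dividing plane: "
            f"eigenvalues {w}, expected {n_zero_expected} zeros"
        )
    return dict(nd=nd, nvec=nvec, pL=pL, pR=pR, AL=AL, AR=AR, b=b_perp,
                w=w[nz], U=U[:, nz], tl=tl, tr=tr)


def _math_factorial(q):
    import math

    return math.factorial(q)


def tm_element_fundamental(field_L: InstantonField, field_R: InstantonField,
                           path: MinimumActionPath, *, state_L=None,
                           state_R=None, S_cp: float | None = None) -> float:
    """Closed-form Herring coupling for at most one quantum on each side.

    The plane integral of the product of the two semiclassical
    wavefunctions is a Gaussian integral with (at most) linear prefactors
    and is evaluated analytically: with ``Abar`` the sum of the two width
    matrices restricted to the plane (tangent projected out; det' is the
    product of its nonzero eigenvalues) and ``mu = -Abar^+ b`` the shift
    induced by the tangent-discontinuity term ``b`` (nonzero only for
    unequal-depth wells),

        h = -(p0L + p0R)/2 * N_L N_R * exp(-W0_tot - W1L - W1R)
            * (2 pi)^(k/2) / sqrt(det' Abar) * exp(b^T Abar^+ b / 2) * G,

    where ``G`` is 1 for GS-GS, ``F + U^T mu`` for one excited side, and
    ``(F_L + U_L^T mu)(F_R + U_R^T mu) + U_L^T Abar^+ U_R`` for two.
    """
    n_modes = len(field_L.omega)
    qL = _normalize_state(state_L, n_modes)
    qR = _normalize_state(state_R, n_modes)
    if sum(qL) > 1 or sum(qR) > 1:
        raise ValueError("fundamental route handles nu, nu' <= 1; use tm_element_numeric")
    if S_cp is None:
        S_cp = path.S_cp
    geo = _plane_basis(field_L, field_R, path, S_cp)
    lam, U = geo["w"], geo["U"]
    detp = float(np.prod(lam))
    Ainv = (U / lam) @ U.T
    mu = -Ainv @ geo["b"]
    shift = 0.5 * float(geo["b"] @ Ainv @ geo["b"])
    pref = _harm_norm(field_L, qL) * _harm_norm(field_R, qR)
    expo = -(field_L.W0(S_cp) + field_R.W0(S_cp)
             + field_L.W1(S_cp) + field_R.W1(S_cp)) + shift
    k = len(lam)
    gauss = (2.0 * np.pi) ** (k / 2.0) / np.sqrt(detp)

    def lin(field, quanta):
        m = int(np.argmax(quanta))
        exc = field.excitation(m)
        return float(exc.F(field, S_cp)) + float(exc.U(S_cp) @ mu), exc.U(S_cp)

    if sum(qL) == 0 and sum(qR) == 0:
        G = 1.0
    elif sum(qL) == 1 and sum(qR) == 0:
        G = lin(field_L, qL)[0]
    elif sum(qL) == 0 and sum(qR) == 1:
        G = lin(field_R, qR)[0]
    else:
        gl, Ul = lin(field_L, qL)
        gr, Ur = lin(field_R, qR)
        G = gl * gr + float(Ul @ Ainv @ Ur)
    return float(-0.5 * (geo["pL"] + geo["pR"]) * pref * np.exp(expo) * gauss * G)


def _harm_norm(field, quanta):
    n_cart = len(field.x_min) - field.well.n_zero
    det0 = float(np.prod(field.omega))
    pref = (det0 / np.pi ** n_cart) ** 0.25
    for m, q in enumerate(quanta):
        if q:
            pref *= (2.0 * field.omega[m]) ** (q / 2.0) / np.sqrt(_math_factorial(q))
    return pref


def tm_element_numeric(field_L: InstantonField, field_R: InstantonField,
                       path: MinimumActionPath, *, state_L=None, state_R=None,
                       S_cp: float | None = None, order: int = 20) -> float:
    """Herring coupling by Gauss-Hermite quadrature over the dividing plane.

    Handles arbitrary multi-mode excitations: the polynomial prefactor of
    each side is ``prod_m (F_m + U_m^T dx)^(nu_m)``.  Quadrature is taken
    in the eigenbasis of the symmetrized plane-restricted width matrix,
    ``order`` points per transverse dimension; the Gaussian weight of the
    product wavefunction is factored into the rule so only the polynomial
    and the linear-shift exponential are sampled.
    """
    n_modes = len(field_L.omega)
    qL = _normalize_state(state_L, n_modes)
    qR = _normalize_state(state_R, n_modes)
    if S_cp is None:
        S_cp = path.S_cp
    geo = _plane_basis(field_L, field_R, path, S_cp)
    lam, U = geo["w"], geo["U"]
    k = len(lam)
    if k > 6:
        raise ValueError("tensor-product quadrature impractical beyond 6 transverse dims")
    z, wq = hermgauss(order)
    pref = _harm_norm(field_L, qL) * _harm_norm(field_R, qR)
    expo = -(field_L.W0(S_cp) + field_R.W0(S_cp)
             + field_L.W1(S_cp) + field_R.W1(S_cp))
    excL = [(m, field_L.excitation(m)) for m, q in enumerate(qL) if q]
    excR = [(m, field_R.excitation(m)) for m, q in enumerate(qR) if q]
    total = 0.0
    scale = np.sqrt(2.0 / lam)
    for idx in itertools.product(range(order), repeat=k):
        xi = np.array([z[i] for i in idx]) * scale
        dx = U @ xi
        wgt = np.prod([wq[i] for i in idx])
        poly = 1.0
        for m, exc in excL:
            poly *= (float(exc.F(field_L, S_cp)) + float(exc.U(S_cp) @ dx)) ** qL[m]
        for m, exc in excR:
            poly *= (float(exc.F(field_R, S_cp)) + float(exc.U(S_cp) @ dx)) ** qR[m]
        total += wgt * poly * np.exp(-float(geo["b"] @ dx))
    total *= float(np.prod(scale))
    return float(-0.5 * (geo["pL"] + geo["pR"]) * pref * np.exp(expo) * total)


def tm_sensitivity(field_L: InstantonField, field_R: InstantonField,
                   path: MinimumActionPath, *, state_L=None, state_R=None,
                   cp_range=None, n_points: int = 21):
    """Scan the Herring element over connection-point positions.

    Returns ``(h_mean, h_spread, S_values, h_values)`` with the spread as
    half the peak-to-peak variation — the error estimate attached to
    off-resonant couplings (the element is exactly invariant only when the
    two local states are degenerate).  The scan range defaults to the
    central third of the path and must stay inside the barrier region.
    """
    Stot = path.total_length
    if cp_range is None:
        cp_range = (Stot / 3.0, 2.0 * Stot / 3.0)
    a, b = cp_range
    lo = max(field_L.S_range[0], field_R.S_range[0])
    hi = min(field_L.S_range[1], field_R.S_range[1])
    if a < lo or b > hi:
        raise ValueError("cp_range extends beyond the propagated fields")
    _, V_max = path.potential_maximum()
    floor = max(0.0, path.d)
    for end in (a, b):
        if path.v_spline(end) - floor < 0.1 * (V_max - floor):
            raise ValueError("cp_range touches a well region")
    S_values = np.linspace(a, b, n_points)
    h_values = np.array([
        tm_element_fundamental(field_L, field_R, path, state_L=state_L,
                               state_R=state_R, S_cp=S)
        for S in S_values
    ])
    h_mean = float(np.mean(h_values))
    h_spread = float(0.5 * (h_values.max() - h_values.min()))
    return h_mean, h_spread, S_values, h_values


def tm_report(states_L, states_R, h_matrix, spreads=None, diagnostics=None):
    """Tabulate Herring couplings as a tidy DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for i, sl in enumerate(states_L):
        for j, sr in enumerate(states_R):
            row = {"state_L": str(sl), "state_R": str(sr),
                   "h": h_matrix[i][j]}
            if spreads is not None:
                row["spread"] = spreads[i][j]
            rows.append(row)
    df = pd.DataFrame(rows)
    if diagnostics:
        for key, val in diagnostics.items():
            df[key] = val
    return df
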