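"""Minimum-action-path optimization by the string method.

The tunneling path between two wells is the minimizer of the Jacobi action

    W0 = Int sqrt(2 (V(x) - V_min)) dS

over curves connecting the minima, in mass-scaled coordinates.  For wells
of unequal depth (right minimum offset by ``d``) the path is optimized on
the modified surface ``Vt(x) = V(x) - Theta(S - S_cp) d`` with the
connection point fixed at the middle bead, which makes both endpoints sit
at ``Vt = 0``; the optimal path then has a tangent kink at ``S_cp`` and the
dividing-plane normal is taken as the average of the one-sided tangents.

The string iteration displaces beads along the component of the discrete
action gradient perpendicular to the path, treating the stiff elastic part
of the gradient implicitly (a tridiagonal solve per step), and
re-parameterizes the beads to equal arc length after every step.
Convergence is measured as the largest perpendicular component of the
discrete Jacobi-action gradient (max norm over beads), with a default
threshold of 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.linalg import solve_banded

from .potentials import PotentialSurface, Well

__all__ = [
    "MinimumActionPath",
    "optimize_map",
    "jacobi_action",
    "build_modified_pes",
    "spline_fields",
    "save_path_csv",
    "load_path_csv",
]


@dataclass
class MinimumActionPath:
    """A converged, spline-parameterized minimum action path.

    Beads are equally spaced in mass-scaled arc length ``S`` (``S_0 = 0`` at
    the left minimum).  ``v_spline``/``x_spline``/``h_spline`` interpolate
    the potential, the geometry and the Hessian elements versus ``S`` with
    natural cubic splines through the bead values.  ``cp_index`` marks the
    connection point (middle bead by default); for ``d != 0`` the tangent
    there is the renormalized mean of the one-sided spline limits.
    """

    beads: np.ndarray
    arc_lengths: np.ndarray
    d: float
    cp_index: int
    residual: float
    n_iter: int
    action_history: np.ndarray
    v_spline: CubicSpline = field(repr=False, default=None)
    x_spline: CubicSpline = field(repr=False, default=None)
    h_spline: CubicSpline = field(repr=False, default=None)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])

    @property
    def S_cp(self) -> float:
        return float(self.arc_lengths[self.cp_index])

    def tangent(self, S, side: str | None = None):
        """Unit tangent at ``S``; at ``S_cp`` with ``side=None`` the mean of
        the one-sided limits (they differ when ``d != 0``)."""
        eps = 1e-7 * self.total_length
        if side == "L":
            t = self.x_spline(np.minimum(S, self.S_cp) - eps, 1)
        elif side == "R":
            t = self.x_spline(np.maximum(S, self.S_cp) + eps, 1)
        elif abs(float(S) - self.S_cp) < eps and self.d != 0.0:
            t = 0.5 * (self.tangent(S, "L") + self.tangent(S, "R"))
        else:
            t = self.x_spline(S, 1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def potential_maximum(self):
        """(S_max, V_max) of the interpolated potential along the path."""
        from scipy.optimize import minimize_scalar

        s = self.arc_lengths
        imax = int(np.argmax(self.v_spline(s)))
        lo = s[max(imax - 2, 0)]
        hi = s[min(imax + 2, len(s) - 1)]
        r = minimize_scalar(lambda t: -self.v_spline(t), bounds=(lo, hi),
                            method="bounded", options=dict(xatol=1e-12))
        return float(r.x), float(-r.fun)

    def side_floor(self, side: str) -> float:
        """Potential floor of one side on the modified surface (0 or d)."""
        return 0.0 if side == "L" else float(self.d)


def build_modified_pes(pes: PotentialSurface, d: float, path: MinimumActionPath):
    """Return ``Vt(x) = V(x) - Theta(S - S_cp) d`` as a bead-wise rule.

    The Heaviside shift is attached to bead indices relative to the path's
    connection point (a path estimate assigns each bead a side), which is
    how the modified surface enters the string iteration; the gradient is
    untouched because the shift is piecewise constant.
    """
    cp = path.cp_index

    def vtilde(bead_index, x):
        return pes.energy(x) - (d if bead_index >= cp else 0.0)

    return vtilde


def _equal_arc_reparam(beads: np.ndarray, n: int, fine: int = 8) -> np.ndarray:
    """Redistribute beads to equal arc length along the interpolating spline."""
    seg = np.linalg.norm(np.diff(beads, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    cs = CubicSpline(s, beads, axis=0)
    ss = np.linspace(0.0, s[-1], fine * n)
    spd = np.linalg.norm(cs(ss, 1), axis=1)
    al = np.concatenate([[0.0], np.cumsum(0.5 * (spd[1:] + spd[:-1]) * np.diff(ss))])
    return cs(np.interp(np.linspace(0.0, al[-1], n), al, ss))


def _discrete_action_grad(pes, beads, d, cp):
    """Trapezoid Jacobi action W0 = sum a_i L_i and its gradient.

    Segment momenta use the modified potential: beads at index >= cp are on
    the right side and are shifted down by ``d`` (both endpoints then sit at
    zero).  Returns (W, grad, a, L) with ``a`` the per-segment mean momenta.
    """
    n = len(beads)
    V = pes.energy(beads)
    G = pes.gradient(beads)
    shift = d * (np.arange(n) >= cp)
    p = np.sqrt(2.0 * np.maximum(V - shift, 0.0))
    pseg_l, pseg_r = p[:-1].copy(), p[1:].copy()
    gp = np.zeros_like(G)
    ok = p > 1e-14
    gp[ok] = G[ok] / p[ok, None]
    gp_l, gp_r = gp[:-1].copy(), gp[1:].copy()
    if d != 0.0:
        # the segment leaving the connection point lies on the R side
        p_cp_R = np.sqrt(2.0 * max(V[cp] - d, 0.0))
        pseg_l[cp] = p_cp_R
        gp_l[cp] = G[cp] / max(p_cp_R, 1e-14)
    dx = np.diff(beads, axis=0)
    L = np.linalg.norm(dx, axis=1)
    u = dx / L[:, None]
    a = 0.5 * (pseg_l + pseg_r)
    W = float(np.sum(a * L))
    grad = np.zeros_like(beads)
    grad[:-1] += 0.5 * gp_l * L[:, None]
    grad[1:] += 0.5 * gp_r * L[:, None]
    grad[1:] += a[:, None] * u
    grad[:-1] -= a[:, None] * u
    return W, grad, a, L


def _perp(g, beads):
    t = np.gradient(beads, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return g - np.einsum("ij,ij->i", g, t)[:, None] * t


def optimize_map(pes: PotentialSurface, wellL: Well, wellR: Well, *,
                 n_beads: int = 301, tol: float = 1e-6, d: float = 0.0,
                 cp: int | None = None, max_iter: int = 20000, step: float = 2.0,
                 init_beads: np.ndarray | None = None,
                 compute_hessians: bool = True) -> MinimumActionPath:
    """Optimize the minimum action path between two characterized wells.

    Parameters
    ----------
    n_beads : int
        String discretization (301 by default; >= 31 required).
    tol : float
        Convergence threshold on the largest perpendicular component of the
        discrete Jacobi-action gradient.
    d : float
        Energy offset of the right well; activates the modified surface
        with the connection point fixed a priori.
    cp : int, optional
        Connection-point bead index; defaults to the middle bead.
    step : float
        Semi-implicit pseudo-time step (backtracked on action increase).
    init_beads : ndarray, optional
        Warm-start path (e.g. from a neighboring sweep point).
    """
    if n_beads < 31:
        raise ValueError("n_beads must be >= 31")
    xL, xR = wellL.geometry, wellR.geometry
    if np.linalg.norm(xL - xR) < 1e-8:
        raise ValueError("wells coincide")
    if cp is None:
        cp = n_beads // 2
    if init_beads is not None:
        beads = _equal_arc_reparam(np.asarray(init_beads, float), n_beads)
        beads[0], beads[-1] = xL, xR
    else:
        frac = np.linspace(0.0, 1.0, n_beads)[:, None]
        beads = xL[None, :] + frac * (xR - xL)[None, :]
    history = []
    res = np.inf
    dt = step
    W_prev = np.inf
    it = 0
    for it in range(max_iter):
        W, g, a, L = _discrete_action_grad(pes, beads, d, cp)
        history.append(W)
        gperp = _perp(g, beads)
        res = float(np.abs(gperp[1:-1]).max())
        if res < tol:
            break
        if W > W_prev * (1 + 1e-9) and dt > 1e-3 * step:
            dt *= 0.5  # backtrack on action increase
        W_prev = W
        nint = n_beads - 2
        al = a[:-1] / L[:-1]
        ar = a[1:] / L[1:]
        di = 1.0 + dt * (al[:nint] + ar[:nint])
        lo = np.concatenate([-dt * al[1:nint], [0.0]])
        up = np.concatenate([[0.0], -dt * ar[: nint - 1]])
        ab = np.vstack([up, di, lo])
        rhs = -dt * gperp[1:-1]
        dxk = np.empty_like(rhs)
        for c in range(beads.shape[1]):
            dxk[:, c] = solve_banded((1, 1), ab, rhs[:, c])
        beads[1:-1] += dxk
        beads = _equal_arc_reparam(beads, n_beads)
        beads[0], beads[-1] = xL, xR
    else:
        raise RuntimeError(
            f"string iteration hit the cap ({max_iter}); residual {res:.2e}"
        )
    if np.linalg.norm(beads[0] - beads[-1]) < 1e-6:
        raise RuntimeError("path collapsed onto a single well")
    beads = _equal_arc_reparam(beads, n_beads)
    beads[0], beads[-1] = xL, xR
    path = MinimumActionPath(
        beads=beads,
        arc_lengths=np.zeros(n_beads),
        d=d,
        cp_index=cp,
        residual=res,
        n_iter=it + 1,
        action_history=np.asarray(history),
    )
    spline_fields(path, pes, compute_hessians=compute_hessians)
    return path


def spline_fields(path: MinimumActionPath, pes: PotentialSurface, *,
                  compute_hessians: bool = True) -> MinimumActionPath:
    """Attach natural-cubic-spline interpolants of x(S), V(S) and H(S).

    Hessians are evaluated at every bead and their elements interpolated
    individually.  ``S`` is strictly increasing by construction (the string
    step ends with an equal-arc-length reparameterization); a non-monotonic
    bead sequence is rejected.
    """
    beads = path.beads
    seg = np.linalg.norm(np.diff(beads, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("bead arc lengths must be strictly increasing")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    path.arc_lengths = s
    path.x_spline = CubicSpline(s, beads, axis=0, bc_type="natural")
    path.v_spline = CubicSpline(s, pes.energy(beads), bc_type="natural")
    if compute_hessians:
        H = pes.hessian(beads)
        path.h_spline = CubicSpline(s, H, axis=0, bc_type="natural")
    return path


def jacobi_action(path: MinimumActionPath, side: str, *, S_from=None, S_to=None,
                  tol: float = 1e-10) -> float:
    """Jacobi action W0 of one side's segment, from the spline of V(S).

    The momentum uses the side's potential floor on the modified surface
    (``V`` for L, ``V - d`` for R).  Values of ``V - floor`` below zero by
    more than ``100 * tol`` abort (the path strayed below the well floor);
    smaller excursions are clipped to zero.
    """
    floor = path.side_floor(side)
    if side == "L":
        a = 0.0 if S_from is None else S_from
        b = path.S_cp if S_to is None else S_to
    else:
        a = path.S_cp if S_from is None else S_from
        b = path.total_length if S_to is None else S_to
    if b <= a:
        return 0.0
    vmin = min(path.v_spline(np.linspace(a, b, 200)).min() - floor, 0.0)
    if vmin < -max(100 * tol, 1e-8):
        raise ValueError(f"V dips {vmin:g} below the {side} floor on [{a:g},{b:g}]")

    def p0(S):
        return np.sqrt(np.maximum(2.0 * (path.v_spline(S) - floor), 0.0))

    val, _ = quad(p0, a, b, limit=400)
    return float(val)


# ---------------------------------------------------------------------------
# checkpointing (plain-text, round-trips losslessly at full precision)


def save_path_csv(path: MinimumActionPath, pes: PotentialSurface, filename):
    nd = path.beads.shape[1]
    H = pes.hessian(path.beads).reshape(path.n_beads, nd * nd)
    cols = {"bead": np.arange(path.n_beads), "S": path.arc_lengths,
            "V": pes.energy(path.beads)}
    for i in range(nd):
        cols[f"x{i}"] = path.beads[:, i]
    for i in range(nd):
        for j in range(nd):
            cols[f"H{i}{j}"] = H[:, i * nd + j]
    df = pd.DataFrame(cols)
    df.attrs = {}
    with open(filename, "w") as fh:
        fh.write(f"# tunspec path checkpoint d={path.d!r} cp={path.cp_index} "
                 f"residual={path.residual!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def load_path_csv(filename, pes: PotentialSurface) -> MinimumActionPath:
    with open(filename) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=", 1) for tok in header.split() if "=" in tok)
    nd = sum(c.startswith("x") for c in df.columns)
    beads = df[[f"x{i}" for i in range(nd)]].to_numpy()
    path = MinimumActionPath(
        beads=beads, arc_lengths=df["S"].to_numpy(), d=float(meta["d"]),
        cp_index=int(meta["cp"]), residual=float(meta["residual"]),
        n_iter=0, action_history=np.array([]),
    )
    spline_fields(path, pes)
    return path
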