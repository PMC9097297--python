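"""Single-well anharmonic vibrational states: VSCF and VCISD.

The well potential is expanded around its minimum in the n-mode hierarchy
truncated after pair couplings,

    V(q) = V0 + sum_i v_i(q_i) + sum_{i<j} v_ij(q_i, q_j),

with q the normal coordinates of the (mass-scaled) Hessian.  Each 1-mode
cut is sampled at the Gauss-Hermite DVR points of the mode's harmonic
oscillator (zeros of the Hermite polynomial scaled by the harmonic length
scale 1/sqrt(omega_i)) and fitted to a polynomial through the origin
(orders 1..8 by default; with eight points the fit is an exact
interpolation).  Pair corrections are sampled on the rectangular grid of
the same DVR points and fitted to tensor-product monomials q_i^a q_j^b,
a, b >= 1, again exactly determined on the grid.

The VSCF basis for each mode is a set of harmonic-oscillator functions
whose frequency is *not* the harmonic frequency but the fundamental
E1 - E0 of the fitted 1-mode Hamiltonian, computed in a 100-function sine
DVR; this adapts the basis to strongly anharmonic cuts.  After VSCF
convergence the virtual modals of the mean-field operator span the
configuration space for VCISD: at most two modes excited simultaneously,
at most ``max_quanta`` (6) quanta in any mode.  States are labeled by the
dominant CI coefficient; a near-tie (top two weights within 10%) sets the
``ambiguous`` flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss

from .potentials import PotentialSurface, Well

__all__ = [
    "NModeSurface",
    "LocalState",
    "build_nmode_surface",
    "mode_basis_frequency",
    "vscf_solve",
    "vcisd_solve",
    "solve_well_vci",
    "local_spectrum_report",
]


# ---------------------------------------------------------------------------
# harmonic-oscillator basis utilities (mass 1, frequency omega)


def ho_functions(n_basis: int, omega: float, q: np.ndarray) -> np.ndarray:
    """Values of the first ``n_basis`` HO eigenfunctions at points ``q``."""
    z = np.sqrt(omega) * q
    chi = np.zeros((n_basis, len(q)))
    chi[0] = (omega / np.pi) ** 0.25 * np.exp(-z * z / 2)
    if n_basis > 1:
        chi[1] = np.sqrt(2.0) * z * chi[0]
    for n in range(2, n_basis):
        chi[n] = np.sqrt(2.0 / n) * z * chi[n - 1] - np.sqrt((n - 1) / n) * chi[n - 2]
    return chi


def ho_kinetic(n_basis: int, omega: float) -> np.ndarray:
    """<m| p^2/2 |n> in the HO basis of frequency omega."""
    T = np.zeros((n_basis, n_basis))
    for n in range(n_basis):
        T[n, n] = 0.5 * omega * (n + 0.5)
        if n + 2 < n_basis:
            T[n, n + 2] = T[n + 2, n] = -0.25 * omega * np.sqrt((n + 1) * (n + 2))
    return T


def ho_q_powers(n_basis: int, omega: float, k_max: int) -> np.ndarray:
    """<m| q^k |n> for k = 0..k_max, exact by Gauss-Hermite quadrature."""
    npt = (k_max + 2 * n_basis) // 2 + 4
    z, w = hermgauss(npt)
    q = z / np.sqrt(omega)
    chi = ho_functions(n_basis, omega, q)
    wgt = w * np.exp(z * z) / np.sqrt(omega)
    Q = np.empty((k_max + 1, n_basis, n_basis))
    for k in range(k_max + 1):
        Q[k] = (chi * (q ** k * wgt)) @ chi.T
    return Q


# ---------------------------------------------------------------------------
# the n-mode surface


@dataclass
class NModeSurface:
    """1-mode + 2-mode representation of a well potential.

    ``poly1[i]`` holds coefficients (constant term first, fixed to zero) of
    the i-th 1-mode cut; ``poly2[(i, j)]`` the matrix of pair-coupling
    coefficients over monomials ``q_i^a q_j^b`` (a, b >= 1).  Residuals of
    the least-squares fits are recorded; on an exactly determined grid they
    are at rounding level.
    """

    well: Well
    n_dvr: int
    fit_order: int
    q_dvr: list = field(default_factory=list)
    poly1: list = field(default_factory=list)
    poly2: dict = field(default_factory=dict)
    fit_residuals: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.poly1)

    def v1(self, i: int, q) -> np.ndarray:
        return np.polyval(self.poly1[i][::-1], q)

    def v2(self, i: int, j: int, qi, qj) -> np.ndarray:
        C = self.poly2[(i, j)]
        Mi = np.vander(np.atleast_1d(qi), self.fit_order + 1, increasing=True)[:, 1:]
        Mj = np.vander(np.atleast_1d(qj), self.fit_order + 1, increasing=True)[:, 1:]
        return np.einsum("pa,ab,pb->p", Mi, C, Mj)

    def evaluate(self, q) -> np.ndarray:
        """V - V0 of the truncated representation at normal coordinates q."""
        q = np.atleast_2d(q)
        out = sum(self.v1(i, q[:, i]) for i in range(self.n_modes))
        for (i, j) in self.poly2:
            out = out + self.v2(i, j, q[:, i], q[:, j])
        return out


def build_nmode_surface(pes: PotentialSurface, well: Well, *, n_dvr: int = 8,
                        fit_order: int = 8) -> NModeSurface:
    """Sample and fit the 1-mode and 2-mode terms of a well potential."""
    surf = NModeSurface(well=well, n_dvr=n_dvr, fit_order=fit_order)
    z, _ = hermgauss(n_dvr)
    x0 = well.geometry
    V0 = well.energy
    U = well.normal_modes
    for i, w in enumerate(well.frequencies):
        q = z / np.sqrt(w)
        surf.q_dvr.append(q)
        pts = x0[None, :] + q[:, None] * U[:, i][None, :]
        v = pes.energy(pts) - V0
        M = np.vander(q, fit_order + 1, increasing=True)[:, 1:]
        coef, resid = _fit(M, v, f"mode {i}")
        surf.poly1.append(np.concatenate([[0.0], coef]))
        surf.fit_residuals[("1mode", i)] = resid
    for i, j in itertools.combinations(range(len(well.frequencies)), 2):
        qi, qj = surf.q_dvr[i], surf.q_dvr[j]
        Xi, Xj = np.meshgrid(qi, qj, indexing="ij")
        pts = (x0[None, None, :] + Xi[..., None] * U[:, i][None, None, :]
               + Xj[..., None] * U[:, j][None, None, :])
        Vg = pes.energy(pts) - V0
        resid_grid = Vg - surf.v1(i, Xi) - surf.v1(j, Xj)
        Mi = np.vander(qi, fit_order + 1, increasing=True)[:, 1:]
        Mj = np.vander(qj, fit_order + 1, increasing=True)[:, 1:]
        # resid = Mi C Mj^T, exactly determined when n_dvr == fit_order
        C = np.linalg.solve(Mi, np.linalg.solve(Mj, resid_grid.T).T)
        surf.poly2[(i, j)] = C
        back = np.einsum("pa,ab,qb->pq", Mi, C, Mj)
        surf.fit_residuals[("2mode", i, j)] = float(np.abs(back - resid_grid).max())
    return surf


def _fit(M, v, what):
    cond = np.linalg.cond(M)
    if cond > 1e12:
        warnings.warn(f"ill-conditioned fit for {what} (cond {cond:.1e}); "
                      "reducing order", stacklevel=3)
        M = M[:, : M.shape[1] - 1]
    if M.shape[0] == M.shape[1]:
        coef = np.linalg.solve(M, v)
        resid = 0.0
    else:
        coef, res, *_ = np.linalg.lstsq(M, v, rcond=None)
        resid = float(np.sqrt(res[0])) if len(res) else 0.0
    if M.shape[1] < len(v):
        coef = np.concatenate([coef, np.zeros(len(v) - len(coef))])
    return coef, resid


# ---------------------------------------------------------------------------
# basis frequency from a sine-DVR solve of the 1-mode Hamiltonian


def sine_dvr_hamiltonian(v_grid: np.ndarray, length: float) -> np.ndarray:
    """Kinetic + diagonal potential in a sine (particle-in-box) DVR.

    The kinetic matrix is assembled spectrally, ``T = S diag(k^2 pi^2 /
    (2 L^2)) S^T`` with the unitary sine transform ``S_{ik} =
    sqrt(2/(n+1)) sin(i k pi/(n+1))`` — exact for -1/2 d^2/dq^2 with box
    eigenfunctions, by construction.
    """
    n = len(v_grid)
    i = np.arange(1, n + 1)
    S = np.sqrt(2.0 / (n + 1)) * np.sin(np.outer(i, i) * np.pi / (n + 1))
    e_k = (i * np.pi / length) ** 2 / 2.0
    T = (S * e_k) @ S.T
    return T + np.diag(v_grid)


def mode_basis_frequency(poly1: np.ndarray, q_max: float, *, n_basis: int = 100,
                         box_factor: float = 1.6) -> float:
    """Fundamental E1 - E0 of a fitted 1-mode cut, used as basis frequency.

    The 1-mode Hamiltonian is solved in a sine DVR with ``n_basis``
    functions on a box of half-width ``box_factor * q_max`` around the
    minimum.  If the fitted polynomial's high-order tail turns the box
    edges down below the interior maximum (an unbound fit), the box is
    shrunk with a warning until the cut is confining.
    """
    L = box_factor * q_max
    for _ in range(8):
        grid = np.linspace(-L, L, n_basis + 2)[1:-1]
        v = np.polyval(poly1[::-1], grid)
        interior = v[len(v) // 4 : -len(v) // 4]
        if min(v[0], v[-1]) >= interior.max():
            break
        warnings.warn("1-mode fit unbound on the box; shrinking", stacklevel=2)
        L *= 0.8
    else:
        raise ValueError("could not find a confining box for the 1-mode cut")
    H = sine_dvr_hamiltonian(v, 2 * L)
    ev = np.linalg.eigvalsh(H)
    return float(ev[1] - ev[0])


# ---------------------------------------------------------------------------
# VSCF


class _ModeOperators:
    """Per-mode matrices in the HO basis of the mode's basis frequency."""

    def __init__(self, surf: NModeSurface, i: int, n_basis: int):
        self.omega_basis = mode_basis_frequency(surf.poly1[i], np.abs(surf.q_dvr[i]).max())
        self.T = ho_kinetic(n_basis, self.omega_basis)
        self.Q = ho_q_powers(n_basis, self.omega_basis, surf.fit_order)
        self.V1 = np.einsum("k,kmn->mn", surf.poly1[i][1:], self.Q[1:])
        self.core = self.T + self.V1


def vscf_solve(surf: NModeSurface, *, basis_size: int = 7, tol: float = 1e-9,
               max_iter: int = 200):
    """Ground-state VSCF on the 1+2-mode surface.

    Returns ``(modals, E_vscf, ops)``: per-mode modal coefficient matrices
    (columns = modals of the converged mean-field operator, in the HO
    basis), the VSCF ground-state energy (excluding the well reference
    V0), and the per-mode operator cache.  Convergence is on successive
    energy changes; persistent oscillation triggers one damped retry
    before aborting.
    """
    nm = surf.n_modes
    ops = [_ModeOperators(surf, i, basis_size) for i in range(nm)]
    pair = {}
    for (i, j), C in surf.poly2.items():
        pair[(i, j)] = np.einsum("kl,kmn,lpq->mnpq", C, ops[i].Q[1:], ops[j].Q[1:])
    gs = [np.eye(basis_size)[:, 0] for _ in range(nm)]
    modal_mats = [np.eye(basis_size) for _ in range(nm)]

    def run(damping):
        nonlocal gs, modal_mats
        E_old = np.inf
        for _ in range(max_iter):
            e_modes = []
            for i in range(nm):
                F = ops[i].core.copy()
                for (a, b), P in pair.items():
                    if a == i:
                        F = F + np.einsum("mnpq,p,q->mn", P, gs[b], gs[b])
                    elif b == i:
                        F = F + np.einsum("mnpq,m,n->pq", P, gs[a], gs[a])
                w, Umat = np.linalg.eigh(F)
                new = Umat[:, 0]
                if new @ gs[i] < 0:
                    new = -new
                gs[i] = damping * gs[i] + (1 - damping) * new
                gs[i] /= np.linalg.norm(gs[i])
                modal_mats[i] = Umat
                e_modes.append(w[0])
            double = sum(
                np.einsum("mnpq,m,n,p,q->", P, gs[a], gs[a], gs[b], gs[b])
                for (a, b), P in pair.items()
            )
            E = float(sum(e_modes) - double)
            if abs(E - E_old) < tol:
                return E
            E_old = E
        return None

    E = run(0.0)
    if E is None:
        E = run(0.5)
    if E is None:
        raise RuntimeError("VSCF failed to converge (oscillation persisted)")
    return modal_mats, E, ops


# ---------------------------------------------------------------------------
# VCISD


@dataclass
class LocalState:
    """A single-well vibrational eigenstate of the VCISD Hamiltonian."""

    label: tuple
    energy: float
    ci_vector: np.ndarray
    well: str = ""
    ambiguous: bool = False

    def __str__(self):
        name = "GS" if sum(self.label) == 0 else "+".join(
            f"nu{i + 1}" for i, q in enumerate(self.label) for _ in range(q)
        )
        return f"{name}({self.well})" if self.well else name


def _ci_space(n_modes: int, max_quanta: int):
    """Singles + doubles configurations: at most two modes excited."""
    confs = [tuple([0] * n_modes)]
    for i in range(n_modes):
        for q in range(1, max_quanta + 1):
            c = [0] * n_modes
            c[i] = q
            confs.append(tuple(c))
    for i, j in itertools.combinations(range(n_modes), 2):
        for qi in range(1, max_quanta + 1):
            for qj in range(1, max_quanta + 1):
                c = [0] * n_modes
                c[i], c[j] = qi, qj
                confs.append(tuple(c))
    return confs


def vcisd_solve(surf: NModeSurface, modals, ops, *, max_quanta: int = 6,
                well_label: str = "", n_states: int | None = None):
    """Diagonalize the vibrational Hamiltonian in the VSCF-modal CI space.

    Configurations are VSCF-modal products with at most two modes excited
    and at most ``max_quanta`` quanta per mode.  Returned states carry
    absolute energies (well reference V0 included) sorted ascending and
    labels from the dominant CI coefficient.
    """
    nm = surf.n_modes
    nb = modals[0].shape[0]
    if max_quanta + 1 > nb:
        raise ValueError("max_quanta exceeds the modal space")
    core_m = [modals[i].T @ ops[i].core @ modals[i] for i in range(nm)]
    Qm = [np.einsum("kmn,mi,nj->kij", ops[i].Q[1:], modals[i], modals[i])
          for i in range(nm)]
    pair_m = {}
    for (i, j), C in surf.poly2.items():
        pair_m[(i, j)] = np.einsum("kl,kac,lbd->acbd", C, Qm[i], Qm[j])
    confs = _ci_space(nm, max_quanta)
    dim = len(confs)
    H = np.zeros((dim, dim))
    for p, cp in enumerate(confs):
        for r in range(p, dim):
            cr = confs[r]
            diff = [k for k in range(nm) if cp[k] != cr[k]]
            if len(diff) > 2:
                continue
            val = 0.0
            if len(diff) == 0:
                val += sum(core_m[k][cp[k], cp[k]] for k in range(nm))
            elif len(diff) == 1:
                k = diff[0]
                val += core_m[k][cp[k], cr[k]]
            for (i, j), P in pair_m.items():
                others = [k for k in diff if k not in (i, j)]
                if others:
                    continue
                val += P[cp[i], cr[i], cp[j], cr[j]]
            H[p, r] = H[r, p] = val
    ev, evec = np.linalg.eigh(H)
    states = []
    n_keep = dim if n_states is None else min(n_states, dim)
    for k in range(n_keep):
        weights = evec[:, k] ** 2
        top = np.argsort(weights)[::-1]
        ambiguous = bool(weights[top[1]] > 0.9 * weights[top[0]]) if dim > 1 else False
        states.append(LocalState(
            label=confs[int(top[0])],
            energy=float(ev[k] + surf.well.energy),
            ci_vector=evec[:, k],
            well=well_label,
            ambiguous=ambiguous,
        ))
    return states


def solve_well_vci(pes: PotentialSurface, well: Well, *, n_dvr: int = 8,
                   fit_order: int = 8, basis_size: int = 7, max_quanta: int = 6,
                   well_label: str = "", n_states: int | None = None):
    """End-to-end local spectrum of one well (surface -> VSCF -> VCISD)."""
    surf = build_nmode_surface(pes, well, n_dvr=n_dvr, fit_order=fit_order)
    modals, E_vscf, ops = vscf_solve(surf, basis_size=basis_size)
    states = vcisd_solve(surf, modals, ops, max_quanta=max_quanta,
                         well_label=well_label, n_states=n_states)
    return states, surf, E_vscf


def local_spectrum_report(states, *, unit: float = 1.0):
    """States as a tidy DataFrame: label, energy, energy above local GS."""
    import pandas as pd

    e0 = states[0].energy
    rows = []
    for st in states:
        w = st.ci_vector ** 2
        lead = float(np.max(w))
        rows.append({
            "label": str(st), "quanta": st.label,
            "energy": st.energy * unit,
            "relative": (st.energy - e0) * unit,
            "leading_weight": lead,
            "ambiguous": st.ambiguous,
        })
    return pd.DataFrame(rows)
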