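"""Potential-energy surfaces, mass scaling, and stationary-point analysis.

All tunneling machinery in this package operates in *mass-scaled* Cartesian
coordinates, ``xt = sqrt(m) * x``, in which the kinetic-energy metric is the
identity and classical dynamics reduces to unit-mass motion.  This module
provides

* the :class:`PotentialSurface` contract (energy / gradient / Hessian),
* the built-in two-dimensional double-well benchmark potential
  (:class:`Model2D` and :class:`Model2DParams`),
* mass-scaling wrappers and a plug-in registry for molecular surfaces,
* stationary-point characterization (:func:`characterize_minimum`),
  translation/rotation projection and the positive-semidefinite matrix
  square root used to initialize the instanton width matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "PotentialSurface",
    "Model2DParams",
    "Model2D",
    "MassScaledPES",
    "CallablePES",
    "Well",
    "characterize_minimum",
    "project_trans_rot",
    "matrix_sqrt_psd",
    "register_pes",
    "get_pes",
    "load_xyz",
    "ATOMIC_MASSES",
]

#: Atomic masses in electron-mass units (me), for the molecular adapter.
ATOMIC_MASSES = {
    "H": 1837.152646,
    "D": 3671.482935,
    "C": 21894.16673,
    "N": 25532.65222,
    "O": 29156.94568,
    "S": 58441.80487,
}

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class PotentialSurface:
    """Contract for a potential-energy surface in mass-scaled coordinates.

    Subclasses implement :meth:`energy` and :meth:`gradient`; the Hessian
    defaults to symmetrized central differences of the gradient (step
    ``hess_step`` in mass-scaled units), which is exact enough (error
    ~1e-9 on unit-scale surfaces) for the Riccati width propagation.

    Attributes
    ----------
    dimension : int
        Number of mass-scaled Cartesian coordinates.
    masses : ndarray
        Per-coordinate masses used for the scaling (unit metric after it).
    """

    dimension: int = 0
    masses: np.ndarray | None = None
    hess_step: float = 1e-6

    def energy(self, x):
        raise NotImplementedError

    def gradient(self, x):
        raise NotImplementedError

    def hessian(self, x):
        x = np.asarray(x, float)
        n = x.shape[-1]
        h = self.hess_step
        H = np.empty(x.shape[:-1] + (n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = h
            H[..., i, :] = (self.gradient(x + e) - self.gradient(x - e)) / (2 * h)
        return 0.5 * (H + np.swapaxes(H, -1, -2))


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class Model2DParams:
    """Parameters of the built-in 2D double-well benchmark potential.

    The two wells sit at ``x = (-beta, 0)`` and ``(+beta, 0)`` (plain, not
    mass-scaled, coordinates).  Each well is exactly harmonic at its minimum
    with Hessian eigenvalues ``(alpha1, alpha2)`` and normal modes inclined
    by ``+theta`` (left) / ``-theta`` (right) to the x axis, so that for
    equal parameters the surface has the mirror symmetry x -> -x.  The right
    minimum can be shifted up in energy by ``d`` without changing either
    well's shape.  Harmonic frequencies are ``omega_i = sqrt(alpha_i / m)``.
    """

    alpha1_L: float = 1.6
    alpha2_L: float = 4.0
    alpha1_R: float = 1.6
    alpha2_R: float = 4.0
    beta: float = 2.0
    theta: float = np.pi / 12
    d: float = 0.0
    m: float = 3.5

    @property
    def x_L(self):
        return np.array([-self.beta, 0.0])

    @property
    def x_R(self):
        return np.array([self.beta, 0.0])

    def well_hessians(self):
        UL = _rotation(self.theta)
        UR = _rotation(-self.theta)
        HL = UL @ np.diag([self.alpha1_L, self.alpha2_L]) @ UL.T
        HR = UR @ np.diag([self.alpha1_R, self.alpha2_R]) @ UR.T
        return HL, HR

    def frequencies(self, side: str):
        a1, a2 = (
            (self.alpha1_L, self.alpha2_L)
            if side == "L"
            else (self.alpha1_R, self.alpha2_R)
        )
        return np.sqrt(np.array([a1, a2]) / self.m)


class Model2D(PotentialSurface):
    """The 2D double-well benchmark surface, in mass-scaled coordinates.

    The surface blends the two exact harmonic wells,

        ``V_0 = V_L V_R / (V_L + V_R)``,

    where ``V_{L/R}`` are the quadratic forms of the two minima, and adds the
    right-well energy offset through the quartically flat switch

        ``V = V_0 + d * V_L^2 / (V_L^2 + V_R^2)``.

    Both constructions leave the minima, the minimum energies (0 and ``d``)
    and the Hessians at the minima *exactly* at their prescribed values: near
    either minimum the leading corrections to the pure harmonic well are
    quartic in the displacement.  A startup self-check asserts the harmonic
    limits; it can be disabled with ``check=False``.

    Energies are reported relative to the left minimum, V(x_L) = 0.
    """

    def __init__(self, params: Model2DParams | None = None, check: bool = True,
                 **kwargs):
        if params is None:
            params = Model2DParams(**kwargs)
        elif kwargs:
            raise TypeError("pass either params or keyword overrides, not both")
        self.params = params
        self.dimension = 2
        self.masses = np.full(2, params.m)
        self._sm = np.sqrt(params.m)
        self._HL, self._HR = params.well_hessians()
        if check:
            self._self_check()

    # -- plain (unscaled) coordinate forms --------------------------------
    def _uv(self, x):
        dL = x - self.params.x_L
        dR = x - self.params.x_R
        u = 0.5 * np.einsum("...i,ij,...j->...", dL, self._HL, dL)
        w = 0.5 * np.einsum("...i,ij,...j->...", dR, self._HR, dR)
        return dL, dR, u, w

    def energy_plain(self, x):
        """V at plain (not mass-scaled) coordinates ``x``."""
        x = np.asarray(x, float)
        _, _, u, w = self._uv(x)
        s = u + w
        with np.errstate(invalid="ignore", divide="ignore"):
            v0 = np.where(s > 0, u * w / np.where(s > 0, s, 1.0), 0.0)
            q = u * u + w * w
            sw = np.where(q > 0, u * u / np.where(q > 0, q, 1.0), 0.0)
        return v0 + self.params.d * sw

    def gradient_plain(self, x):
        x = np.asarray(x, float)
        dL, dR, u, w = self._uv(x)
        gu = dL @ self._HL
        gw = dR @ self._HR
        s = (u + w)[..., None]
        u_ = u[..., None]
        w_ = w[..., None]
        with np.errstate(invalid="ignore", divide="ignore"):
            g0 = np.where(s > 0, (w_**2 * gu + u_**2 * gw) / np.where(s > 0, s, 1.0) ** 2, 0.0)
            q = (u * u + w * w)[..., None]
            gs = np.where(
                q > 0,
                2 * u_ * w_ * (w_ * gu - u_ * gw) / np.where(q > 0, q, 1.0) ** 2,
                0.0,
            )
        return g0 + self.params.d * gs

    # -- mass-scaled contract ---------------------------------------------
    def energy(self, xt):
        return self.energy_plain(np.asarray(xt, float) / self._sm)

    def gradient(self, xt):
        return self.gradient_plain(np.asarray(xt, float) / self._sm) / self._sm

    @property
    def minima(self):
        """Mass-scaled coordinates of the two minima (left, right)."""
        return self.params.x_L * self._sm, self.params.x_R * self._sm

    def _self_check(self):
        p = self.params
        for xm, val, Href in ((p.x_L, 0.0, self._HL), (p.x_R, p.d, self._HR)):
            if abs(self.energy_plain(xm) - val) > 1e-10:
                raise RuntimeError("model self-check: minimum energy off")
            if np.linalg.norm(self.gradient_plain(xm)) > 1e-10:
                raise RuntimeError("model self-check: nonzero gradient at minimum")
            Hms = self.hessian(xm * self._sm)
            ev = np.sort(np.linalg.eigvalsh(Hms)) * p.m
            if np.max(np.abs(ev - np.sort(np.linalg.eigvalsh(Href)))) > 1e-6:
                raise RuntimeError("model self-check: harmonic limit violated")


class MassScaledPES(PotentialSurface):
    """Wrap plain-coordinate callables into the mass-scaled contract.

    Parameters
    ----------
    energy, gradient : callable
        Functions of plain Cartesian coordinates (shape ``(n,)``).
    masses : array_like
        Per-coordinate masses (each atomic mass repeated 3x for molecules).
    hessian : callable, optional
        Plain-coordinate Hessian; finite differences of the gradient are
        used when absent.
    """

    def __init__(self, energy, gradient, masses, hessian=None):
        self.masses = np.asarray(masses, float)
        self.dimension = len(self.masses)
        self._sqm = np.sqrt(self.masses)
        self._e = energy
        self._g = gradient
        self._h = hessian

    def energy(self, xt):
        xt = np.asarray(xt, float)
        if xt.ndim == 1:
            return self._e(xt / self._sqm)
        return np.array([self._e(row / self._sqm) for row in xt.reshape(-1, xt.shape[-1])]).reshape(xt.shape[:-1])

    def gradient(self, xt):
        xt = np.asarray(xt, float)
        if xt.ndim == 1:
            return self._g(xt / self._sqm) / self._sqm
        flat = xt.reshape(-1, xt.shape[-1])
        return np.array([self._g(row / self._sqm) / self._sqm for row in flat]).reshape(xt.shape)

    def hessian(self, xt):
        if self._h is None:
            return super().hessian(xt)
        xt = np.asarray(xt, float)
        if xt.ndim == 1:
            return self._h(xt / self._sqm) / np.outer(self._sqm, self._sqm)
        flat = xt.reshape(-1, xt.shape[-1])
        out = np.array([self._h(row / self._sqm) / np.outer(self._sqm, self._sqm) for row in flat])
        return out.reshape(xt.shape + (xt.shape[-1],))


class CallablePES(PotentialSurface):
    """A PES already expressed in mass-scaled coordinates."""

    def __init__(self, energy, gradient, dimension, masses=None, hessian=None):
        self.dimension = dimension
        self.masses = np.ones(dimension) if masses is None else np.asarray(masses, float)
        self._e, self._g, self._h = energy, gradient, hessian

    def energy(self, x):
        return self._e(np.asarray(x, float))

    def gradient(self, x):
        return self._g(np.asarray(x, float))

    def hessian(self, x):
        if self._h is None:
            return super().hessian(x)
        return self._h(np.asarray(x, float))


# ---------------------------------------------------------------------------
# plug-in registry

_PES_REGISTRY: dict[str, object] = {}


def register_pes(name: str, factory):
    """Register a PES factory under a string key for config-driven runs."""
    _PES_REGISTRY[name] = factory


def get_pes(name: str, **kwargs) -> PotentialSurface:
    if name not in _PES_REGISTRY:
        raise KeyError(
            f"unknown PES {name!r}; registered: {sorted(_PES_REGISTRY)}"
        )
    return _PES_REGISTRY[name](**kwargs)


register_pes("model2d", lambda **kw: Model2D(**kw))


# ---------------------------------------------------------------------------
# stationary points


@dataclass
class Well:
    """A characterized potential minimum.

    ``hessian0`` is the (trans/rot-projected, for molecules) mass-scaled
    Hessian at the refined minimum, ``normal_modes`` its eigenvectors in
    columns, ``frequencies`` the square roots of its non-negative
    eigenvalues sorted ascending, and ``A0 = hessian0^(1/2)`` the initial
    Gaussian width matrix of the semiclassical well wavefunction.
    """

    geometry: np.ndarray
    energy: float
    hessian0: np.ndarray
    normal_modes: np.ndarray
    frequencies: np.ndarray
    A0: np.ndarray
    n_zero: int = 0
    label: str = ""

    def harmonic_energy(self, quanta=None) -> float:
        """Local harmonic energy for per-mode quanta (ground state default)."""
        nq = np.zeros(len(self.frequencies)) if quanta is None else np.asarray(quanta, float)
        return self.energy + float(np.sum((nq + 0.5) * self.frequencies))


def matrix_sqrt_psd(h: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric PSD square root; small negative eigenvalues are clipped.

    Eigenvalues below ``-tol * max|eig|`` indicate the input is not a
    (projected) minimum Hessian and raise ``ValueError``.
    """
    h = np.asarray(h, float)
    w, U = np.linalg.eigh(0.5 * (h + h.T))
    scale = max(np.max(np.abs(w)), 1.0)
    if np.min(w) < -tol * scale:
        raise ValueError(f"matrix has significantly negative eigenvalue {np.min(w):g}")
    w = np.clip(w, 0.0, None)
    return (U * np.sqrt(w)) @ U.T


def project_trans_rot(hessian, geometry=None, masses=None, linear=False):
    """Project overall translations and rotations out of a mass-scaled Hessian.

    For a molecular geometry (``geometry`` as ``(n_atoms, 3)`` plain
    Cartesians with per-atom ``masses``) the projector removes the 3
    translational and 3 (2 if ``linear``) rotational directions:
    ``H_proj = P H P``.  With ``geometry=None`` the Hessian is returned
    unchanged (the low-dimensional model case has no such motions).
    """
    H = np.asarray(hessian, float)
    if geometry is None:
        return H.copy()
    geom = np.asarray(geometry, float).reshape(-1, 3)
    m = np.asarray(masses, float)
    if len(m) != len(geom) or len(geom) < 2:
        raise ValueError("need per-atom masses and >= 2 atoms")
    sqm = np.sqrt(m)
    com = (m[:, None] * geom).sum(0) / m.sum()
    x = geom - com
    vecs = []
    for k in range(3):  # translations, mass-weighted
        t = np.zeros_like(geom)
        t[:, k] = sqm
        vecs.append(t.ravel())
    axes = np.eye(3)
    n_rot = 2 if linear else 3
    for k in range(3):  # rotations: sqrt(m) * (e_k x r)
        r = np.cross(np.broadcast_to(axes[k], x.shape), x) * sqm[:, None]
        vecs.append(r.ravel())
    B = np.array(vecs).T
    # orthonormalize, drop null rotations (linear molecules)
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
    n_expected = 3 + n_rot
    if keep.sum() != n_expected:
        raise ValueError(
            f"trans/rot nullspace has {int(keep.sum())} vectors, expected "
            f"{n_expected}; check the `linear` flag"
        )
    q = q[:, keep]
    P = np.eye(H.shape[0]) - q @ q.T
    return P @ H @ P


def characterize_minimum(pes: PotentialSurface, x_guess, *, grad_tol=1e-9,
                         geometry=None, atom_masses=None, linear=False,
                         zero_tol=1e-8, label="") -> Well:
    """Refine a minimum of ``pes`` and build its :class:`Well` record.

    The guess is polished with BFGS on the mass-scaled surface down to
    ``grad_tol`` in the gradient norm; the (projected) Hessian there must be
    positive semidefinite apart from the trans/rot nullspace, otherwise the
    point is a saddle and ``ValueError`` is raised.  Frequencies are sorted
    ascending with the associated normal modes in matching columns.
    """
    x0 = np.asarray(x_guess, float)
    res = minimize(pes.energy, x0, jac=pes.gradient, method="BFGS",
                   options=dict(gtol=grad_tol * 0.1, maxiter=500))
    x_min = res.x
    if np.linalg.norm(pes.gradient(x_min)) > grad_tol:
        # polish once more from the BFGS endpoint with tighter settings
        res = minimize(pes.energy, x_min, jac=pes.gradient, method="BFGS",
                       options=dict(gtol=grad_tol * 1e-3, maxiter=1000))
        x_min = res.x
    g = np.linalg.norm(pes.gradient(x_min))
    if g > grad_tol * 10:
        raise ValueError(f"minimum refinement stalled, |grad| = {g:g}")
    H = pes.hessian(x_min)
    if geometry is not None:
        H = project_trans_rot(H, geometry=geometry, masses=atom_masses, linear=linear)
    w, U = np.linalg.eigh(H)
    scale = max(np.max(np.abs(w)), 1.0)
    zero = np.abs(w) < zero_tol * scale
    if np.any(w < -zero_tol * scale):
        raise ValueError("stationary point has a negative curvature: saddle/maximum")
    nz = ~zero
    order = np.argsort(w[nz])
    freqs = np.sqrt(w[nz][order])
    modes = U[:, nz][:, order]
    return Well(
        geometry=x_min,
        energy=float(pes.energy(x_min)),
        hessian0=H,
        normal_modes=modes,
        frequencies=freqs,
        A0=matrix_sqrt_psd(H),
        n_zero=int(zero.sum()),
        label=label,
    )


# ---------------------------------------------------------------------------
# molecular geometry input


def load_xyz(source) -> tuple[list[str], np.ndarray]:
    """Read an XYZ-format geometry (element, x, y, z in Angstrom).

    Returns the element symbols and coordinates in bohr.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    lines = [ln for ln in io.StringIO(text)]
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError("not an XYZ file: first line must be the atom count") from exc
    symbols, coords = [], []
    for ln in lines[2 : 2 + natoms]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    if len(symbols) != natoms:
        raise ValueError("XYZ file truncated")
    return symbols, np.asarray(coords) * BOHR_PER_ANGSTROM
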