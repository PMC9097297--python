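"""Tunneling-matrix assembly, diagonalization and derived observables.

The vibrational Hamiltonian in the basis of well-localized states is the
block matrix

    [ E^(L)   h    ]
    [ h^T     E^(R)],

with diagonal blocks holding the local vibrational energies (harmonic or
VCI; intra-well off-diagonal elements are neglected by construction) and
the off-diagonal block the Herring couplings from the instanton module.
Diagonalizing it yields the tunneling spectrum; this module also derives
doublet splittings, mixing angles and avoided-crossing locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TunnelingMatrixModel",
    "SpectrumResult",
    "assemble_tm",
    "spectrum",
    "pair_splitting",
    "mixing_angle",
    "locate_avoided_crossing",
]


@dataclass
class TunnelingMatrixModel:
    """Assembled block tunneling matrix with its state bookkeeping."""

    labels_L: list
    labels_R: list
    energies_L: np.ndarray
    energies_R: np.ndarray
    h_block: np.ndarray
    h_asymmetry: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        nL, nR = len(self.energies_L), len(self.energies_R)
        M = np.zeros((nL + nR, nL + nR))
        M[:nL, :nL] = np.diag(self.energies_L)
        M[nL:, nL:] = np.diag(self.energies_R)
        M[:nL, nL:] = self.h_block
        M[nL:, :nL] = self.h_block.T
        return M

    @property
    def labels(self):
        return ([f"{l}(L)" for l in self.labels_L]
                + [f"{l}(R)" for l in self.labels_R])


@dataclass
class SpectrumResult:
    """Eigen-decomposition of a tunneling matrix with doublet analysis."""

    levels: np.ndarray
    vectors: np.ndarray
    labels: list
    n_left: int
    doublets: list = field(default_factory=list)
    splittings: dict = field(default_factory=dict)

    def configurations(self, level: int, n_top: int = 3):
        """Dominant local-state compositions of one eigenstate."""
        w = self.vectors[:, level] ** 2
        top = np.argsort(w)[::-1][:n_top]
        return [(self.labels[i], float(w[i])) for i in top]

    def well_weights(self, level: int):
        w = self.vectors[:, level] ** 2
        return float(w[: self.n_left].sum()), float(w[self.n_left:].sum())

    def report(self) -> pd.DataFrame:
        rows = []
        for k in range(len(self.levels)):
            confs = self.configurations(k)
            rows.append({
                "level": k + 1,
                "energy": self.levels[k],
                "dominant": "; ".join(f"{l}:{w:.2f}" for l, w in confs),
            })
        return pd.DataFrame(rows)


def assemble_tm(local_L, local_R, h_block, *, model_size="all",
                symmetrize: bool = False, zero_pattern=None) -> TunnelingMatrixModel:
    """Build the block tunneling matrix from local states and couplings.

    Parameters
    ----------
    local_L, local_R : sequences of (label, energy) pairs or objects with
        ``label`` and ``energy`` attributes.
    h_block : (nL, nR) couplings.  The assembled matrix
        ``[[E_L, h], [h^T, E_R]]`` is symmetric by construction; ``h[i, j]``
        and ``h[j, i]`` are couplings between *different* state pairs and
        are never mixed.  For symmetric wells with a one-to-one mode
        correspondence they should nearly coincide; ``h_asymmetry`` records
        ``max |h - h^T|`` as a diagnostic, and ``symmetrize=True``
        additionally averages the two (only meaningful in that symmetric
        case).
    model_size : "pairs" | int | "all"
        "pairs" keeps corresponding states only (labels must match
        one-to-one); an integer keeps the lowest k states per well.
    zero_pattern : optional boolean mask forcing symmetry-forbidden
        couplings to exact zero (mirror-symmetric surfaces).
    """
    def unpack(seq):
        labels, energies = [], []
        for item in seq:
            if hasattr(item, "label"):
                labels.append(str(item))
                energies.append(item.energy)
            else:
                lab, en = item
                labels.append(str(lab))
                energies.append(float(en))
        return labels, np.array(energies)

    lab_L, E_L = unpack(local_L)
    lab_R, E_R = unpack(local_R)
    h = np.atleast_2d(np.asarray(h_block, float))
    if h.shape != (len(E_L), len(E_R)):
        raise ValueError(f"h block shape {h.shape} does not match state counts")
    if model_size == "pairs":
        strip = [l.split("(")[0] for l in lab_L]
        strip_R = [l.split("(")[0] for l in lab_R]
        if strip != strip_R:
            raise ValueError(
                "pairs model needs an approximate one-to-one mode "
                f"correspondence; labels differ: {strip} vs {strip_R}"
            )
    elif model_size != "all":
        k = int(model_size)
        oL = np.argsort(E_L)[:k]
        oR = np.argsort(E_R)[:k]
        lab_L = [lab_L[i] for i in oL]
        lab_R = [lab_R[i] for i in oR]
        E_L, E_R = E_L[oL], E_R[oR]
        h = h[np.ix_(oL, oR)]
    asym = 0.0
    if h.shape[0] == h.shape[1]:
        asym = float(np.abs(h - h.T).max())
        if symmetrize:
            h = 0.5 * (h + h.T)
    if zero_pattern is not None:
        h = np.where(np.asarray(zero_pattern, bool), 0.0, h)
    return TunnelingMatrixModel(lab_L, lab_R, E_L, E_R, h, h_asymmetry=asym)


def spectrum(tm: TunnelingMatrixModel) -> SpectrumResult:
    """Diagonalize the tunneling matrix and identify doublets.

    Doublets are pairs of eigenstates sharing the same dominant local-state
    pair (the L and R partners of one mode label); ties are broken by
    energy adjacency.  Splittings are recorded per doublet.
    """
    M = tm.matrix
    ev, vec = np.linalg.eigh(M)
    res = SpectrumResult(levels=ev, vectors=vec, labels=tm.labels,
                         n_left=len(tm.energies_L))
    strip = [l.split("(")[0] for l in tm.labels]
    mode_names = sorted(set(strip))
    # dominant mode label of each eigenstate: weight summed over both wells
    dom = []
    for k in range(len(ev)):
        w = vec[:, k] ** 2
        totals = {m: float(sum(w[i] for i in range(len(w)) if strip[i] == m))
                  for m in mode_names}
        dom.append(max(totals, key=totals.get))
    # a doublet = two consecutive (energy-ordered) states sharing the mode
    grouped: dict = {}
    for k in range(len(ev)):
        grouped.setdefault(dom[k], []).append(k)
    for mode, members in grouped.items():
        for a, b in zip(members[0::2], members[1::2]):
            res.doublets.append((a, b))
            res.splittings.setdefault(mode, float(abs(ev[b] - ev[a])))
    res.doublets.sort()
    return res


def pair_splitting(E_L: float, E_R: float, h: float):
    """Two-level gap and its weak-coupling expansion.

    Returns ``(exact, expansion)`` where ``exact = sqrt(dE^2 + 4 h^2)`` and
    ``expansion = |dE| + 2 h^2 / |dE|`` (the second-order perturbative form,
    valid for |h| << |dE|; residual O(h^4 / dE^3)).  For degenerate levels
    the expansion equals the exact value 2|h|.
    """
    dE = E_L - E_R
    exact = float(np.hypot(dE, 2.0 * h))
    expansion = float(abs(dE) + 2.0 * h * h / abs(dE)) if dE != 0 else float(2 * abs(h))
    return exact, expansion


def mixing_angle(arg, level: int | None = None) -> float:
    """Left-right mixing angle of a doublet, in degrees.

    For a 2x2 pair ``(E_L, E_R, h)`` the angle is
    ``phi = arctan(2 |h| / |E_L - E_R|)``; at exact resonance the states
    are fully delocalized and phi = 90 deg, while phi -> 0 marks
    localization.  For a :class:`SpectrumResult` the generalized form reads
    the rotation off the doublet's two eigenvectors restricted to the
    doublet's own L/R components, ``phi = arctan|c_R/c_L| (lower) +
    arctan|c_L/c_R| (upper)``; in the 2x2 case both terms equal the
    rotation angle and the pair formula is recovered exactly.
    """
    if isinstance(arg, SpectrumResult):
        if not arg.doublets:
            raise ValueError("no doublet identified; inspect well_weights per level")
        if level is None:
            level = min(arg.doublets[0])
        pair = next((p for p in arg.doublets if level in p), None)
        if pair is None:
            raise ValueError(f"level {level} is not part of an identified doublet")
        lo, hi = sorted(pair)
        strip = [l.split("(")[0] for l in arg.labels]
        w = arg.vectors[:, lo] ** 2 + arg.vectors[:, hi] ** 2
        mode = strip[int(np.argmax(w))]
        iL = strip.index(mode)
        iR = arg.n_left + strip[arg.n_left:].index(mode)
        c1L, c1R = arg.vectors[iL, lo], arg.vectors[iR, lo]
        c2L, c2R = arg.vectors[iL, hi], arg.vectors[iR, hi]
        chi = 0.5 * (np.arctan2(abs(c1R), abs(c1L)) + np.arctan2(abs(c2L), abs(c2R)))
        return float(np.degrees(2.0 * chi))
    E_L, E_R, h = arg
    dE = abs(E_L - E_R)
    if dE == 0:
        return 90.0
    return float(np.degrees(np.arctan(2.0 * abs(h) / dE)))


def locate_avoided_crossing(param_grid, gap_function, *, refine_tol=1e-5):
    """Locate the minimal gap of an avoided crossing along a 1D sweep.

    ``gap_function(p)`` returns the tracked level gap at parameter ``p``.
    The grid scan brackets the minimum; a bounded golden-section/Brent
    refinement inside the bracketing cell returns the crossing parameter
    and minimal gap.  Without an interior bracket the grid minimum is
    returned with ``bracketed=False``.
    """
    from scipy.optimize import minimize_scalar

    grid = np.asarray(param_grid, float)
    gaps = np.array([gap_function(p) for p in grid])
    k = int(np.argmin(gaps))
    if k == 0 or k == len(grid) - 1:
        return {"param": float(grid[k]), "gap": float(gaps[k]),
                "bracketed": False, "grid_gaps": gaps}
    r = minimize_scalar(gap_function, bounds=(grid[k - 1], grid[k + 1]),
                        method="bounded", options=dict(xatol=refine_tol))
    return {"param": float(r.x), "gap": float(r.fun), "bracketed": True,
            "grid_gaps": gaps}
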