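"""Shared fixtures: the benchmark surface, one converged path, both fields.

The expensive objects (string optimization, width propagation, the exact
DVR reference) are session-scoped; individual tests treat them as
read-only.
"""

import numpy as np
import pytest

from tunspec import workflows as wf
from tunspec.instanton import InstantonField
from tunspec.pathfinder import optimize_map


@pytest.fixture(scope="session")
def model_sym():
    """Symmetric benchmark surface with both wells characterized."""
    return wf.build_model()


@pytest.fixture(scope="session")
def path_sym(model_sym):
    pes, wellL, wellR = model_sym
    return optimize_map(pes, wellL, wellR, n_beads=301, tol=1e-6)


@pytest.fixture(scope="session")
def fields_sym(model_sym, path_sym):
    _, wellL, wellR = model_sym
    fL = InstantonField(path_sym, wellL, "L", epsilon=0.1)
    fR = InstantonField(path_sym, wellR, "R", epsilon=0.1)
    return fL, fR


@pytest.fixture(scope="session")
def dvr_sym(model_sym):
    """Exact levels of the symmetric surface (gate exercised separately)."""
    pes, *_ = model_sym
    ev, vec, grid, axes = wf.qm_levels(pes, n_levels=8, n_points=128,
                                       check_convergence=False)
    return ev, vec, grid, axes


@pytest.fixture(scope="session")
def separable_model():
    """theta = 0: the surface separates into double-well (x) x harmonic (y)."""
    return wf.build_model(theta=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220419)
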