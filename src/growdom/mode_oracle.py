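"""Per-mode matrix-exponential solver, valid for any rate pattern.

In the boundary-fixed frame every cosine mode evolves independently: the
diffusive and dilution factors are shared by all generations, while the
reaction chain mixes generation amplitudes through the constant lower-
bidiagonal matrix K.  Writing

    C_i(x, t) = sum_n g_n(t) cos(n pi x/L(t)) b_{n,i}(t),
    g_n(t)    = exp(-(n pi)^2 T(t)) * L(0)/L(t),

the amplitude vectors satisfy the linear ODE db_n/dt = K b_n with
b_n(0) given by the per-generation initial Fourier coefficients, so
b_n(t) = expm(K t) b_n(0).  No uncoupling transformation is involved,
hence no distinct-rates restriction: this route is exact up to series
truncation for distinct, repeated, or mixed rate patterns alike, and
serves as an independent cross-check of the closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .exact_series import (
    DEFAULT_TRUNCATION,
    Problem,
    SolutionField,
    _mode_decay,
    _resolve_grid,
    general_ic_coefficients,
)

__all__ = ["evaluate_modal"]


def evaluate_modal(
    problem: Problem,
    grid,
    times,
    N: int = DEFAULT_TRUNCATION,
    grid_kind: str = "xi",
) -> SolutionField:
    """Evaluate all generation densities via per-mode matrix exponentials.

    Same grid semantics as :func:`growdom.exact_series.evaluate_coupled`;
    the G x G matrix exponential is computed densely (scaling and
    squaring), which is ample for the small generation counts tracked.
    """
    times, xi, x = _resolve_grid(problem, grid, times, grid_kind)
    G = problem.lineage.G
    K = problem.lineage.reaction_matrix()
    Psi0 = general_ic_coefficients(problem.ic, problem.growth.L0, N, G)  # (G, N+1)
    n_modes = np.arange(N + 1)
    nt, nx = xi.shape
    C = np.empty((nt, G, nx))
    for it, t in enumerate(times):
        t = float(t)
        B = expm(K * t) @ Psi0                          # amplitudes b_n(t), (G, N+1)
        g = _mode_decay(problem, N, t) * float(problem.growth.dilution_decay(t))
        cosmat = np.cos(np.outer(xi[it], n_modes) * np.pi)  # (nx, N+1)
        C[it] = (B * g) @ cosmat.T
    return SolutionField(times=times, xi=xi, x=x, C=C)
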