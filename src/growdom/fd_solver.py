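"""Finite-difference reference solution on the boundary-fixed domain.

In the coordinate xi = x/L(t) the growth advection cancels and the
coupled system becomes, on the fixed interval 0 < xi < 1,

    dC_i/dt = (D/L^2(t)) d2C_i/dxi2 - (k_i + sigma(t)) C_i
              + m k_{i-1} C_{i-1},

with zero-flux conditions at xi = 0, 1.  The scheme uses central second
differences with a ghost-point Neumann closure and backward Euler in
time for both the diffusion term (time-dependent coefficient D/L^2
evaluated at the new level) and the reaction terms; because the reaction
chain is lower bidiagonal, solving generations in order makes the step
fully implicit with one tridiagonal solve per generation.  Backward
Euler is unconditionally stable, so the default steps dxi = dt = 1e-3
used in the exact-vs-numerical comparisons are limited by accuracy
(first order in dt, second order in dxi), not stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import InvalidParameterError, SolverFailureError
from .exact_series import Problem, SolutionField

__all__ = ["FDConfig", "solve_fd", "initial_grid_values"]


@dataclass(frozen=True)
class FDConfig:
    """Finite-difference discretisation parameters.

    ``dxi`` must divide 1 exactly so the grid lands on both boundaries;
    ``dt`` is the (uniform) implicit time step.
    """

    dxi: float = 1e-3
    dt: float = 1e-3
    scheme: str = "backward-euler"

    def __post_init__(self):
        if self.dxi <= 0 or self.dt <= 0:
            raise InvalidParameterError("dxi and dt must be positive")
        n_cells = 1.0 / self.dxi
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise InvalidParameterError(f"1/dxi must be an integer, got dxi={self.dxi}")
        if self.scheme != "backward-euler":
            raise InvalidParameterError(f"unknown scheme {self.scheme!r}")

    @property
    def n_nodes(self) -> int:
        return int(round(1.0 / self.dxi)) + 1


def initial_grid_values(problem: Problem, xi: np.ndarray, dxi: float) -> np.ndarray:
    """Initial densities on the xi-grid, shape (G, n_nodes).

    A block (Heaviside) profile is discretised by cell averages: each node
    carries the mean density over its control volume [xi - dxi/2,
    xi + dxi/2] (half cells at the boundaries), so the node straddling the
    jump at gamma receives the fractional value.  This keeps the captured
    initial mass independent of where the jump falls relative to the grid.
    General profiles are sampled pointwise.
    """
    G = problem.lineage.G
    L0 = problem.growth.L0
    vals = np.zeros((G, xi.size))
    if problem.ic.kind == "block":
        edge = problem.ic.gamma / L0  # jump position in xi
        lo = np.maximum(xi - dxi / 2.0, 0.0)
        hi = np.minimum(xi + dxi / 2.0, 1.0)
        overlap = np.clip(np.minimum(hi, edge) - lo, 0.0, None)
        vals[0] = problem.ic.C0 * overlap / (hi - lo)
    else:
        assert problem.ic.profiles is not None
        for i in range(G):
            f = problem.ic.profiles[i] if i < len(problem.ic.profiles) else None
            if f is not None:
                vals[i] = np.vectorize(f, otypes=[float])(xi * L0)
    return vals


def solve_fd(
    problem: Problem,
    config: FDConfig,
    output_times: Sequence[float],
) -> SolutionField:
    """March the coupled system and record profiles at the requested times.

    Output times are snapped to the nearest multiple of dt (they differ
    from the request by at most dt/2).  Returns densities on the fixed
    xi-grid together with the corresponding physical coordinates.
    """
    output_times = np.atleast_1d(np.asarray(output_times, dtype=float))
    if np.any(output_times < 0):
        raise InvalidParameterError("output times must be nonnegative")
    dt = config.dt
    steps_out = np.rint(output_times / dt).astype(int)
    n_steps = int(steps_out.max(initial=0))

    M = config.n_nodes
    xi = np.linspace(0.0, 1.0, M)
    dxi = config.dxi
    G = problem.lineage.G
    k = np.asarray(problem.lineage.k)
    m = problem.lineage.m
    D = problem.D
    growth = problem.growth

    C = initial_grid_values(problem, xi, dxi)

    want = {s: i for i, s in enumerate(steps_out)}
    out = np.empty((output_times.size, G, M))
    if 0 in want:
        out[want[0]] = C

    # banded LHS template: ab[0] super-, ab[1] main, ab[2] sub-diagonal
    ab = np.zeros((3, M))
    inv_dxi2 = 1.0 / dxi**2

    for step in range(1, n_steps + 1):
        t_new = step * dt
        mu = dt * D / float(growth.length(t_new)) ** 2 * inv_dxi2
        sig = float(growth.sigma(t_new))
        ab[0, 1:] = -mu
        ab[2, :-1] = -mu
        # ghost-point Neumann closure doubles the single off-diagonal entry
        ab[0, 1] = -2.0 * mu
        ab[2, M - 2] = -2.0 * mu
        C_new = np.empty_like(C)
        for i in range(G):
            ab[1, :] = 1.0 + 2.0 * mu + dt * (k[i] + sig)
            rhs = C[i].copy()
            if i > 0:
                rhs += dt * m * k[i - 1] * C_new[i - 1]
            C_new[i] = solve_banded((1, 1), ab, rhs)
        C = C_new
        if not np.all(np.isfinite(C)):
            raise SolverFailureError(
                f"non-finite values at t={t_new:g}; reduce the time step dt={dt:g}"
            )
        if step in want:
            out[want[step]] = C

    t_snap = steps_out * dt
    L = np.atleast_1d(np.asarray(growth.length(t_snap), dtype=float))
    x = xi[None, :] * L[:, None]
    return SolutionField(
        times=t_snap,
        xi=np.broadcast_to(xi, (t_snap.size, M)).copy(),
        x=x,
        C=out,
    )
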