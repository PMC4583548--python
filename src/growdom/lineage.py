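"""Linear lineage (generation chain) reaction network.

Generation i is converted into generation i+1 at rate k_i; proliferation
produces m = 2 daughters per division, differentiation m = 1.  The
resulting reaction matrix K is lower bidiagonal,

    K[i, i]   = -k_i
    K[i, i-1] =  m * k_{i-1}

and, when all rates are pairwise distinct, the Sun-Clement change of
variables a = W C with the unit-lower-triangular matrix

    W[i, j] = prod_{l=j..i-1} m*k_l / (k_l - k_i)       (j < i, 1-based)

diagonalises it: W K W^{-1} = diag(-k_1, ..., -k_G).  Each uncoupled
variable a_i then satisfies an independent scalar reaction-diffusion
equation with rate k_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.linalg import solve_triangular

from .errors import DistinctRatesRequiredError, InvalidParameterError

__all__ = [
    "LineageModel",
    "reaction_matrix",
    "uncoupling_matrix",
    "inverse_uncoupling",
    "RATE_EQUALITY_RTOL",
]

# Two rates are treated as repeated when closer than this (relative) -- below
# it the uncoupling products are numerically singular and callers must use the
# closed-form limits or the per-mode matrix-exponential solver.
RATE_EQUALITY_RTOL = 1e-8


def _rates_equal(ki: float, kj: float) -> bool:
    return abs(ki - kj) <= RATE_EQUALITY_RTOL * max(1.0, abs(ki), abs(kj))


@dataclass(frozen=True)
class LineageModel:
    """A chain of G generations with per-generation conversion rates.

    Parameters
    ----------
    k
        Rates k_1..k_G (1/time) at which generation i converts into
        generation i+1.  Negative rates are accepted with a warning: the
        uncoupled equations can then be unbounded in time.
    m
        Amplification factor: 2 for proliferation (each division yields two
        daughters), 1 for differentiation (one-for-one conversion).  Other
        values are accepted but flagged, since their biological meaning is
        unclear.
    """

    k: Tuple[float, ...]
    m: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "k", tuple(float(v) for v in self.k))
        object.__setattr__(self, "m", float(self.m))
        if len(self.k) < 1:
            raise InvalidParameterError("at least one generation is required")
        if self.m not in (1.0, 2.0):
            warnings.warn(
                f"amplification factor m={self.m} is neither 1 (differentiation) "
                "nor 2 (proliferation); proceeding, but interpret with care",
                stacklevel=2,
            )
        if any(v < 0 for v in self.k):
            warnings.warn(
                "negative rate(s) supplied; the uncoupled solutions can be "
                "unbounded when k_i < 0",
                stacklevel=2,
            )

    @property
    def G(self) -> int:
        """Number of generations tracked."""
        return len(self.k)

    def rate_pattern(self) -> List[List[int]]:
        """Partition generation indices (0-based) into groups of equal rate.

        Equality is judged at :data:`RATE_EQUALITY_RTOL`; groups are returned
        in order of first appearance.
        """
        groups: List[List[int]] = []
        for i, ki in enumerate(self.k):
            for grp in groups:
                if _rates_equal(ki, self.k[grp[0]]):
                    grp.append(i)
                    break
            else:
                groups.append([i])
        return groups

    def has_distinct_rates(self) -> bool:
        return len(self.rate_pattern()) == self.G

    def reaction_matrix(self) -> np.ndarray:
        """Lower-bidiagonal reaction matrix K of the generation chain."""
        K = np.diag([-ki for ki in self.k]).astype(float)
        for i in range(1, self.G):
            K[i, i - 1] = self.m * self.k[i - 1]
        return K

    def uncoupling_matrix(self) -> np.ndarray:
        """Unit-lower-triangular W with W K W^{-1} = diag(-k).

        Raises
        ------
        DistinctRatesRequiredError
            If any two rates coincide (to :data:`RATE_EQUALITY_RTOL`); the
            transformation is singular there.
        """
        self._require_distinct()
        G = len(self.k)
        W = np.eye(G)
        for i in range(G):
            prod = 1.0
            # accumulate the product from l = i-1 down to j
            for j in range(i - 1, -1, -1):
                prod *= self.m * self.k[j] / (self.k[j] - self.k[i])
                W[i, j] = prod
        return W

    def inverse_uncoupling(self, a: np.ndarray) -> np.ndarray:
        """Recover coupled fields C from uncoupled fields a = W C.

        ``a`` has the generation axis first (shape (G,) or (G, ...)); the
        unit-lower-triangular system is solved by forward substitution, so
        the round trip through the transform is exact to rounding.
        """
        W = self.uncoupling_matrix()
        a = np.asarray(a, dtype=float)
        if a.shape[0] != self.G:
            raise InvalidParameterError(
                f"expected leading axis of length G={self.G}, got {a.shape[0]}"
            )
        flat = a.reshape(self.G, -1)
        C = solve_triangular(W, flat, lower=True, unit_diagonal=True)
        return C.reshape(a.shape)

    def _require_distinct(self) -> None:
        for i in range(self.G):
            for j in range(i + 1, self.G):
                if _rates_equal(self.k[i], self.k[j]):
                    raise DistinctRatesRequiredError(
                        f"rates k[{i + 1}]={self.k[i]} and k[{j + 1}]={self.k[j]} are "
                        "(numerically) equal; the uncoupling transformation is "
                        "singular -- use the repeated-rate closed forms or the "
                        "per-mode solver"
                    )


def reaction_matrix(model: LineageModel) -> np.ndarray:
    """Module-level wrapper for :meth:`LineageModel.reaction_matrix`."""
    return model.reaction_matrix()


def uncoupling_matrix(model: LineageModel) -> np.ndarray:
    """Module-level wrapper for :meth:`LineageModel.uncoupling_matrix`."""
    return model.uncoupling_matrix()


def inverse_uncoupling(model: LineageModel, a: np.ndarray) -> np.ndarray:
    """Module-level wrapper for :meth:`LineageModel.inverse_uncoupling`."""
    return model.inverse_uncoupling(a)
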