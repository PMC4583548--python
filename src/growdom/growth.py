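"""Uniform domain-growth laws for a 1-D interval 0 < x < L(t).

Uniform growth means the local stretch rate dv/dx is independent of
position, so the whole domain elongates at a common relative rate
sigma(t) = L'(t)/L(t) and the growth-induced velocity field is linear in
position, v(x, t) = x*sigma(t), with the origin held fixed.  The solvers
need four derived quantities from a growth law:

* ``length(t)``        -- L(t), the domain length;
* ``sigma(t)``         -- the dilution rate L'(t)/L(t);
* ``velocity(x, t)``   -- the advection velocity x*sigma(t);
* ``rescaled_time(D, t)`` -- T(t) = int_0^t D/L(s)^2 ds, the time variable
  in which the boundary-fixed diffusion coefficient becomes constant;
* ``dilution_decay(t)``   -- L(0)/L(t) = exp(-int_0^t sigma ds), the factor
  by which uniform growth dilutes a spatially constant density.

Exponential (L = L0*e^{alpha t}) and linear (L = L0 + beta*t) laws carry
closed forms for all of these; a custom law supplies L(t) only and the
rest is obtained by numerical differentiation and adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .errors import InvalidParameterError, NumericalIntegrationError

__all__ = [
    "GrowthLaw",
    "make_exponential",
    "make_linear",
    "make_custom",
    "rescaled_time",
    "dilution_decay",
]

# Relative step for finite-difference differentiation of ln L(t) (custom laws).
_FD_REL_STEP = 1e-6
# Absolute tolerance for adaptive quadrature of D/L^2 (custom laws).
_QUAD_ABS_TOL = 1e-12


@dataclass(frozen=True)
class GrowthLaw:
    """A uniform growth law for the domain 0 < x < L(t).

    Use :func:`make_exponential`, :func:`make_linear` or :func:`make_custom`
    instead of constructing instances directly.

    Parameters
    ----------
    kind
        ``"exponential"``, ``"linear"`` or ``"custom"``.
    L0
        Initial domain length L(0) > 0.
    alpha
        Relative elongation rate (1/time); exponential kind only.
    beta
        Absolute elongation rate (length/time); linear kind only.
    length_fn
        Callable t -> L(t); custom kind only.
    """

    kind: str
    L0: float
    alpha: Optional[float] = None
    beta: Optional[float] = None
    length_fn: Optional[Callable[[float], float]] = field(default=None, repr=False)

    # -- primitive quantities -------------------------------------------------

    def length(self, t):
        """Domain length L(t)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            out = self.L0 * np.exp(self.alpha * t)
        elif self.kind == "linear":
            out = self.L0 + self.beta * t
        else:
            out = np.vectorize(self.length_fn, otypes=[float])(t)
            if np.any(out <= 0.0):
                raise InvalidParameterError("custom growth law returned L(t) <= 0")
        return out[()] if out.ndim == 0 else out

    def sigma(self, t):
        """Dilution rate sigma(t) = L'(t)/L(t) (uniform growth)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            out = np.full_like(t, self.alpha, dtype=float)
        elif self.kind == "linear":
            out = self.beta / (self.L0 + self.beta * t)
        else:
            out = self._sigma_fd(t)
        return out[()] if out.ndim == 0 else out

    def _sigma_fd(self, t):
        # central difference of ln L; forward-biased near t = 0 so the stencil
        # never leaves the supported range t >= 0
        h = _FD_REL_STEP * np.maximum(1.0, np.abs(t))
        lo = np.maximum(t - h, 0.0)
        hi = lo + 2.0 * h
        out = (np.log(self.length(hi)) - np.log(self.length(lo))) / (2.0 * h)
        if np.any(out < -1e-9):
            raise InvalidParameterError(
                "custom growth law is shrinking (dL/dt < 0); only growth is supported"
            )
        return out

    def velocity(self, x, t):
        """Growth advection velocity v(x, t) = x*sigma(t); v(0, t) = 0."""
        return np.asarray(x, dtype=float) * self.sigma(t)

    # -- derived quantities used by the solvers --------------------------------

    def rescaled_time(self, D: float, t):
        """Rescaled time T(t) = int_0^t D/L(s)^2 ds.

        Closed form for exponential growth, D*(1 - e^{-2 alpha t})/(2 alpha L0^2),
        and for linear growth, (D/beta)*(1/L0 - 1/(L0 + beta t)); adaptive
        quadrature otherwise.
        """
        if D <= 0:
            raise InvalidParameterError(f"diffusivity must be positive, got {D}")
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise InvalidParameterError("rescaled_time requires t >= 0")
        if self.kind == "exponential":
            # T = (D t / L0^2) * (1 - e^{-z})/z with z = 2 alpha t; the
            # series branch keeps the factor accurate down to z = 0
            z = 2.0 * self.alpha * t_arr
            with np.errstate(invalid="ignore", divide="ignore"):
                factor = np.where(
                    z < 1e-8, 1.0 - z / 2.0 + z * z / 6.0, -np.expm1(-z) / np.where(z == 0, 1.0, z)
                )
            out = D * t_arr / self.L0**2 * factor
        elif self.kind == "linear":
            # (1/L0 - 1/(L0+bt))/b simplifies exactly, stable as b -> 0
            out = D * t_arr / (self.L0 * (self.L0 + self.beta * t_arr))
        else:
            out = np.vectorize(lambda s: self._rescaled_time_quad(D, s), otypes=[float])(t_arr)
        return out[()] if out.ndim == 0 else out

    def _rescaled_time_quad(self, D: float, t: float) -> float:
        if t == 0.0:
            return 0.0
        val, err = quad(
            lambda s: D / float(self.length(s)) ** 2,
            0.0,
            t,
            epsabs=_QUAD_ABS_TOL,
            epsrel=1e-12,
            limit=200,
        )
        if not math.isfinite(val) or err > max(_QUAD_ABS_TOL, 1e-8 * abs(val)) * 1e4:
            raise NumericalIntegrationError(
                f"quadrature of D/L^2 over [0, {t}] did not converge (err={err:g})"
            )
        return val

    def dilution_decay(self, t):
        """Accumulated dilution factor exp(-int_0^t sigma ds) = L(0)/L(t)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise InvalidParameterError("dilution_decay requires t >= 0")
        out = self.L0 / self.length(t_arr)
        return out[()] if np.ndim(out) == 0 else out


def _check_L0(L0: float) -> None:
    if not (L0 > 0):
        raise InvalidParameterError(f"initial length L0 must be positive, got {L0}")


def make_exponential(L0: float, alpha: float) -> GrowthLaw:
    """Exponential growth L(t) = L0*e^{alpha t}: sigma = alpha, v = alpha*x."""
    _check_L0(L0)
    if alpha < 0:
        raise InvalidParameterError("shrinking domains (alpha < 0) are not supported")
    return GrowthLaw(kind="exponential", L0=float(L0), alpha=float(alpha))


def make_linear(L0: float, beta: float) -> GrowthLaw:
    """Linear growth L(t) = L0 + beta*t: sigma = beta/L(t), v = x*beta/L(t)."""
    _check_L0(L0)
    if beta < 0:
        raise InvalidParameterError("shrinking domains (beta < 0) are not supported")
    return GrowthLaw(kind="linear", L0=float(L0), beta=float(beta))


def make_custom(length_fn: Callable[[float], float], t_check: float = 50.0) -> GrowthLaw:
    """Growth law defined by an arbitrary length function L(t).

    The length function is the experimentally specified primitive; sigma(t)
    is recovered by finite-difference differentiation of ln L(t) and T(t)
    by adaptive quadrature.  A coarse monotonicity check over [0, t_check]
    rejects obviously shrinking laws up front; shrinkage encountered later
    during evaluation is also rejected.
    """
    L0 = float(length_fn(0.0))
    _check_L0(L0)
    law = GrowthLaw(kind="custom", L0=L0, length_fn=length_fn)
    probe = np.linspace(0.0, t_check, 41)
    lengths = law.length(probe)
    if np.any(np.diff(lengths) < -1e-9 * np.maximum(1.0, lengths[:-1])):
        raise InvalidParameterError(
            "custom growth law is shrinking on the probed range; only growth is supported"
        )
    return law


def rescaled_time(law: GrowthLaw, D: float, t):
    """Module-level convenience wrapper for :meth:`GrowthLaw.rescaled_time`."""
    return law.rescaled_time(D, t)


def dilution_decay(law: GrowthLaw, t):
    """Module-level convenience wrapper for :meth:`GrowthLaw.dilution_decay`."""
    return law.dilution_decay(t)
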