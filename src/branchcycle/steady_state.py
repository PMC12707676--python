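"""Malthusian growth rate, asymptotic phase fractions and T_SSD detection.

With gamma phase durations sharing a common rate ``beta0`` and mean offspring
``m = 2``, the characteristic equation ``m * psi1^(g) psi2^(g) psi3^(g) = 1``
(hat denoting Laplace transforms) has the closed-form root

    gamma = beta0 * (2 ** (1 / (alpha1 + alpha2 + alpha3)) - 1).

The asymptotic fraction of cells in each phase follows from the stable phase
distribution of a supercritical age-dependent branching process; the three
fractions sum to one exactly by the characteristic equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import BaselineParams

__all__ = ["SteadyStateResult", "growth_rate", "growth_rate_numeric",
           "asymptotic_fractions", "detect_tssd"]


@dataclass(frozen=True)
class SteadyStateResult:
    gamma: float
    fractions: tuple[float, float, float]
    t_ssd: float | None = None


def growth_rate(params: BaselineParams) -> float:
    """Closed-form Malthusian parameter (1/hour)."""
    total_shape = params.alpha1 + params.alpha2 + params.alpha3
    return params.beta0 * (2.0 ** (1.0 / total_shape) - 1.0)


def growth_rate_numeric(params: BaselineParams) -> float:
    """Bracketing root of ``2 * (beta0/(gamma+beta0))**sum(alpha) = 1``.

    Independent cross-check of :func:`growth_rate`.
    """
    total_shape = params.alpha1 + params.alpha2 + params.alpha3

    def charfun(g: float) -> float:
        return 2.0 * (params.beta0 / (g + params.beta0)) ** total_shape - 1.0

    return brentq(charfun, 1e-12, 10.0 * params.beta0, xtol=1e-14, rtol=1e-15)


def asymptotic_fractions(params: BaselineParams) -> tuple[float, float, float]:
    """Asymptotic (pG1, pS, pG2M); components positive, summing to 1."""
    gamma = growth_rate(params)
    r = params.beta0 / (gamma + params.beta0)
    a1, a2, a3 = params.shapes
    p_g1 = 2.0 * (1.0 - r ** a1)
    p_s = 2.0 * (r ** a1 - r ** (a1 + a2))
    p_g2m = 2.0 * (r ** (a1 + a2) - r ** (a1 + a2 + a3))
    return (p_g1, p_s, p_g2m)


def detect_tssd(curves, window: float = 5.0, tol: float = 1e-4) -> float:
    """Time at which the G1 fraction has stabilized (balanced growth).

    Returns the smallest grid time ``t >= window`` from which
    ``(fracG1(t') - fracG1(t' - window))**2 < tol`` holds for every later
    grid time ``t' >= t`` on the curve.  The persistence requirement keeps
    transient oscillations of the synchronized start - where the lagged
    difference crosses zero while the fractions are still far from
    equilibrium - from triggering a premature detection.  Raises if the
    curve horizon is shorter than the window; returns ``None`` if the rule
    is never satisfied.

    ``curves`` is a :class:`~branchcycle.renewal_engine.PopulationCurves`
    (anything exposing ``grid`` and ``fractions['G1']`` works).
    """
    grid = curves.grid
    if grid.horizon < window:
        raise ValueError("curve horizon shorter than the comparison window")
    g1 = np.asarray(curves.fractions["G1"], dtype=float)
    lag = int(round(window / grid.step))
    ok = (g1[lag:] - g1[:-lag]) ** 2 < tol
    persistent = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.nonzero(persistent)[0]
    if hits.size == 0:
        return None
    return (hits[0] + lag) * grid.step
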