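"""Phase- and state-duration distributions and their grid discretization.

Cell-cycle phase completion times are gamma distributed with a common rate
parameter shared across phases, so the full cycle length is again gamma with
shape ``alpha1 + alpha2 + alpha3``.  Drug-induced repair/arrest states follow
Weibull laws whose scale parameters are driven to zero at zero dose; a zero
scale therefore denotes a state that is traversed instantly.

The renewal engine works on a uniform :class:`TimeGrid` and represents every
duration by its probability mass per grid bin.  Masses are exact CDF
differences taken on half-offset (centered) bins, ``G(t_k + h/2) - G(t_k -
h/2)``, so that discretized distributions conserve mass exactly and carry no
systematic half-step timing bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "TimeGrid",
    "Duration",
    "GammaPhase",
    "WeibullState",
    "FixedDuration",
    "Convolution",
    "ResidualDuration",
    "gamma_cdf",
    "gamma_laplace",
    "weibull_cdf",
    "discretize_cdf",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid ``0, step, 2*step, ..., horizon`` (hours)."""

    step: float = 0.1
    horizon: float = 72.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.horizon < self.step:
            raise ValueError("horizon must be at least one step")

    @property
    def n(self) -> int:
        return int(round(self.horizon / self.step)) + 1

    @property
    def points(self) -> np.ndarray:
        return np.arange(self.n) * self.step

    def index_of(self, t: float) -> int:
        return int(round(t / self.step))


class Duration:
    """A nonnegative random duration: CDF, mean, sampler and grid mass."""

    def cdf(self, t):
        raise NotImplementedError

    @property
    def mean(self) -> float:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size=None):
        raise NotImplementedError

    def kernel(self, grid: TimeGrid) -> np.ndarray:
        """Probability mass per bin on centered bins.

        ``kernel[k]`` is the probability that the duration falls in
        ``(t_k - h/2, t_k + h/2]`` (with the first bin ``[0, h/2]``), so a
        duration of exactly zero contributes to lag 0.
        """
        h = grid.step
        edges = np.concatenate(([0.0], grid.points + h / 2.0))
        vals = np.asarray(self.cdf(edges), dtype=float)
        k = np.diff(vals)
        # numerical noise guard: CDFs are monotone by construction
        return np.clip(k, 0.0, None)

    def survival(self, grid: TimeGrid) -> np.ndarray:
        """``P(duration > t_k)`` at the grid points.

        A state of identically zero duration is never occupied, so its
        survival is identically zero (cells pass through instantly).
        """
        if self.mean == 0.0:
            return np.zeros(grid.n)
        return 1.0 - np.asarray(self.cdf(grid.points), dtype=float)


def _check_nonneg_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


@dataclass(frozen=True)
class GammaPhase(Duration):
    """Gamma-distributed phase completion time (shape alpha, rate beta0)."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")

    def cdf(self, t):
        t = _check_nonneg_t(t)
        return special.gammainc(self.shape, self.rate * t)

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def var(self) -> float:
        return self.shape / self.rate**2

    def laplace(self, s) -> float:
        """Laplace transform ``(rate / (s + rate)) ** shape``; 1 at s = 0."""
        s = np.asarray(s, dtype=float)
        if np.any(s <= -self.rate):
            raise ValueError("laplace transform diverges for s <= -rate")
        return (self.rate / (s + self.rate)) ** self.shape

    def sample(self, rng, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


@dataclass(frozen=True)
class WeibullState(Duration):
    """Weibull-distributed drug-state residence time.

    ``scale == 0`` is legal and denotes an instantaneous state (the dose-zero
    limit of the Hill-scaled downtimes): the CDF is 1 for every t > 0.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("weibull shape must be positive")
        if self.scale < 0:
            raise ValueError("weibull scale must be nonnegative")

    def cdf(self, t):
        t = _check_nonneg_t(t)
        if self.scale == 0.0:
            return np.where(t > 0, 1.0, 0.0)
        with np.errstate(over="ignore"):  # (t/scale)**shape may overflow to
            # inf for tiny scales; expm1(-inf) correctly gives cdf = 1
            return -np.expm1(-((t / self.scale) ** self.shape))

    @property
    def mean(self) -> float:
        if self.scale == 0.0:
            return 0.0
        return self.scale * special.gamma(1.0 + 1.0 / self.shape)

    def sample(self, rng, size=None):
        if self.scale == 0.0:
            return np.zeros(size) if size is not None else 0.0
        return self.scale * rng.weibull(self.shape, size=size)


@dataclass(frozen=True)
class FixedDuration(Duration):
    """Deterministic residence time (used for the apoptotic compartment)."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("duration must be nonnegative")

    def cdf(self, t):
        t = _check_nonneg_t(t)
        return np.where(t >= self.value, 1.0, 0.0) if self.value > 0 else np.where(t > 0, 1.0, 0.0)

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng, size=None):
        return np.full(size, self.value) if size is not None else self.value


class Convolution(Duration):
    """Sum of independent durations (downtime followed by progression).

    Drug-induced downtime halts the cycle and normal progression then
    resumes, so the total residence time in such a state is the convolution
    of the downtime law with the baseline phase duration.
    """

    def __init__(self, *parts: Duration) -> None:
        if not parts:
            raise ValueError("need at least one component")
        # degenerate (zero-duration) components are exact deltas at zero:
        # dropping them keeps the dose-0 limit bitwise identical to the
        # bare phase duration
        live = tuple(p for p in parts if p.mean > 0.0)
        self.parts = live if live else parts[:1]

    @property
    def mean(self) -> float:
        return float(sum(p.mean for p in self.parts))

    def cdf(self, t):
        if len(self.parts) == 1:
            return self.parts[0].cdf(t)
        raise NotImplementedError(
            "multi-component convolution CDFs are only realized on a "
            "TimeGrid via kernel()")

    def kernel(self, grid: TimeGrid) -> np.ndarray:
        k = self.parts[0].kernel(grid)
        for p in self.parts[1:]:
            k = np.convolve(k, p.kernel(grid))[: grid.n]
        return k

    def survival(self, grid: TimeGrid) -> np.ndarray:
        if self.mean == 0.0:
            return np.zeros(grid.n)
        if len(self.parts) == 1:
            return self.parts[0].survival(grid)
        k = self.kernel(grid)
        # cumsum(k)[j] ~ G(t_j + h/2); recenter to the grid point
        cdf_pts = np.cumsum(k) - 0.5 * k
        return np.clip(1.0 - cdf_pts, 0.0, 1.0)

    def sample(self, rng, size=None):
        return sum(np.asarray(p.sample(rng, size=size)) for p in self.parts)


class ResidualDuration(Duration):
    """Remaining phase time of a cell observed mid-phase in balanced growth.

    In a supercritical population growing at Malthusian rate ``gamma`` the
    age density of cells within a phase is proportional to
    ``exp(-gamma * a) * (1 - G(a))``.  The residual-time CDF is

        R(t) = int exp(-gamma a) [G(a + t) - G(a)] da
             / int exp(-gamma a) [1 - G(a)] da .

    ``gamma = 0`` recovers the classical equilibrium residual-life law
    ``R(t) = (1/mean) int_0^t (1 - G(u)) du``.
    """

    def __init__(self, phase: Duration, growth_rate: float, t_max: float = 80.0,
                 resolution: float = 0.05) -> None:
        if growth_rate < 0:
            raise ValueError("growth rate must be nonnegative")
        self.phase = phase
        self.growth_rate = float(growth_rate)
        if phase.mean <= 0:
            # degenerate instantaneous phase: nothing left to wait for
            self._t = np.array([0.0, t_max])
            self._cdf = np.array([1.0, 1.0])
            return
        a_max = phase.mean + 12.0 * np.sqrt(getattr(phase, "var", phase.mean))
        ages = np.linspace(0.0, a_max, 801)
        w = np.exp(-self.growth_rate * ages)
        g_a = np.asarray(phase.cdf(ages), dtype=float)
        denom = np.trapezoid(w * (1.0 - g_a), ages)
        ts = np.arange(0.0, t_max + resolution, resolution)
        # G(a + t) for all (t, a): moderate-size dense evaluation
        g_at = np.asarray(phase.cdf(ages[None, :] + ts[:, None]), dtype=float)
        num = np.trapezoid(w[None, :] * (g_at - g_a[None, :]), ages, axis=1)
        cdf = np.clip(num / denom, 0.0, 1.0)
        cdf = np.maximum.accumulate(cdf)
        self._t = ts
        self._cdf = cdf

    def cdf(self, t):
        t = _check_nonneg_t(t)
        return np.interp(t, self._t, self._cdf, left=0.0, right=1.0)

    @property
    def mean(self) -> float:
        return float(np.trapezoid(1.0 - self._cdf, self._t))

    def sample(self, rng, size=None):
        u = rng.random(size)
        return np.interp(u, self._cdf, self._t)


# ---------------------------------------------------------------------------
# module-level operation surface

def gamma_cdf(phase: GammaPhase, t):
    """CDF of a gamma phase-duration at time ``t`` (hours)."""
    return phase.cdf(t)


def gamma_laplace(phase: GammaPhase, s):
    """Laplace transform of the gamma phase-duration density at ``s``."""
    return phase.laplace(s)


def weibull_cdf(state: WeibullState, t):
    """CDF of a Weibull state-duration at time ``t`` (hours)."""
    return state.cdf(t)


def discretize_cdf(cdf, grid: TimeGrid, tol: float = 1e-12):
    """Sample a CDF on the grid and return (values, right-edge increments).

    Increments are ``G(t_k) - G(t_{k-1})`` with a leading ``G(0)`` term; they
    are nonnegative and sum to ``cdf(horizon)``.  Raises if the sampled
    values decrease by more than ``tol``.
    """
    vals = np.asarray(cdf(grid.points), dtype=float)
    inc = np.diff(np.concatenate(([0.0], vals)))
    if np.any(inc < -tol):
        raise ValueError("cdf is not monotone on the grid")
    return vals, np.clip(inc, 0.0, None)
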