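"""Synthetic flow-cytometry-like phase-fraction trajectories.

The generator emulates the data the calibration machinery consumes: the
engine's noiseless phase fractions at a set of sampling times, plus
independent additive Gaussian noise per phase — exactly the noise structure
the likelihood assumes.  Noise is *not* renormalized across phases (doing so
would correlate the errors); draws outside [0, 1] are clipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import TrajectoryData
from .distributions import TimeGrid
from .params import BaselineParams, G2MTreatmentParams, STreatmentParams
from .renewal_engine import simulate_treatment_run, simulate_untreated
from .steady_state import asymptotic_fractions

__all__ = ["SyntheticSpec", "generate_trajectory", "model_fractions"]

log = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating conditions for one synthetic dataset.

    ``sigma2`` is the per-phase noise variance on fractions; the default
    8e-4 (sd about 0.028) matches the scale of treated-trajectory
    measurement noise in the reference calibrations.  Untreated
    trajectories start from 100% G1 cells at time zero; treated ones start
    at the balanced-growth state with time measured from drug-in.
    """

    baseline: BaselineParams
    times: tuple = tuple(float(t) for t in np.arange(4.0, 61.0, 4.0))
    sigma2: tuple[float, float, float] = (8e-4, 8e-4, 8e-4)
    seed: int = 0
    treatment: G2MTreatmentParams | STreatmentParams | None = None
    dose: float = 0.0
    step: float = 0.1
    include_steady_state: bool = True

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma2):
            raise ValueError("noise variances must be nonnegative")
        if len(self.times) == 0:
            raise ValueError("need at least one observation time")


import functools


@functools.lru_cache(maxsize=32)
def _noiseless_fractions(baseline, times, treatment, dose, step):
    horizon = max(times)
    from dataclasses import replace
    n_gen = int(np.ceil(horizon / baseline.mean_cycle)) + 3
    base = replace(baseline, n_gen=n_gen)
    grid = TimeGrid(step, horizon)
    if treatment is None:
        curves = simulate_untreated(base, grid)
    else:
        kw = ({"g2m": treatment, "dose_g2m": dose}
              if isinstance(treatment, G2MTreatmentParams)
              else {"s": treatment, "dose_s": dose})
        curves, _ = simulate_treatment_run(
            base, grid=grid, initial_fractions="asymptotic", t_ssd=0.0, **kw)
    idx = [grid.index_of(t) for t in times]
    out = np.column_stack([np.asarray(curves.fractions[p])[idx]
                           for p in PHASES])
    out.setflags(write=False)
    return out


def model_fractions(spec: SyntheticSpec) -> np.ndarray:
    """Noiseless model fractions at the spec's observation times (cached)."""
    return np.array(_noiseless_fractions(spec.baseline, tuple(spec.times),
                                         spec.treatment, spec.dose,
                                         spec.step))


def generate_trajectory(spec: SyntheticSpec) -> TrajectoryData:
    """Model fractions plus independent per-phase Gaussian noise.

    Reproducible under the spec's seed; zero variance returns the noiseless
    output exactly.  Clipping to [0, 1] happens only on extreme draws and is
    logged (fractions are physical).
    """
    clean = model_fractions(spec)
    rng = np.random.default_rng(spec.seed)
    sd = np.sqrt(np.asarray(spec.sigma2))
    noisy = clean + rng.standard_normal(clean.shape) * sd[None, :]
    n_clip = int(np.sum((noisy < 0) | (noisy > 1)))
    if n_clip:
        log.warning("clipped %d noisy fraction(s) to [0, 1]", n_clip)
    noisy = np.clip(noisy, 0.0, 1.0)
    steady = None
    if spec.treatment is None and spec.include_steady_state:
        ss = np.asarray(asymptotic_fractions(spec.baseline))
        steady = np.clip(ss + rng.standard_normal(3) * sd, 0.0, 1.0)
    return TrajectoryData(np.asarray(spec.times, dtype=float), noisy, steady)
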