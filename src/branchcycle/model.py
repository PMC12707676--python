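"""Model/Results front end for calibrating the branching-process model.

:class:`PhaseFractionModel` binds observed phase-fraction trajectories to a
forward model (untreated cycling, or one of the drug machines with a chosen
subset of free treatment parameters) and a uniform-box prior.  ``fit()``
runs the RAM sampler over the model parameters and the three per-phase
noise variances jointly and returns a :class:`PhaseFractionResults` holding
the chain, posterior means, credible intervals and a text summary.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .calibration import (Chain, TrajectoryData, log_posterior, ram_sample,
                          summarize_chain)
from .distributions import TimeGrid
from .params import BaselineParams, G2MTreatmentParams, STreatmentParams
from .renewal_engine import simulate_treatment_run, simulate_untreated
from .steady_state import asymptotic_fractions

__all__ = ["PhaseFractionModel", "PhaseFractionResults",
           "untreated_predictor", "treated_predictor"]

PHASES = ("G1", "S", "G2M")

#: generous default prior boxes (untreated shape/rate, noise variances)
UNTREATED_BOUNDS = {"alpha1": (2.0, 25.0), "alpha2": (2.0, 25.0),
                    "alpha3": (2.0, 25.0), "beta0": (0.3, 5.0)}
SIGMA2_BOUNDS = (1e-6, 0.05)


def untreated_predictor(times, step: float = 0.1):
    """Map (alpha1, alpha2, alpha3, beta0) -> (trajectory, steady state).

    The trajectory is the expected phase-fraction curve of a population
    synchronized in G1 at time zero, evaluated at ``times``; the steady
    state is the closed-form balanced-growth mix.
    """
    times = np.asarray(times, dtype=float)
    horizon = float(times.max())
    grid = TimeGrid(step, horizon)
    idx = [grid.index_of(t) for t in times]

    def predict(theta):
        a1, a2, a3, b0 = (float(v) for v in theta)
        mean_cycle = (a1 + a2 + a3) / b0
        n_gen = int(np.ceil(horizon / mean_cycle)) + 3
        base = BaselineParams(a1, a2, a3, b0, n_gen=n_gen)
        curves = simulate_untreated(base, grid)
        traj = np.column_stack([np.asarray(curves.fractions[p])[idx]
                                for p in PHASES])
        return traj, np.asarray(asymptotic_fractions(base))

    return predict


def treated_predictor(base: BaselineParams, treatment, dose: float,
                      vary, times, step: float = 0.2, n_gen: int = 6):
    """Map a vector over the ``vary`` fields of ``treatment`` -> trajectory.

    The remaining treatment parameters stay at their configured values; the
    run starts from the balanced-growth state with time measured from
    drug-in, matching the convention of treated flow-cytometry series.
    """
    is_g2m = isinstance(treatment, G2MTreatmentParams)
    if not is_g2m and not isinstance(treatment, STreatmentParams):
        raise TypeError("treatment must be a G2M or S parameter block")
    times = np.asarray(times, dtype=float)
    grid = TimeGrid(step, float(times.max()))
    idx = [grid.index_of(t) for t in times]
    base = replace(base, n_gen=n_gen)

    def predict(theta):
        trt = replace(treatment, **dict(zip(vary, (float(v) for v in theta))))
        kw = ({"g2m": trt, "dose_g2m": dose} if is_g2m
              else {"s": trt, "dose_s": dose})
        curves, _ = simulate_treatment_run(
            base, grid=grid, initial_fractions="asymptotic", t_ssd=0.0, **kw)
        return np.column_stack([np.asarray(curves.fractions[p])[idx]
                                for p in PHASES])

    return predict


class PhaseFractionModel:
    """Phase-fraction trajectory data bound to a forward model and priors.

    Parameters
    ----------
    data : TrajectoryData
        Observed per-phase fractions over time (fractions in [0, 1]).
    kind : {"untreated", "g2m", "s"}
        Which forward model generates the predictions.
    base, treatment, dose, vary
        For treated kinds: the fixed baseline parameters, the treatment
        block, the dose (nM) and the treatment fields to estimate.
    bounds : dict, optional
        Uniform prior boxes per free parameter (name -> (low, high)).
    """

    def __init__(self, data: TrajectoryData, kind: str = "untreated",
                 base: BaselineParams | None = None, treatment=None,
                 dose: float = 0.0, vary=None, bounds=None,
                 step: float | None = None):
        if kind not in ("untreated", "g2m", "s"):
            raise ValueError("kind must be untreated, g2m or s")
        self.data = data
        self.kind = kind
        if kind == "untreated":
            self.param_names = ["alpha1", "alpha2", "alpha3", "beta0"]
            self.predict = untreated_predictor(data.times,
                                               step=step or 0.1)
            box = dict(UNTREATED_BOUNDS)
        else:
            if base is None or treatment is None or not vary:
                raise ValueError(
                    "treated models need base, treatment and vary")
            self.param_names = list(vary)
            self.predict = treated_predictor(base, treatment, dose, vary,
                                             data.times, step=step or 0.2)
            box = {name: _default_treated_bounds(treatment, name)
                   for name in vary}
        if bounds:
            box.update(bounds)
        self.noise_names = ["sigma2_g1", "sigma2_s", "sigma2_g2m"]
        self.bounds = np.array([box[n] for n in self.param_names]
                               + [SIGMA2_BOUNDS] * 3, dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, steady_state=None, **kwargs):
        """Build from a tidy table with time_h / frac_g1 / frac_s / frac_g2m."""
        return cls(TrajectoryData.from_frame(df, steady_state), **kwargs)

    # -- fitting -----------------------------------------------------------
    def log_posterior(self, theta_full) -> float:
        return log_posterior(theta_full, self.data, self.predict,
                             self.bounds, len(self.param_names))

    def fit(self, n_iter: int = 20_000, seed: int = 0,
            burn_in_frac: float = 0.5, target_accept: float = 0.234,
            init=None) -> "PhaseFractionResults":
        if init is None:
            init = self.bounds.mean(axis=1)
        names = self.param_names + self.noise_names
        scale = np.diag(0.05 * (self.bounds[:, 1] - self.bounds[:, 0]))
        chain = ram_sample(self.log_posterior, init, n_iter,
                           target_accept=target_accept, seed=seed,
                           s0=scale, param_names=names)
        return PhaseFractionResults(self, chain, burn_in_frac)


def _default_treated_bounds(treatment, name) -> tuple[float, float]:
    value = getattr(treatment, name)
    if name.startswith(("q", "md_")):
        return (0.0, 1.0)
    return (max(0.0, 0.2 * value), max(5.0, 3.0 * value))


class PhaseFractionResults:
    """Posterior summaries of a fitted phase-fraction model."""

    def __init__(self, model: PhaseFractionModel, chain: Chain,
                 burn_in_frac: float = 0.5):
        self.model = model
        self.chain = chain
        self.burn_in_frac = burn_in_frac
        self._table = summarize_chain(chain, burn_in_frac, ci_level=0.50)

    @property
    def params(self) -> pd.Series:
        return self._table["mean"]

    def ci(self, level: float = 0.50) -> pd.DataFrame:
        return summarize_chain(self.chain, self.burn_in_frac,
                               ci_level=level)[["ci_low", "ci_high"]]

    @property
    def acceptance_rate(self) -> float:
        return self.chain.acceptance_rate

    def predicted_fractions(self) -> np.ndarray:
        """Trajectory predictions at the posterior-mean parameters."""
        pred = self.model.predict(
            self.params[self.model.param_names].to_numpy())
        return pred[0] if isinstance(pred, tuple) else pred

    def summary(self, ci_level: float = 0.50) -> str:
        tab = summarize_chain(self.chain, self.burn_in_frac, ci_level)
        lines = [
            "Phase-fraction branching-process model",
            f"  kind: {self.model.kind}    draws: "
            f"{self.chain.draws.shape[0]} (burn-in "
            f"{int(100 * self.burn_in_frac)}%)",
            f"  acceptance rate: {self.acceptance_rate:.3f}   "
            f"target: {self.chain.target_accept}",
            "",
            tab.rename(columns={
                "ci_low": f"ci{int(100 * ci_level)}_low",
                "ci_high": f"ci{int(100 * ci_level)}_high",
            }).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data points and posterior-mean trajectory per phase."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        pred = self.predicted_fractions()
        t = self.model.data.times
        colors = ("tab:green", "tab:orange", "tab:blue")
        for j, (p, c) in enumerate(zip(PHASES, colors)):
            ax.plot(t, self.model.data.fractions[:, j], "o", color=c,
                    label=f"{p} data")
            ax.plot(t, pred[:, j], "-", color=c, label=f"{p} fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("fraction of live cells")
        ax.legend(ncol=2, fontsize="small")
        return ax
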