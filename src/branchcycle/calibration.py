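"""Gaussian-noise likelihood, uniform-prior posterior and RAM sampling.

Observed phase-fraction time series are modeled as the engine's predicted
fractions plus independent zero-mean Gaussian noise per phase, with
phase-specific variances sampled alongside the model parameters.  Sampling
uses the Robust Adaptive Metropolis algorithm: a Metropolis chain whose
lower-triangular proposal factor is adapted by rank-one updates so that the
empirical acceptance rate converges to a target (0.234 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrajectoryData", "NoiseParams", "Chain", "log_likelihood",
           "log_posterior", "ram_sample", "summarize_chain"]

PHASES = ("G1", "S", "G2M")


@dataclass
class TrajectoryData:
    """Phase-fraction observations d_{p}(t_j), optionally with a steady state.

    ``fractions`` has shape (n_times, 3) in the order (G1, S, G2M).  When
    ``steady_state`` is given (an observed balanced-growth mix), model fits
    compare both the simulated trajectory and the analytic asymptotic
    fractions against the data, which sharpens identifiability of the
    untreated parameters.
    """

    times: np.ndarray
    fractions: np.ndarray
    steady_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.times.size, 3):
            raise ValueError("fractions must be (n_times, 3)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.steady_state is not None:
            self.steady_state = np.asarray(self.steady_state, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times,
                             "frac_g1": self.fractions[:, 0],
                             "frac_s": self.fractions[:, 1],
                             "frac_g2m": self.fractions[:, 2]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, steady_state=None):
        return cls(df["time_h"].to_numpy(),
                   df[["frac_g1", "frac_s", "frac_g2m"]].to_numpy(),
                   steady_state)


@dataclass(frozen=True)
class NoiseParams:
    """Per-phase measurement-noise variances (G1, S, G2M)."""

    sigma2: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma2):
            raise ValueError("noise variances must be positive")


def log_likelihood(theta, noise: NoiseParams, data: TrajectoryData,
                   model_fn) -> float:
    """Gaussian log-likelihood of the data under ``model_fn(theta)``.

    ``model_fn`` maps theta to predicted fractions shaped like
    ``data.fractions`` (plus a predicted steady-state row if the data carry
    one).  Nonpositive variances yield ``-inf`` (a rejected point) rather
    than an exception, so they can be sampled freely.
    """
    s2 = np.asarray(noise.sigma2, dtype=float)
    if np.any(s2 <= 0) or not np.all(np.isfinite(s2)):
        return -np.inf
    pred = model_fn(theta)
    if isinstance(pred, tuple):
        pred_traj, pred_ss = pred
    else:
        pred_traj, pred_ss = pred, None
    if not np.all(np.isfinite(pred_traj)):
        return -np.inf
    out = 0.0
    for p in range(3):
        resid = pred_traj[:, p] - data.fractions[:, p]
        n_p = resid.size
        if data.steady_state is not None:
            if pred_ss is None:
                raise ValueError("data carry a steady state but the model "
                                 "did not predict one")
            resid = np.concatenate(
                (resid, [pred_ss[p] - data.steady_state[p]]))
            n_p += 1
        out += (-0.5 * n_p * np.log(2.0 * np.pi * s2[p])
                - float(resid @ resid) / (2.0 * s2[p]))
    return out


def log_posterior(theta_full, data: TrajectoryData, model_fn,
                  prior_bounds, n_model: int) -> float:
    """Uniform-box posterior over (model parameters, noise variances).

    ``theta_full`` stacks ``n_model`` model parameters followed by the three
    noise variances; ``prior_bounds`` is an array of (low, high) rows of the
    same length.  Outside any bound the log-posterior is ``-inf``.
    """
    theta_full = np.asarray(theta_full, dtype=float)
    bounds = np.asarray(prior_bounds, dtype=float)
    if np.any(theta_full < bounds[:, 0]) or np.any(theta_full > bounds[:, 1]):
        return -np.inf
    noise = NoiseParams(tuple(theta_full[n_model:n_model + 3]))
    return log_likelihood(theta_full[:n_model], noise, data, model_fn)


@dataclass
class Chain:
    """RAM output: draws, log-posteriors, acceptance and proposal factors."""

    draws: np.ndarray          # (n_iter, dim)
    log_post: np.ndarray       # (n_iter,)
    accepted: np.ndarray       # (n_iter,) bool
    seed: int
    target_accept: float
    param_names: list[str] | None = None
    proposal_factor: np.ndarray | None = None   # final S

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def to_frame(self) -> pd.DataFrame:
        names = self.param_names or [f"p{i}"
                                     for i in range(self.draws.shape[1])]
        df = pd.DataFrame(self.draws, columns=names)
        df["log_post"] = self.log_post
        df["accepted"] = self.accepted
        return df


def ram_sample(log_post, init, n_iter: int, target_accept: float = 0.234,
               seed: int = 0, s0=None, param_names=None) -> Chain:
    """Robust Adaptive Metropolis sampling.

    Proposals are ``y = x + S_n u`` with spherical standard-normal ``u``;
    after each step the factor is updated through

        S_{n+1} S_{n+1}^T = S_n (I + eta_n (alpha_n - a*) u u^T / |u|^2) S_n^T

    with step size ``eta_n = min(1, d * n^(-2/3))``, driving the empirical
    acceptance toward the target ``a*``.  Reproducible under a fixed seed.
    """
    x = np.asarray(init, dtype=float).copy()
    d = x.size
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-posterior")
    s_fac = np.eye(d) * 0.1 if s0 is None else np.array(s0, dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_iter, d))
    lps = np.empty(n_iter)
    acc = np.zeros(n_iter, dtype=bool)
    for n in range(n_iter):
        u = rng.standard_normal(d)
        y = x + s_fac @ u
        lp_y = log_post(y)
        with np.errstate(over="ignore"):
            alpha = min(1.0, np.exp(lp_y - lp)) if np.isfinite(lp_y) else 0.0
        if rng.random() < alpha:
            x, lp = y, lp_y
            acc[n] = True
        draws[n] = x
        lps[n] = lp
        eta = min(1.0, d * (n + 1) ** (-2.0 / 3.0))
        norm2 = float(u @ u)
        if norm2 > 0:
            su = s_fac @ u
            scale = eta * (alpha - target_accept) / norm2
            m_next = s_fac @ s_fac.T + scale * np.outer(su, su)
            try:
                s_fac = np.linalg.cholesky(m_next)
            except np.linalg.LinAlgError:
                pass  # keep the previous factor on a rare indefinite update
    return Chain(draws, lps, acc, seed, target_accept,
                 list(param_names) if param_names else None, s_fac)


def summarize_chain(chain: Chain, burn_in_frac: float = 0.5,
                    ci_level: float = 0.50) -> pd.DataFrame:
    """Posterior means and central credible intervals after burn-in."""
    if not 0.0 <= burn_in_frac < 1.0:
        raise ValueError("burn_in_frac must be in [0, 1)")
    start = int(burn_in_frac * chain.draws.shape[0])
    post = chain.draws[start:]
    lo_q = 0.5 - ci_level / 2.0
    hi_q = 0.5 + ci_level / 2.0
    names = chain.param_names or [f"p{i}" for i in range(post.shape[1])]
    return pd.DataFrame({
        "mean": post.mean(axis=0),
        "ci_low": np.quantile(post, lo_q, axis=0),
        "ci_high": np.quantile(post, hi_q, axis=0),
    }, index=names)
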