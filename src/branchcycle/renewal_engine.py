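"""Expected-count dynamics by truncated renewal (Neumann) convolution.

For a state machine with duration-mass kernels ``K_i`` and expected-offspring
matrix ``m``, the expected number of cells occupying state ``j`` at time
``t`` descending from one ancestor entering state ``i`` at time 0 is

    M_ij(t) = sum_k [ (K m)^{*k} ]_ij  convolved with  S_j(t),

where ``S_j`` is the state's survival function and ``*k`` the k-fold
convolution power.  The sum is truncated at the longest directed path of the
(acyclic) state graph, which makes it exact.  Convolutions are carried out
with FFTs on the zero-padded grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import TimeGrid
from .params import BaselineParams
from .state_graph import (StateGraph, build_combination, build_g2m_treated,
                          build_s_treated, build_untreated)
from .steady_state import asymptotic_fractions, detect_tssd

__all__ = ["MomentField", "PopulationCurves", "compute_moment_field",
           "expected_phase_counts", "per_generation_breakdown",
           "simulate_untreated", "simulate_treatment_run"]

PHASES = ("G1", "S", "G2M")


@dataclass
class MomentField:
    """M(t): expected per-state counts per ancestor state on a time grid."""

    grid: TimeGrid
    graph: StateGraph
    ancestors: list[int]
    M: np.ndarray  # (n_t, n_ancestors, n_states)

    def ancestor_index(self, state: int) -> int:
        return self.ancestors.index(state)


@dataclass
class PopulationCurves:
    """Per-phase expected counts/fractions plus apoptotic bookkeeping."""

    grid: TimeGrid
    counts: dict[str, np.ndarray]
    fractions: dict[str, np.ndarray]
    per_generation: dict[tuple[int, str], np.ndarray]
    apoptotic: np.ndarray
    cumulative_dead: np.ndarray
    state_counts: pd.DataFrame | None = None
    #: cumulative cells that have drawn a death fate (committed to death,
    #: possibly still in a pre-apoptotic transit state); None when only
    #: occupancies are available
    committed_dead: np.ndarray | None = None

    @property
    def total_live(self) -> np.ndarray:
        return sum(self.counts[p] for p in PHASES)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, generation, state, value."""
        rows = []
        t = self.grid.points
        for (gen, kind), curve in self.per_generation.items():
            rows.append(pd.DataFrame({"time_h": t, "generation": gen,
                                      "state": kind, "value": curve}))
        rows.append(pd.DataFrame({"time_h": t, "generation": 0,
                                  "state": "apoptotic",
                                  "value": self.apoptotic}))
        return pd.concat(rows, ignore_index=True)

    def fractions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.grid.points,
                             "frac_g1": self.fractions["G1"],
                             "frac_s": self.fractions["S"],
                             "frac_g2m": self.fractions["G2M"]})

    def plot(self, ax=None):
        """Phase-fraction trajectories (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        for p, color in zip(PHASES, ("tab:green", "tab:orange", "tab:blue")):
            ax.plot(self.grid.points, self.fractions[p], color=color,
                    label=p)
        ax.set_xlabel("time after treatment (h)")
        ax.set_ylabel("fraction of live cells")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------

def _propagate(graph: StateGraph, grid: TimeGrid,
               init: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward renewal propagation.

    ``init`` has shape (n_batch, n_states): expected cells entering each
    state at time 0.  Returns ``(counts, entries)`` of shape
    (n_batch, n_states, n_t): expected occupancy and cumulative entries.
    """
    n_t = grid.n
    nfft = 1 << int(np.ceil(np.log2(2 * n_t)))
    kern = graph.kernels(grid)
    surv = graph.survivals(grid)
    m = graph.m_matrix()
    k_hat = np.fft.rfft(kern, n=nfft, axis=1)
    s_hat = np.fft.rfft(surv, n=nfft, axis=1)

    n_b = init.shape[0]
    cur = np.zeros((n_b, graph.n_states, n_t))
    cur[:, :, 0] = init
    acc = cur.copy()
    depth = graph.longest_path()
    # m is very sparse (a couple of offspring entries per state): propagate
    # along its nonzero triplets instead of dense matrix products.  Entry
    # masses are truncated to the grid after every convolution step, which
    # both discards irrelevant post-horizon mass and prevents circular
    # wrap-around of the FFT convolution.
    nz_i, nz_j = np.nonzero(m)
    weights = m[nz_i, nz_j]
    for _ in range(depth):
        cur_hat = np.fft.rfft(cur, n=nfft, axis=2)
        exits = np.fft.irfft(cur_hat * k_hat[None], n=nfft,
                             axis=2)[:, :, :n_t]
        nxt = np.zeros((graph.n_states, n_b, n_t))
        np.add.at(nxt, nz_j,
                  weights[:, None, None] * exits.swapaxes(0, 1)[nz_i])
        cur = nxt.swapaxes(0, 1)
        acc += cur
        if not np.any(cur > 1e-300):
            break
    acc_hat = np.fft.rfft(acc, n=nfft, axis=2)
    counts = np.fft.irfft(acc_hat * s_hat[None], n=nfft, axis=2)[:, :, :n_t]
    entries = np.cumsum(acc, axis=2)
    # kernel-consistent survivals observe the system at t_k + h/2; average
    # neighboring samples to recenter on the grid points (O(h^2)); at t = 0
    # the occupancy is the initial condition itself
    counts[:, :, 1:] = 0.5 * (counts[:, :, :-1] + counts[:, :, 1:])
    counts[:, :, 0] = init
    entries[:, :, 1:] = 0.5 * (entries[:, :, :-1] + entries[:, :, 1:])
    # clip tiny negative FFT round-off
    return np.clip(counts, 0.0, None), np.clip(entries, 0.0, None)


def compute_moment_field(graph: StateGraph, grid: TimeGrid,
                         ancestors: list[int] | None = None) -> MomentField:
    """Expected-progeny field M(t) for the requested ancestor states."""
    if grid.horizon < min(
            (s.duration.mean for i, s in enumerate(graph.states)
             if s.phase != "apoptotic" and s.duration.mean > 0),
            default=0.0) * 3:
        warnings.warn("grid horizon is short relative to state durations")
    if ancestors is None:
        ancestors = list(range(graph.n_states))
    init = np.zeros((len(ancestors), graph.n_states))
    for row, a in enumerate(ancestors):
        init[row, a] = 1.0
    counts, _ = _propagate(graph, grid, init)
    return MomentField(grid, graph, list(ancestors),
                       np.moveaxis(counts, 2, 0))


def _kind(name: str) -> str:
    """State name without its generation suffix."""
    base, _, tail = name.rpartition("_g")
    return base if base and tail.isdigit() else name


def _death_weights(graph: StateGraph) -> np.ndarray:
    """Per-state probability that the drawn fate leads straight to death."""
    w = np.zeros(graph.n_states)
    for i, st in enumerate(graph.states):
        w[i] = sum(f.prob for f in st.fates
                   if any(c == graph.apoptotic for c, _ in f.children))
    return w


def _curves_from_state_counts(graph: StateGraph, grid: TimeGrid,
                              state_counts: np.ndarray,
                              apop_entries: np.ndarray,
                              committed=None) -> PopulationCurves:
    counts = {p: np.zeros(grid.n) for p in PHASES}
    per_gen: dict[tuple[int, str], np.ndarray] = {}
    for i, st in enumerate(graph.states):
        if st.phase == "apoptotic":
            continue
        counts[st.phase] += state_counts[i]
        key = (st.generation, _kind(st.name))
        per_gen[key] = per_gen.get(key, 0.0) + state_counts[i]
    total = sum(counts.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = {p: np.where(total > 0, counts[p] / total, np.nan)
                     for p in PHASES}
    apoptotic = state_counts[graph.apoptotic]
    cumulative_dead = apop_entries
    names = [s.name for s in graph.states]
    sc = pd.DataFrame(state_counts.T, columns=names)
    sc.insert(0, "time_h", grid.points)
    return PopulationCurves(grid, counts, fractions, per_gen, apoptotic,
                            cumulative_dead, sc, committed)


def expected_phase_counts(field: MomentField,
                          initial: dict[int, float]) -> PopulationCurves:
    """Phase counts/fractions for an initial mix over ancestor states."""
    if not initial or all(v == 0 for v in initial.values()):
        raise ValueError("initial condition must contain a positive count")
    graph, grid = field.graph, field.grid
    state_counts = np.zeros((graph.n_states, grid.n))
    for state, count in initial.items():
        if count < 0:
            raise ValueError("initial counts must be nonnegative")
        state_counts += count * field.M[:, field.ancestor_index(state), :].T
    # cumulative deaths: apoptotic occupancy(t) = inflow(t) - inflow(t-lag)
    # for the fixed clearance lag, so cumulative inflow unrolls recursively
    apop = state_counts[graph.apoptotic]
    lag = grid.index_of(graph.states[graph.apoptotic].duration.mean)
    cum_dead = apop.copy()
    if lag:
        for k in range(lag, grid.n):
            cum_dead[k] = apop[k] + cum_dead[k - lag]
    return _curves_from_state_counts(graph, grid, state_counts, cum_dead)


def per_generation_breakdown(field: MomentField,
                             initial: dict[int, float]) -> dict:
    """(generation, state-kind) -> expected count curve."""
    return expected_phase_counts(field, initial).per_generation


# ---------------------------------------------------------------------------
# high-level runs

def _run(graph: StateGraph, grid: TimeGrid,
         initial: dict[int, float]) -> PopulationCurves:
    init = np.zeros((1, graph.n_states))
    for state, count in initial.items():
        init[0, state] = count
    counts, entries = _propagate(graph, grid, init)
    committed = _death_weights(graph) @ entries[0]
    return _curves_from_state_counts(graph, grid, counts[0],
                                     entries[0, graph.apoptotic], committed)


def simulate_untreated(params: BaselineParams, grid: TimeGrid,
                       initial_phase: str = "G1") -> PopulationCurves:
    """Expected dynamics from one ancestor synchronized in ``initial_phase``."""
    graph = build_untreated(params)
    return _run(graph, grid, {graph.fresh[initial_phase]: 1.0})


def simulate_treatment_run(base: BaselineParams, g2m=None, s=None,
                           dose_g2m: float = 0.0, dose_s: float = 0.0,
                           grid: TimeGrid | None = None,
                           t_ssd: float | None = None,
                           tssd_tol: float = 1e-4,
                           initial_fractions=None,
                           apoptotic_duration: float | None = None):
    """Untreated growth to T_SSD, then drug exposure, time re-zeroed.

    The live-phase snapshot at T_SSD becomes the treated machine's initial
    condition: each phase's occupants start in a pre-treatment state whose
    duration is the residual time of a cell observed mid-phase in balanced
    growth.  ``initial_fractions`` may override the snapshot (a 3-tuple, or
    the string ``"asymptotic"`` for the closed-form balanced-growth mix).

    Returns ``(curves, t_ssd)`` with curve time measured from treatment.
    """
    if grid is None:
        grid = TimeGrid(0.1, 72.0)
    if initial_fractions is None or t_ssd is None:
        warm_h = max(12.0 * base.mean_cycle, 60.0)
        n_gen_u = int(np.ceil(warm_h / base.mean_cycle)) + 3
        from dataclasses import replace
        warm_params = replace(base, n_gen=n_gen_u)
        warm_grid = TimeGrid(grid.step, warm_h)
        warm = simulate_untreated(warm_params, warm_grid)
        if t_ssd is None:
            t_ssd = detect_tssd(warm, tol=tssd_tol)
            if t_ssd is None:
                raise ValueError("steady state not reached inside the "
                                 "untreated horizon")
        if t_ssd > warm_grid.horizon:
            raise ValueError("t_ssd beyond the untreated horizon")
        if initial_fractions is None:
            k = warm_grid.index_of(t_ssd)
            initial_fractions = tuple(warm.fractions[p][k] for p in PHASES)
    if initial_fractions == "asymptotic":
        initial_fractions = asymptotic_fractions(base)

    kwargs = {}
    if apoptotic_duration is not None:
        kwargs["apoptotic_duration"] = apoptotic_duration
    if g2m is not None and s is not None:
        graph = build_combination(base, g2m, s, dose_g2m, dose_s, grid,
                                  **kwargs)
    elif g2m is not None:
        graph = build_g2m_treated(base, g2m, dose_g2m, grid, **kwargs)
    elif s is not None:
        graph = build_s_treated(base, s, dose_s, grid, **kwargs)
    else:
        raise ValueError("provide at least one treatment parameter block")
    initial = {graph.occupants[p]: f
               for p, f in zip(PHASES, initial_fractions)}
    curves = _run(graph, grid, initial)
    return curves, t_ssd
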