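"""Exact stochastic agent-level simulation of a state graph.

Every cell draws its state residence time from the state's duration law and
its fate from the state's branching law, independently of all other cells.
The simulation is event-driven (priority queue ordered by exit time, ties
broken by cell id), so event times are exact; grid binning happens only when
summarizing.  This simulator is the brute-force oracle for the expected-count
renewal engine: their phase counts must agree within Monte-Carlo error.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import TimeGrid
from .renewal_engine import PopulationCurves, _kind
from .state_graph import StateGraph

__all__ = ["simulate_population", "summarize", "ancestor_phase_counts"]

PHASES = ("G1", "S", "G2M")


def _fate_label(graph: StateGraph, state: int, children) -> str:
    st = graph.states[state]
    if any(c == graph.apoptotic for c, _ in children):
        return "die"
    if any(k == 2 for _, k in children):
        return "divide"
    if not children:
        return "end"
    if st.phase == "G2M" and all(graph.states[c].phase == "G1"
                                 for c, _ in children):
        return "slip"
    return "advance"


def simulate_population(graph: StateGraph, n_ancestors: int, horizon: float,
                        seed: int, initial_probs=None) -> pd.DataFrame:
    """Simulate ``n_ancestors`` independent lineages up to ``horizon`` hours.

    ``initial_probs`` maps state index -> probability of an ancestor
    starting there (default: all ancestors enter the fresh G1 state).
    Returns the event log: one row per cell with entry/exit times, state,
    generation, fate and ancestor id.  Bit-reproducible under a fixed seed.
    """
    if n_ancestors < 1:
        raise ValueError("need at least one ancestor")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)

    states = graph.states
    fate_probs = [np.array([f.prob for f in st.fates]) for st in states]
    fate_cum = [np.cumsum(p) for p in fate_probs]

    cell_id = 0
    heap: list[tuple[float, int]] = []
    rows: list[tuple] = []

    def spawn(state: int, entry: float, parent: int, ancestor: int):
        nonlocal cell_id
        cid = cell_id
        cell_id += 1
        dur = float(states[state].duration.sample(rng))
        exit_t = entry + dur
        cum = fate_cum[state]
        children: tuple = ()
        if cum.size:
            u = rng.random()
            j = int(np.searchsorted(cum, u, side="right"))
            if j < cum.size:
                children = states[state].fates[j].children
        rows.append((cid, parent, ancestor, state, states[state].name,
                     states[state].generation, entry, exit_t,
                     _fate_label(graph, state, children), children))
        if exit_t <= horizon and children:
            heapq.heappush(heap, (exit_t, cid))
        return cid

    if initial_probs is None:
        start_states = np.full(n_ancestors, graph.fresh["G1"])
    else:
        keys = np.array(list(initial_probs.keys()))
        p = np.array(list(initial_probs.values()), dtype=float)
        p = p / p.sum()
        start_states = keys[rng.choice(len(keys), size=n_ancestors, p=p)]
    for a in range(n_ancestors):
        spawn(int(start_states[a]), 0.0, -1, a)

    while heap:
        exit_t, cid = heapq.heappop(heap)
        _, _, anc, state, _, _, _, _, _, children = rows[cid]
        for child_state, copies in children:
            for _ in range(copies):
                spawn(child_state, exit_t, cid, anc)

    log = pd.DataFrame(
        [r[:9] for r in rows],
        columns=["cell_id", "parent_id", "ancestor", "state", "state_name",
                 "generation", "entry", "exit", "fate"])
    return log


def _occupancy(entry: np.ndarray, exit_: np.ndarray,
               grid: TimeGrid) -> np.ndarray:
    """Number of intervals [entry, exit) covering each grid point."""
    h, n = grid.step, grid.n
    delta = np.zeros(n + 1)
    k_in = np.ceil(entry / h - 1e-12).astype(int)
    k_out = np.ceil(exit_ / h - 1e-12).astype(int)
    np.add.at(delta, np.clip(k_in, 0, n), 1.0)
    np.add.at(delta, np.clip(k_out, 0, n), -1.0)
    return np.cumsum(delta)[:n]


def summarize(log: pd.DataFrame, grid: TimeGrid,
              graph: StateGraph) -> PopulationCurves:
    """Bin an event log into the renewal engine's curve conventions."""
    counts = {p: np.zeros(grid.n) for p in PHASES}
    per_gen: dict[tuple[int, str], np.ndarray] = {}
    apoptotic = np.zeros(grid.n)
    cum_dead = np.zeros(grid.n)
    committed = np.zeros(grid.n)
    if len(log):
        die = log[log["fate"] == "die"]
        if len(die):
            k_in = np.ceil(die["entry"].to_numpy() / grid.step - 1e-12)
            delta = np.zeros(grid.n + 1)
            np.add.at(delta, np.clip(k_in.astype(int), 0, grid.n), 1.0)
            committed = np.cumsum(delta)[:grid.n]
        for state, sub in log.groupby("state"):
            st = graph.states[state]
            occ = _occupancy(sub["entry"].to_numpy(), sub["exit"].to_numpy(),
                             grid)
            if st.phase == "apoptotic":
                apoptotic += occ
                k_in = np.ceil(sub["entry"].to_numpy() / grid.step - 1e-12)
                delta = np.zeros(grid.n + 1)
                np.add.at(delta, np.clip(k_in.astype(int), 0, grid.n), 1.0)
                cum_dead += np.cumsum(delta)[:grid.n]
                continue
            counts[st.phase] += occ
            key = (st.generation, _kind(st.name))
            per_gen[key] = per_gen.get(key, 0.0) + occ
    total = sum(counts.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = {p: np.where(total > 0, counts[p] / total, np.nan)
                     for p in PHASES}
    return PopulationCurves(grid, counts, fractions, per_gen, apoptotic,
                            cum_dead, committed_dead=committed)


def ancestor_phase_counts(log: pd.DataFrame, graph: StateGraph,
                          times: np.ndarray) -> np.ndarray:
    """Per-ancestor live phase counts at given times: (n_anc, 3, n_times).

    Ancestors are independent replicates, so across-ancestor standard errors
    of these counts are valid Monte-Carlo uncertainties for the mean.
    """
    times = np.asarray(times, dtype=float)
    n_anc = int(log["ancestor"].max()) + 1
    out = np.zeros((n_anc, len(PHASES), times.size))
    phase_of = np.array(
        [PHASES.index(s.phase) if s.phase in PHASES else -1
         for s in graph.states])
    ph = phase_of[log["state"].to_numpy()]
    live = ph >= 0
    entry = log["entry"].to_numpy()[live]
    exit_ = log["exit"].to_numpy()[live]
    anc = log["ancestor"].to_numpy()[live]
    phl = ph[live]
    for j, t in enumerate(times):
        sel = (entry <= t) & (exit_ > t)
        np.add.at(out[:, :, j], (anc[sel], phl[sel]), 1.0)
    return out
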