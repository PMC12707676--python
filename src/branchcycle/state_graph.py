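"""Generation-expanded state machines for untreated and drug-exposed cells.

The untreated machine is the plain three-phase cycle: G1 -> S -> G2/M per
generation, with every mitosis producing two G1 daughters of the next
generation.  Drug exposure is introduced by enlarging the per-generation
block with repair/arrest states and death branches:

G2/M-phase drugs (taxanes)
    A cell completing its (residual or full) G2/M time branches into
    unfaithful repair (UR, prob q1), faithful repair (FR, q2), arrest before
    mitotic slippage (MS, q3) or an unperturbed exit.  UR/FR survivors
    divide; an MS survivor slips out of mitosis as a single cell.  Daughters
    of UR and MS mothers inherit damage: they pass through an arrested G1
    (G1arrest) and possibly an arrested S (Sarrest), each realized as a
    Weibull repair downtime convolved with the baseline phase duration, with
    competing death edges drawn from separate Weibull death-time laws.
    Cells that were in G1 at treatment traverse a recalibrated first S phase.

S-phase drugs (gemcitabine)
    A cell completing G1 may be blocked at the G1/S border (G1block, prob
    q1); a cell completing S branches into UR/FR downtime states (q2/q3).
    Damage from unfaithful S repair is carried into an arrested G2/M state
    (G2Marrest) with its own division-or-death fate.  Undamaged generation-1
    lineages traverse a recalibrated first G2/M phase.

The concurrent combination composes both rule sets: G1/S passages obey the
S-drug rules, G2/M passages the G2/M-drug rules, each scaled by its own
dose.  All drug downtimes, death probabilities and branch probabilities are
Hill-scaled, so at dose zero each treated machine reduces exactly to the
untreated one.  Deaths feed a shared apoptotic compartment with a fixed
residence time, after which cells are removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .distributions import (Convolution, Duration, FixedDuration, GammaPhase,
                            ResidualDuration, TimeGrid, WeibullState)
from .dose_response import (EffectiveG2MParams, EffectiveSParams, scale_g2m,
                            scale_s)
from .params import (APOPTOTIC_DURATION_H, BaselineParams, G2MTreatmentParams,
                     STreatmentParams)
from .steady_state import growth_rate

__all__ = ["State", "Fate", "StateGraph", "build_untreated",
           "build_g2m_treated", "build_s_treated", "build_combination",
           "residual_duration_cdf"]

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class Fate:
    """One branch outcome: probability and the (state, copies) children."""

    prob: float
    children: tuple[tuple[int, int], ...] = ()


@dataclass
class State:
    name: str
    phase: str          # 'G1' | 'S' | 'G2M' | 'apoptotic'
    generation: int
    cohort: str         # 'pre' (cycling at treatment) | 'post'
    duration: Duration
    fates: list[Fate] = field(default_factory=list)


class StateGraph:
    """States, branching law and duration CDFs of one model variant."""

    def __init__(self, states: list[State], apoptotic: int,
                 fresh: dict[str, int], occupants: dict[str, int] | None = None):
        self.states = states
        self.apoptotic = apoptotic
        self.fresh = fresh            # phase label -> fresh gen-1 state index
        self.occupants = occupants    # phase label -> pre-treatment occupant
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def m_matrix(self) -> np.ndarray:
        """Expected-offspring matrix: m[i, j] per completed state i."""
        m = np.zeros((self.n_states, self.n_states))
        for i, st in enumerate(self.states):
            for fate in st.fates:
                for child, k in fate.children:
                    m[i, child] += fate.prob * k
        return m

    def live_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.states)
                         if s.phase != "apoptotic"], dtype=int)

    def kernels(self, grid: TimeGrid) -> np.ndarray:
        cache: dict[int, np.ndarray] = {}
        rows = []
        for s in self.states:  # states share duration objects: discretize once
            key = id(s.duration)
            if key not in cache:
                cache[key] = s.duration.kernel(grid)
            rows.append(cache[key])
        return np.stack(rows)

    def survivals(self, grid: TimeGrid) -> np.ndarray:
        """Per-state survival consistent with the discretized kernels.

        Computed as ``1 - cumsum(kernel)`` so that occupancy plus departed
        mass is conserved exactly bin by bin; together with the centered
        kernels this makes every propagated quantity an O(step^2)-accurate
        observation at ``t_k + step/2`` (recentered in the engine).
        """
        return np.clip(1.0 - np.cumsum(self.kernels(grid), axis=1), 0.0, 1.0)

    def topo_order(self) -> list[int]:
        """Topological order; raises if the graph has a directed cycle."""
        children = [set() for _ in range(self.n_states)]
        indeg = [0] * self.n_states
        for i, st in enumerate(self.states):
            for fate in st.fates:
                for child, _k in fate.children:
                    if child not in children[i]:
                        children[i].add(child)
                        indeg[child] += 1
        order, stack = [], [i for i in range(self.n_states) if indeg[i] == 0]
        while stack:
            i = stack.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != self.n_states:
            raise ValueError("state graph contains a directed cycle")
        return order

    def longest_path(self) -> int:
        """Number of edges on the longest directed path (Neumann depth)."""
        depth = [0] * self.n_states
        for i in reversed(self.topo_order()):
            best = 0
            for fate in self.states[i].fates:
                for child, _k in fate.children:
                    best = max(best, 1 + depth[child])
            depth[i] = best
        return max(depth, default=0)

    def validate(self) -> None:
        for i, st in enumerate(self.states):
            total = 0.0
            for fate in st.fates:
                if fate.prob < -1e-12:
                    raise ValueError(
                        f"state {st.name}: negative fate probability")
                total += fate.prob
                for child, k in fate.children:
                    if k == 2 and st.phase != "G2M":
                        raise ValueError(
                            f"state {st.name}: division out of a "
                            f"non-G2M state")
                    if k not in (1, 2):
                        raise ValueError(
                            f"state {st.name}: invalid multiplicity {k}")
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"state {st.name}: fate probabilities sum to {total}")
        if self.states[self.apoptotic].fates:
            raise ValueError("apoptotic state must be absorbing")
        self.topo_order()

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def dur_desc(d: Duration):
            if isinstance(d, GammaPhase):
                return {"family": "gamma", "shape": d.shape, "rate": d.rate}
            if isinstance(d, WeibullState):
                return {"family": "weibull", "shape": d.shape,
                        "scale": d.scale}
            if isinstance(d, FixedDuration):
                return {"family": "fixed", "value": d.value}
            if isinstance(d, Convolution):
                return {"family": "convolution",
                        "parts": [dur_desc(p) for p in d.parts]}
            if isinstance(d, ResidualDuration):
                return {"family": "residual",
                        "growth_rate": d.growth_rate,
                        "phase": dur_desc(d.phase)}
            return {"family": type(d).__name__}

        payload = {
            "states": [
                {"index": i, "name": s.name, "phase": s.phase,
                 "generation": s.generation, "cohort": s.cohort,
                 "duration": dur_desc(s.duration),
                 "fates": [{"prob": f.prob,
                            "children": [list(c) for c in f.children]}
                           for f in s.fates]}
                for i, s in enumerate(self.states)],
            "apoptotic": self.apoptotic,
            "fresh": self.fresh,
            "occupants": self.occupants,
        }
        return json.dumps(payload, indent=1)


import functools


@functools.lru_cache(maxsize=64)
def residual_duration_cdf(phase: GammaPhase, gamma_rate: float,
                          t_max: float = 120.0) -> ResidualDuration:
    """Residual-time law of a phase observed in exponential balanced growth.

    Returns a :class:`~branchcycle.distributions.ResidualDuration`; its
    ``.cdf`` is the callable CDF.  ``gamma_rate = 0`` gives the classical
    equilibrium residual-life distribution.  Cached: repeated graph builds
    with the same baseline reuse the numeric construction.
    """
    return ResidualDuration(phase, gamma_rate, t_max=t_max)


# ---------------------------------------------------------------------------
# builders

class _Builder:
    def __init__(self) -> None:
        self.states: list[State] = []

    def add(self, name, phase, gen, cohort, duration) -> int:
        self.states.append(State(name, phase, gen, cohort, duration))
        return len(self.states) - 1

    def set_fates(self, idx: int, fates) -> None:
        self.states[idx].fates = [Fate(p, tuple(children))
                                  for p, children in fates if p > 0.0]


def build_untreated(params: BaselineParams) -> StateGraph:
    """Plain cycling machine: 3 states per generation, division x2."""
    b = _Builder()
    psi = [GammaPhase(a, params.beta0) for a in params.shapes]
    idx = {}
    for g in range(1, params.n_gen + 1):
        for p, d in zip(PHASES, psi):
            idx[(p, g)] = b.add(f"{p}_g{g}", p, g, "post", d)
    apop = b.add("apoptotic", "apoptotic", 0, "post",
                 FixedDuration(APOPTOTIC_DURATION_H))
    for g in range(1, params.n_gen + 1):
        b.set_fates(idx[("G1", g)], [(1.0, [(idx[("S", g)], 1)])])
        b.set_fates(idx[("S", g)], [(1.0, [(idx[("G2M", g)], 1)])])
        if g < params.n_gen:
            b.set_fates(idx[("G2M", g)],
                        [(1.0, [(idx[("G1", g + 1)], 2)])])
        else:
            b.set_fates(idx[("G2M", g)], [])
    fresh = {p: idx[(p, 1)] for p in PHASES}
    return StateGraph(b.states, apop, fresh)


def _build_treated(base: BaselineParams,
                   g2m: EffectiveG2MParams | None,
                   s: EffectiveSParams | None,
                   grid: TimeGrid,
                   apoptotic_duration: float = APOPTOTIC_DURATION_H,
                   with_occupants: bool = True) -> StateGraph:
    """Shared constructor for single-drug and combination machines."""
    b = _Builder()
    n_gen = base.n_gen
    psi1, psi2, psi3 = (GammaPhase(a, base.beta0) for a in base.shapes)
    gam = growth_rate(base)
    t_res = float(grid.horizon) + 1.0

    # durations ------------------------------------------------------------
    if g2m is not None:
        w_ur = WeibullState(g2m.b_g2m, g2m.lam_ur)
        w_fr = WeibullState(g2m.b_g2m, g2m.lam_fr)
        w_ms = WeibullState(g2m.b_g2m, g2m.lam_ms)
        d_g1a_live = Convolution(WeibullState(g2m.b_g2m, g2m.lam_g1arrest), psi1)
        d_g1a_die = WeibullState(g2m.b_dg2m, g2m.lam_dg1)
        d_sa_live = Convolution(WeibullState(g2m.b_g2m, g2m.lam_sarrest), psi2)
        d_sa_die = WeibullState(g2m.b_dg2m, g2m.lam_ds)
        s_first = Convolution(psi2, WeibullState(g2m.b_s, g2m.a_s_scale))
    else:
        s_first = psi2
    if s is not None:
        w_g1block = WeibullState(s.b_s, s.lam_g1block)
        w_ur_s = WeibullState(s.b_s, s.lam_ur)
        w_fr_s = WeibullState(s.b_s, s.lam_fr)
        d_g2ma_live = Convolution(WeibullState(s.b_s, s.lam_g2marrest), psi3)
        d_g2ma_die = WeibullState(s.b_ds, s.lam_dg2m)
        g2m_first = Convolution(psi3, WeibullState(s.b_g2m, s.a_g2m_scale))
    else:
        g2m_first = psi3

    # states ---------------------------------------------------------------
    idx: dict[tuple, int] = {}

    def _add(key, name, phase, gen, dur, cohort="post"):
        idx[key] = b.add(name, phase, gen, cohort, dur)

    for g in range(1, n_gen + 1):
        _add(("G1", g), f"G1_g{g}", "G1", g, psi1)
        if s is not None:
            _add(("G1block", g), f"G1block_g{g}", "G1", g, w_g1block)
        _add(("S", g), f"S_g{g}", "S", g, s_first if g == 1 else psi2)
        if s is not None:
            _add(("UR_S", g), f"UR_S_g{g}", "S", g, w_ur_s)
            _add(("FR_S", g), f"FR_S_g{g}", "S", g, w_fr_s)
            _add(("G2Ma_in", g), f"G2Marrest_in_g{g}", "G2M", g,
                 FixedDuration(0.0))
            _add(("G2Ma_live", g), f"G2Marrest_g{g}", "G2M", g, d_g2ma_live)
            _add(("G2Ma_die", g), f"G2Marrest_dying_g{g}", "G2M", g,
                 d_g2ma_die)
        _add(("G2M", g), f"G2M_g{g}", "G2M", g,
             g2m_first if g == 1 else psi3)
        if g2m is not None:
            _add(("UR", g), f"UR_g{g}", "G2M", g, w_ur)
            _add(("FR", g), f"FR_g{g}", "G2M", g, w_fr)
            _add(("MS", g), f"MS_g{g}", "G2M", g, w_ms)
            if g >= 2:
                _add(("G1a_in", g), f"G1arrest_in_g{g}", "G1", g,
                     FixedDuration(0.0))
                _add(("G1a_live", g), f"G1arrest_g{g}", "G1", g, d_g1a_live)
                _add(("G1a_die", g), f"G1arrest_dying_g{g}", "G1", g,
                     d_g1a_die)
                _add(("Sa_in", g), f"Sarrest_in_g{g}", "S", g,
                     FixedDuration(0.0))
                _add(("Sa_live", g), f"Sarrest_g{g}", "S", g, d_sa_live)
                _add(("Sa_die", g), f"Sarrest_dying_g{g}", "S", g, d_sa_die)
    occ = None
    if with_occupants:
        _add(("G1occ", 1), "G1_cycling", "G1", 1,
             residual_duration_cdf(psi1, gam, t_res), cohort="pre")
        _add(("Socc", 1), "S_cycling", "S", 1,
             residual_duration_cdf(psi2, gam, t_res), cohort="pre")
        _add(("G2Mocc", 1), "G2M_cycling", "G2M", 1,
             residual_duration_cdf(psi3, gam, t_res), cohort="pre")
        occ = {"G1": idx[("G1occ", 1)], "S": idx[("Socc", 1)],
               "G2M": idx[("G2Mocc", 1)]}
    apop = b.add("apoptotic", "apoptotic", 0, "post",
                 FixedDuration(apoptotic_duration))

    # flows ----------------------------------------------------------------
    def s_entry(g):
        """Branches taken when a G1-type progression completes."""
        if s is not None:
            return [(s.q1, [(idx[("G1block", g)], 1)]),
                    (1.0 - s.q1, [(idx[("S", g)], 1)])]
        return [(1.0, [(idx[("S", g)], 1)])]

    def s_exit(g):
        """Branches taken when an S-type progression completes."""
        if s is not None:
            return [(s.q2, [(idx[("UR_S", g)], 1)]),
                    (s.q3, [(idx[("FR_S", g)], 1)]),
                    (1.0 - s.q2 - s.q3, [(idx[("G2M", g)], 1)])]
        return [(1.0, [(idx[("G2M", g)], 1)])]

    def division(g):
        """Two fresh G1 daughters, truncated past the last generation."""
        if g < n_gen:
            return [(idx[("G1", g + 1)], 2)]
        return []

    def g2m_exit(g):
        """Branches taken when a G2/M-type progression completes."""
        if g2m is not None:
            return [(g2m.q1, [(idx[("UR", g)], 1)]),
                    (g2m.q2, [(idx[("FR", g)], 1)]),
                    (g2m.q3, [(idx[("MS", g)], 1)]),
                    (1.0 - g2m.q1 - g2m.q2 - g2m.q3, division(g))]
        return [(1.0, division(g))]

    for g in range(1, n_gen + 1):
        b.set_fates(idx[("G1", g)], s_entry(g))
        b.set_fates(idx[("S", g)], s_exit(g))
        b.set_fates(idx[("G2M", g)], g2m_exit(g))
        if s is not None:
            b.set_fates(idx[("G1block", g)],
                        [(s.md_g1block, [(apop, 1)]),
                         (1.0 - s.md_g1block, [(idx[("S", g)], 1)])])
            b.set_fates(idx[("UR_S", g)],
                        [(s.md_ur, [(apop, 1)]),
                         (1.0 - s.md_ur, [(idx[("G2Ma_in", g)], 1)])])
            b.set_fates(idx[("FR_S", g)],
                        [(s.md_fr, [(apop, 1)]),
                         (1.0 - s.md_fr, [(idx[("G2M", g)], 1)])])
            b.set_fates(idx[("G2Ma_in", g)],
                        [(s.md_g2marrest, [(idx[("G2Ma_die", g)], 1)]),
                         (1.0 - s.md_g2marrest, [(idx[("G2Ma_live", g)], 1)])])
            b.set_fates(idx[("G2Ma_die", g)], [(1.0, [(apop, 1)])])
            b.set_fates(idx[("G2Ma_live", g)], g2m_exit(g))
        if g2m is not None:
            def damaged_daughters(g, k):
                if g < n_gen:
                    return [(idx[("G1a_in", g + 1)], k)]
                return []
            b.set_fates(idx[("UR", g)],
                        [(g2m.md_ur, [(apop, 1)]),
                         (1.0 - g2m.md_ur, damaged_daughters(g, 2))])
            b.set_fates(idx[("FR", g)],
                        [(g2m.md_fr, [(apop, 1)]),
                         (1.0 - g2m.md_fr, division(g))])
            b.set_fates(idx[("MS", g)],
                        [(g2m.md_ms, [(apop, 1)]),
                         (1.0 - g2m.md_ms, damaged_daughters(g, 1))])
            if g >= 2:
                b.set_fates(idx[("G1a_in", g)],
                            [(g2m.md_g1arrest, [(idx[("G1a_die", g)], 1)]),
                             (1.0 - g2m.md_g1arrest,
                              [(idx[("G1a_live", g)], 1)])])
                b.set_fates(idx[("G1a_die", g)], [(1.0, [(apop, 1)])])
                live = 1.0 - g2m.md_g1arrest
                p_normal = g2m.q4 / live if live > 0 else 0.0
                p_normal = min(p_normal, 1.0)
                # damaged daughters that shed their damage re-enter the
                # ordinary G1/S border (block rules apply); the rest carry
                # damage into an arrested S phase
                fates = [(p_normal * p, ch) for p, ch in s_entry(g)]
                fates.append((1.0 - p_normal, [(idx[("Sa_in", g)], 1)]))
                b.set_fates(idx[("G1a_live", g)], fates)
                b.set_fates(idx[("Sa_in", g)],
                            [(g2m.md_sarrest, [(idx[("Sa_die", g)], 1)]),
                             (1.0 - g2m.md_sarrest,
                              [(idx[("Sa_live", g)], 1)])])
                b.set_fates(idx[("Sa_die", g)], [(1.0, [(apop, 1)])])
                b.set_fates(idx[("Sa_live", g)], s_exit(g))
    if with_occupants:
        b.set_fates(idx[("G1occ", 1)], s_entry(1))
        b.set_fates(idx[("Socc", 1)], s_exit(1))
        b.set_fates(idx[("G2Mocc", 1)], g2m_exit(1))

    fresh = {p: idx[(p, 1)] for p in PHASES}
    return StateGraph(b.states, apop, fresh, occ)


def build_g2m_treated(base: BaselineParams, trt: G2MTreatmentParams,
                      dose: float, grid: TimeGrid,
                      **kwargs) -> StateGraph:
    """Machine for a G2/M-phase drug (taxane) at ``dose`` nM."""
    return _build_treated(base, scale_g2m(trt, dose), None, grid, **kwargs)


def build_s_treated(base: BaselineParams, trt: STreatmentParams,
                    dose: float, grid: TimeGrid, **kwargs) -> StateGraph:
    """Machine for an S-phase drug (gemcitabine) at ``dose`` nM."""
    return _build_treated(base, None, scale_s(trt, dose), grid, **kwargs)


def build_combination(base: BaselineParams, g2m: G2MTreatmentParams,
                      s: STreatmentParams, dose_g2m: float, dose_s: float,
                      grid: TimeGrid, **kwargs) -> StateGraph:
    """Concurrent combination machine, each drug scaled by its own dose."""
    return _build_treated(base, scale_g2m(g2m, dose_g2m),
                          scale_s(s, dose_s), grid, **kwargs)
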