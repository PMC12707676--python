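"""Structure and semantics of the untreated and drug-exposed state machines."""

import json
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from branchcycle.distributions import GammaPhase, TimeGrid
from branchcycle.params import (DOSE_LADDERS, MODEL2_BASELINE, MODEL2_G2M,
                                MODEL3_S, BaselineParams)
from branchcycle.renewal_engine import _run
from branchcycle.state_graph import (build_combination, build_g2m_treated,
                                     build_s_treated, build_untreated,
                                     residual_duration_cdf)

PHASES = ("G1", "S", "G2M")


class TestUntreatedGraph:
    def test_single_generation_truncates_division(self):
        g = build_untreated(BaselineParams(9.0, 9.0, 10.0, 1.8, n_gen=1))
        live = [s for s in g.states if s.phase != "apoptotic"]
        assert len(live) == 3
        g2m = next(i for i, s in enumerate(g.states) if s.name == "G2M_g1")
        assert not g.states[g2m].fates

    def test_mitosis_yields_two_daughters(self):
        g = build_untreated(BaselineParams(9.0, 9.0, 10.0, 1.8, n_gen=2))
        m = g.m_matrix()
        i = next(k for k, s in enumerate(g.states) if s.name == "G2M_g1")
        j = next(k for k, s in enumerate(g.states) if s.name == "G1_g2")
        assert m[i, j] == 2.0
        assert m[i].sum() == 2.0

    def test_row_offspring_counts_are_zero_one_or_two(self, base2):
        g = build_untreated(base2)
        sums = g.m_matrix().sum(axis=1)
        assert set(np.round(sums, 12)) <= {0.0, 1.0, 2.0}


class TestTreatedGraphStructure:
    def test_saturating_dose_normal_exit_probability(self, base2, grid72):
        # q1 + q2 + q3 = 0.619 + 0.119 + 0.102 at full effect
        g = build_g2m_treated(base2, MODEL2_G2M, 1e9, grid72)
        i = next(k for k, s in enumerate(g.states) if s.name == "G2M_g2")
        normal = [f for f in g.states[i].fates
                  if any(g.states[c].name == "G1_g3" for c, _ in f.children)]
        assert normal[0].prob == pytest.approx(0.160, abs=1e-3)

    def test_surviving_repair_states_divide_slippage_does_not(self, base2,
                                                              grid72):
        g = build_g2m_treated(base2, MODEL2_G2M, 120.0, grid72)
        m = g.m_matrix()
        live = g.live_indices()
        for k, s in enumerate(g.states):
            if s.name.startswith("UR_g") and s.generation < base2.n_gen:
                assert m[k, live].sum() == pytest.approx(
                    2.0 * (1.0 - _md_ur(120.0)))
            if s.name.startswith("MS_g") and s.generation < base2.n_gen:
                assert m[k, live].sum() == pytest.approx(
                    1.0 * (1.0 - _md_ms(120.0)))

    @pytest.mark.parametrize("drug", ["g2m", "s", "combination"])
    def test_fate_rows_are_subprobability_on_dose_ladder(self, base2, grid72,
                                                         drug):
        ladders = {"g2m": DOSE_LADDERS["paclitaxel"],
                   "s": DOSE_LADDERS["gemcitabine"],
                   "combination": DOSE_LADDERS["paclitaxel"]}
        for dose in ladders[drug]:
            if drug == "g2m":
                g = build_g2m_treated(base2, MODEL2_G2M, dose, grid72)
            elif drug == "s":
                g = build_s_treated(base2, MODEL3_S, dose, grid72)
            else:
                g = build_combination(base2, MODEL2_G2M, MODEL3_S, dose,
                                      dose / 2.0, grid72)
            for st in g.states:
                total = sum(f.prob for f in st.fates)
                assert -1e-12 <= total <= 1.0 + 1e-9
            # validate() re-checks multiplicities and acyclicity
            g.validate()

    def test_dead_state_absorbing_and_graph_acyclic(self, base2, grid72):
        g = build_combination(base2, MODEL2_G2M, MODEL3_S, 120.0, 260.0,
                              grid72)
        assert not g.states[g.apoptotic].fates
        g.topo_order()  # raises on a cycle

    def test_json_serialization_round_trips_labels(self, base2, grid72):
        g = build_g2m_treated(base2, MODEL2_G2M, 120.0, grid72)
        payload = json.loads(g.to_json())
        assert len(payload["states"]) == g.n_states
        assert payload["states"][g.apoptotic]["phase"] == "apoptotic"
        assert payload["occupants"]["G1"] == g.occupants["G1"]


def _md_ur(dose):
    from branchcycle.dose_response import scale_g2m
    return scale_g2m(MODEL2_G2M, dose).md_ur


def _md_ms(dose):
    from branchcycle.dose_response import scale_g2m
    return scale_g2m(MODEL2_G2M, dose).md_ms


class TestNullDoseEquivalence:
    def test_both_drug_machines_reduce_to_untreated(self, base2, grid):
        gu = build_untreated(base2)
        ref = _run(gu, grid, {gu.fresh["G1"]: 1.0})
        for build, trt in ((build_g2m_treated, MODEL2_G2M),
                           (build_s_treated, MODEL3_S)):
            g = build(base2, trt, 0.0, grid)
            got = _run(g, grid, {g.fresh["G1"]: 1.0})
            for p in PHASES:
                np.testing.assert_allclose(got.counts[p], ref.counts[p],
                                           atol=1e-8)

    def test_combination_reduces_to_each_single_drug(self, base2, grid):
        for dose_g2m, dose_s, build, trt in (
                (120.0, 0.0, build_g2m_treated, MODEL2_G2M),
                (0.0, 260.0, build_s_treated, MODEL3_S)):
            comb = build_combination(base2, MODEL2_G2M, MODEL3_S, dose_g2m,
                                     dose_s, grid)
            single = build(base2, trt, dose_g2m or dose_s, grid)
            got = _run(comb, grid, {comb.fresh["G1"]: 1.0})
            ref = _run(single, grid, {single.fresh["G1"]: 1.0})
            for p in PHASES:
                np.testing.assert_allclose(got.counts[p], ref.counts[p],
                                           atol=1e-8)


class TestResidualDuration:
    def test_exponential_phase_is_memoryless(self):
        ph = GammaPhase(1.0, 0.5)
        res = residual_duration_cdf(ph, 0.03, t_max=60.0)
        for t in (0.5, 2.0, 5.0, 10.0, 20.0):
            assert res.cdf(t) == pytest.approx(float(ph.cdf(t)), abs=2e-3)

    def test_zero_growth_matches_equilibrium_residual_life(self):
        ph = GammaPhase(6.0, 1.2)
        res = residual_duration_cdf(ph, 0.0, t_max=60.0)
        for t in (1.0, 3.0, 6.0, 10.0):
            want = quad(lambda u: 1.0 - ph.cdf(u), 0, t)[0] / ph.mean
            assert res.cdf(t) == pytest.approx(want, abs=1e-3)

    def test_residual_mean_below_full_mean(self):
        # observing mid-phase can only shorten the remaining time
        for gam in (0.0, 0.05, 0.2):
            ph = GammaPhase(9.215, 1.824)
            res = residual_duration_cdf(ph, gam, t_max=60.0)
            assert res.mean <= ph.mean
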