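"""Expected-count engine: identities, partitions, treatment runs."""

from dataclasses import replace

import numpy as np
import pytest

from branchcycle.distributions import GammaPhase, TimeGrid
from branchcycle.params import (BaselineParams, MODEL2_BASELINE, MODEL2_G2M,
                                MODEL3_S)
from branchcycle.renewal_engine import (compute_moment_field,
                                        expected_phase_counts,
                                        per_generation_breakdown,
                                        simulate_treatment_run,
                                        simulate_untreated, _run)
from branchcycle.state_graph import (build_g2m_treated, build_untreated,
                                     build_s_treated)
from branchcycle.steady_state import asymptotic_fractions, growth_rate

PHASES = ("G1", "S", "G2M")


class TestMomentField:
    def test_identity_at_time_zero(self, base2, grid):
        g = build_untreated(base2)
        field = compute_moment_field(g, grid)
        np.testing.assert_allclose(field.M[0], np.eye(g.n_states),
                                   atol=1e-12)

    def test_single_state_graph_is_survival_function(self):
        g = build_untreated(BaselineParams(9.0, 9.0, 10.0, 1.8, n_gen=1))
        grid = TimeGrid(0.1, 30.0)
        field = compute_moment_field(g, grid)
        i = next(k for k, s in enumerate(g.states) if s.name == "G2M_g1")
        # a childless state only holds its own ancestor while it lasts
        expect = 1.0 - GammaPhase(10.0, 1.8).cdf(grid.points)
        np.testing.assert_allclose(field.M[:, i, i], expect, atol=2e-3)

    def test_linearity_in_initial_condition(self, base2, grid):
        g = build_untreated(base2)
        field = compute_moment_field(g, grid)
        one = expected_phase_counts(field, {g.fresh["G1"]: 1.0})
        three = expected_phase_counts(field, {g.fresh["G1"]: 3.0})
        for p in PHASES:
            np.testing.assert_allclose(three.counts[p], 3.0 * one.counts[p],
                                       rtol=1e-12)
            np.testing.assert_allclose(three.fractions[p], one.fractions[p],
                                       rtol=1e-9)

    def test_initial_pure_g1_gives_unit_g1_fraction(self, base2, grid):
        g = build_untreated(base2)
        field = compute_moment_field(g, grid)
        curves = expected_phase_counts(field, {g.fresh["G1"]: 1.0})
        assert curves.fractions["G1"][0] == pytest.approx(1.0)
        assert curves.fractions["S"][0] == pytest.approx(0.0)

    def test_empty_initial_condition_rejected(self, base2, grid):
        field = compute_moment_field(build_untreated(base2), grid)
        with pytest.raises(ValueError):
            expected_phase_counts(field, {})


class TestPartitions:
    def test_per_generation_sums_to_phase_counts(self, base2, grid):
        g = build_g2m_treated(base2, MODEL2_G2M, 120.0, grid)
        fr = asymptotic_fractions(base2)
        curves = _run(g, grid, {g.occupants[p]: f
                                for p, f in zip(PHASES, fr)})
        total = sum(curves.counts[p] for p in PHASES)
        parts = sum(curves.per_generation.values())
        np.testing.assert_allclose(parts, total, atol=1e-9)

    def test_single_generation_has_no_second_generation_curves(self):
        p = BaselineParams(9.0, 9.0, 10.0, 1.8, n_gen=1)
        curves = simulate_untreated(p, TimeGrid(0.1, 30.0))
        assert all(gen == 1 for gen, _kind in curves.per_generation)

    def test_fractions_sum_to_one_over_live_states(self, base2, grid):
        curves = simulate_untreated(base2, grid)
        total = sum(np.asarray(curves.fractions[p]) for p in PHASES)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_ur_accumulates_faster_than_fr_when_q1_exceeds_q2(self, base2,
                                                              grid):
        field = compute_moment_field(
            build_g2m_treated(base2, MODEL2_G2M, 120.0, grid), grid)
        g = field.graph
        breakdown = per_generation_breakdown(
            field, {g.occupants["G2M"]: 1.0})
        ur = sum(v for (gen, kind), v in breakdown.items() if kind == "UR")
        fr = sum(v for (gen, kind), v in breakdown.items() if kind == "FR")
        k24 = grid.index_of(24.0)
        assert ur[k24] > fr[k24]


class TestExponentialGrowth:
    def test_log_total_slope_matches_malthusian_rate(self):
        params = replace(MODEL2_BASELINE, n_gen=14)
        curves = simulate_untreated(params, TimeGrid(0.1, 170.0))
        t = curves.grid.points
        sel = t >= 110.0  # asymptotic regime
        slope = np.polyfit(t[sel], np.log(curves.total_live[sel]), 1)[0]
        assert slope == pytest.approx(growth_rate(MODEL2_BASELINE), rel=0.02)


class TestTreatmentRun:
    def test_zero_dose_run_stays_at_asymptotic_fractions(self, base2):
        grid = TimeGrid(0.1, 40.0)
        curves, _ = simulate_treatment_run(
            base2, g2m=MODEL2_G2M, dose_g2m=0.0, grid=grid,
            initial_fractions="asymptotic", t_ssd=0.0)
        for p, want in zip(PHASES, asymptotic_fractions(base2)):
            np.testing.assert_allclose(curves.fractions[p], want, atol=5e-3)

    def test_treatment_time_snapshot_matches_asymptotic_state(self, base2):
        grid = TimeGrid(0.1, 24.0)
        curves, t_ssd = simulate_treatment_run(
            base2, g2m=MODEL2_G2M, dose_g2m=120.0, grid=grid)
        assert t_ssd is not None
        for p, want in zip(PHASES, asymptotic_fractions(base2)):
            assert curves.fractions[p][0] == pytest.approx(want, abs=0.02)

    def test_g1_accumulation_under_s_phase_drug(self, base2):
        # a strong G1/S block (q1 = 0.789) piles cells up in G1 within the
        # first cycle after gemcitabine exposure
        grid = TimeGrid(0.1, 30.0)
        curves, _ = simulate_treatment_run(
            base2, s=MODEL3_S, dose_s=260.0, grid=grid,
            initial_fractions="asymptotic", t_ssd=0.0)
        g1_0 = curves.fractions["G1"][0]
        assert curves.fractions["G1"][:grid.index_of(16.0)].max() > g1_0 + 0.1

    def test_grid_refinement_changes_fractions_below_half_percent(self,
                                                                  base2):
        vals = {}
        for step in (0.1, 0.05):
            grid = TimeGrid(step, 48.0)
            curves, _ = simulate_treatment_run(
                base2, g2m=MODEL2_G2M, dose_g2m=120.0, grid=grid,
                initial_fractions="asymptotic", t_ssd=0.0)
            vals[step] = {p: np.asarray(curves.fractions[p])[
                [grid.index_of(t) for t in (6.0, 12.0, 24.0, 48.0)]]
                for p in PHASES}
        for p in PHASES:
            assert np.max(np.abs(vals[0.1][p] - vals[0.05][p])) < 0.005
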