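"""Likelihood/posterior identities and RAM sampler behavior."""

import numpy as np
import pytest

from branchcycle.calibration import (NoiseParams, TrajectoryData,
                                     log_likelihood, log_posterior,
                                     ram_sample, summarize_chain)


def _data(times=None, fractions=None, steady=None):
    times = np.array([1.0, 2.0]) if times is None else times
    if fractions is None:
        fractions = np.array([[0.5, 0.3, 0.2], [0.4, 0.35, 0.25]])
    return TrajectoryData(times, fractions, steady)


class TestLogLikelihood:
    def test_perfect_fit_closed_form_zero(self):
        # sigma^2 = 1/(2*pi) makes the normalization vanish; with zero
        # residuals and n_p = 2 the log-likelihood is exactly 0
        data = _data()
        noise = NoiseParams((1.0 / (2 * np.pi),) * 3)
        ll = log_likelihood(None, noise, data, lambda _t: data.fractions)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_doubling_residuals_quadruples_quadratic_term(self):
        data = _data()
        noise = NoiseParams((0.01, 0.01, 0.01))
        base = data.fractions

        def shifted(delta):
            return log_likelihood(None, noise, data, lambda _t: base + delta)

        l0 = shifted(0.0)
        l1 = shifted(0.01)
        l2 = shifted(0.02)
        assert (l0 - l2) == pytest.approx(4.0 * (l0 - l1), rel=1e-9)

    def test_matches_independent_direct_summation(self):
        rng = np.random.default_rng(3)
        times = np.arange(1.0, 9.0)
        obs = rng.uniform(0.1, 0.6, size=(8, 3))
        pred = rng.uniform(0.1, 0.6, size=(8, 3))
        s2 = rng.uniform(0.001, 0.02, size=3)
        data = TrajectoryData(times, obs)
        got = log_likelihood(None, NoiseParams(tuple(s2)), data,
                             lambda _t: pred)
        want = 0.0
        for p in range(3):
            for j in range(8):
                want += (-0.5 * np.log(2 * np.pi * s2[p])
                         - (pred[j, p] - obs[j, p]) ** 2 / (2 * s2[p]))
        assert got == pytest.approx(want, rel=1e-12)

    def test_nonpositive_variance_is_rejected_point(self):
        data = _data()
        bad = NoiseParams.__new__(NoiseParams)
        object.__setattr__(bad, "sigma2", (0.0, 0.01, 0.01))
        assert log_likelihood(None, bad, data,
                              lambda _t: data.fractions) == -np.inf

    def test_invariant_to_time_point_ordering(self):
        rng = np.random.default_rng(4)
        times = np.arange(1.0, 7.0)
        obs = rng.uniform(0.1, 0.6, size=(6, 3))
        noise = NoiseParams((0.01, 0.01, 0.01))
        pred = rng.uniform(0.1, 0.6, size=(6, 3))
        fwd = log_likelihood(None, noise, TrajectoryData(times, obs),
                             lambda _t: pred)
        # same pairs presented in reverse order
        rev = log_likelihood(None, noise,
                             TrajectoryData(times, obs[::-1]),
                             lambda _t: pred[::-1])
        assert fwd == pytest.approx(rev, rel=1e-12)


class TestLogPosterior:
    def test_outside_any_bound_is_minus_infinity(self):
        data = _data()
        bounds = [(0.0, 1.0)] * 2 + [(1e-6, 0.1)] * 3
        model = lambda t: data.fractions
        assert log_posterior([1.5, 0.5, 0.01, 0.01, 0.01], data, model,
                             bounds, 2) == -np.inf

    def test_inside_bounds_equals_likelihood(self):
        data = _data()
        bounds = [(0.0, 1.0)] * 2 + [(1e-6, 0.1)] * 3
        model = lambda t: data.fractions
        lp = log_posterior([0.5, 0.5, 0.01, 0.01, 0.01], data, model,
                           bounds, 2)
        ll = log_likelihood(None, NoiseParams((0.01,) * 3), data, model)
        assert lp == pytest.approx(ll)


class TestRamSampler:
    def test_same_seed_identical_chains(self):
        lp = lambda x: -0.5 * float(x @ x)
        a = ram_sample(lp, np.zeros(3), 500, seed=11)
        b = ram_sample(lp, np.zeros(3), 500, seed=11)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_acceptance_adapts_toward_target(self):
        lp = lambda x: -0.5 * float(x @ x)
        chain = ram_sample(lp, np.zeros(2), 20_000, seed=7)
        assert np.mean(chain.accepted[10_000:]) == pytest.approx(0.234,
                                                                 abs=0.03)

    def test_gaussian_target_moments_recovered(self):
        lp = lambda x: -0.5 * float(x @ x)
        chain = ram_sample(lp, np.zeros(2), 20_000, seed=8)
        tail = chain.draws[10_000:]
        se = 1.0 / np.sqrt(tail.shape[0] / 20)  # crude ESS-adjusted error
        assert np.all(np.abs(tail.mean(axis=0)) < 3 * se)

    def test_posterior_constant_shift_leaves_chain_unchanged(self):
        # the dropped normalizing constant cannot affect the chain (up to
        # floating-point rounding of the acceptance-ratio subtraction)
        lp = lambda x: -0.5 * float(x @ x)
        shifted = lambda x: lp(x) + 123.4
        a = ram_sample(lp, np.zeros(2), 2_000, seed=5)
        b = ram_sample(shifted, np.zeros(2), 2_000, seed=5)
        np.testing.assert_allclose(a.draws, b.draws, atol=1e-9)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            ram_sample(lambda x: -np.inf, np.zeros(2), 10, seed=0)


class TestSummarizeChain:
    def test_constant_chain_zero_width_interval(self):
        lp = lambda x: 0.0
        chain = ram_sample(lambda x: 0.0, np.array([2.0]), 100, seed=0,
                           s0=np.zeros((1, 1)))
        tab = summarize_chain(chain, burn_in_frac=0.5)
        assert tab["ci_low"].iloc[0] == tab["ci_high"].iloc[0] == \
            tab["mean"].iloc[0] == pytest.approx(2.0)

    def test_zero_ci_level_degenerates_to_median(self):
        lp = lambda x: -0.5 * float(x @ x)
        chain = ram_sample(lp, np.zeros(1), 2_000, seed=1)
        tab = summarize_chain(chain, ci_level=0.0)
        assert tab["ci_low"].iloc[0] == pytest.approx(
            tab["ci_high"].iloc[0])


class TestTrajectoryData:
    def test_frame_round_trip(self):
        d = _data()
        d2 = TrajectoryData.from_frame(d.to_frame())
        np.testing.assert_array_equal(d.fractions, d2.fractions)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryData(np.array([1.0]), np.array([[1.2, 0.0, 0.0]]))
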