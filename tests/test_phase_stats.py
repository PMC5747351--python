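"""Phase extraction and the descriptive analyses over inferred profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulseswitch.phase_stats import (
    classify_cell,
    count_switches,
    pairwise_trace_correlation,
    population_rate_trajectory,
    posterior_predictive_mrna,
    profile_to_phases,
    rate_duration_regression,
    switch_pair_analysis,
)
from pulseswitch.types import (
    KineticParams,
    LuminescenceTrace,
    Phase,
    PosteriorEnsemble,
    PosteriorSample,
    SwitchProfile,
)

WINDOW = (0.0, 48.0)


def prof(times, rates):
    return SwitchProfile(tuple(times), tuple(rates), WINDOW)


@st.composite
def profiles(draw):
    k = draw(st.integers(0, 5))
    times = sorted(draw(st.lists(
        st.floats(0.5, 47.5), min_size=k, max_size=k, unique=True)))
    rates = [draw(st.floats(0.1, 100.0))]
    for _ in range(k):
        nxt = draw(st.floats(0.1, 100.0))
        while nxt == rates[-1]:
            nxt += 0.1
        rates.append(nxt)
    return prof(times, rates)


class TestPhases:
    def test_k0_single_phase_both_censored(self):
        phases = profile_to_phases(prof((), (5.0,)), "c")
        assert len(phases) == 1
        p = phases[0]
        assert p.left_censored and p.right_censored
        assert p.entering_direction == "start"
        assert p.duration == pytest.approx(48.0)

    def test_durations_and_directions(self):
        phases = profile_to_phases(prof((10.0, 20.0), (2.0, 10.0, 3.0)), "c")
        assert [p.duration for p in phases] == pytest.approx([10.0, 10.0, 28.0])
        assert [p.entering_direction for p in phases] == ["start", "up", "down"]

    def test_strictly_decreasing_rates_all_down(self):
        phases = profile_to_phases(prof((5.0, 15.0, 30.0),
                                        (40.0, 20.0, 8.0, 1.0)), "c")
        assert all(p.entering_direction == "down" for p in phases[1:])

    @given(profiles())
    @settings(max_examples=100, deadline=None)
    def test_phases_tile_window(self, profile):
        phases = profile_to_phases(profile, "c")
        assert sum(p.duration for p in phases) == pytest.approx(48.0)
        for a, b in zip(phases[:-1], phases[1:]):
            assert a.end == b.start


class TestCounting:
    def test_counts_per_profile(self):
        per_cell, summary = count_switches(
            {"BSA": [prof((5.0, 10.0, 20.0), (2.0, 10.0, 6.0, 3.0))]})
        row = per_cell.iloc[0]
        assert (row.up, row.down) == (1, 2)

    def test_uniform_cohort_sem_zero(self):
        profs = [prof((5.0, 10.0, 20.0), (2.0, 10.0, 6.0, 3.0))] * 6
        per_cell, summary = count_switches({"BSA": profs})
        assert summary.loc[0, "down_mean"] / summary.loc[0, "up_mean"] == 2.0
        assert summary.loc[0, "down_sem"] == 0.0

    @given(profiles())
    @settings(max_examples=100, deadline=None)
    def test_up_plus_down_equals_k(self, profile):
        per_cell, _ = count_switches({"x": [profile]})
        assert per_cell.up[0] + per_cell.down[0] == profile.n_switches

    def test_generative_asymmetry_recovered(self):
        from pulseswitch.simulate import CohortConfig, make_cohort

        cohort = make_cohort(CohortConfig(n_cells=30, n_down_range=(2, 2),
                                          sigma=5.0), seed=3)
        per_cell, summary = count_switches({"BSA": cohort.profiles})
        assert summary.loc[0, "up_mean"] == pytest.approx(1.0, abs=1e-9)
        assert summary.loc[0, "down_mean"] == pytest.approx(
            2.0, abs=3 * max(summary.loc[0, "down_sem"], 0.1))


class TestRateDuration:
    def test_exact_inverse_relation(self):
        phases = []
        for i, rate in enumerate((1.0, 2.0, 5.0, 10.0, 20.0)):
            dur = np.exp(3.0) / rate  # ln tau = 3 - ln beta
            start = float(i * 5)
            phases.append(Phase("c", start, start + dur, rate, "up",
                                False, False))
        fit = rate_duration_regression(phases)
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)

    def test_independent_durations_give_near_zero_r(self):
        rng = np.random.default_rng(4)
        phases = [Phase("c", 0.0, float(d), float(r), "up", False, False)
                  for d, r in zip(rng.lognormal(1.0, 0.5, 1000),
                                  rng.lognormal(2.0, 0.8, 1000))]
        fit = rate_duration_regression(phases)
        assert abs(fit.pearson_r) < 0.1

    def test_censored_phases_excluded(self):
        phases = [Phase("c", 0.0, 5.0, 2.0, "start", True, False),
                  Phase("c", 5.0, 10.0, 4.0, "up", False, False),
                  Phase("c", 10.0, 20.0, 8.0, "down", False, False),
                  Phase("c", 20.0, 48.0, 1.0, "down", False, True)]
        with pytest.raises(ValueError):
            rate_duration_regression(phases)  # only 2 usable

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            rate_duration_regression([Phase("c", 0.0, 5.0, 2.0, "up",
                                            False, False)])


class TestSwitchPairs:
    def test_single_pair_labelled(self):
        pairs, corr = switch_pair_analysis([prof((10.0, 20.0),
                                                 (1.0, 9.0, 4.0))])
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row.scenario == "Up-Down"
        assert row.prev_amplitude == pytest.approx(8.0)
        assert row.curr_amplitude == pytest.approx(-5.0)

    def test_small_scenarios_undefined_not_zero(self):
        pairs, corr = switch_pair_analysis([prof((10.0, 20.0),
                                                 (1.0, 9.0, 4.0))])
        updown = corr[corr.scenario == "Up-Down"].iloc[0]
        assert np.isnan(updown.r)
        assert updown.n_pairs == 1

    def test_all_up_profile_gives_only_upup(self):
        pairs, _ = switch_pair_analysis([prof((10.0, 20.0, 30.0),
                                              (1.0, 2.0, 4.0, 8.0))])
        assert set(pairs.scenario) == {"Up-Up"}

    def test_correlated_generator_recovered(self):
        rng = np.random.default_rng(8)
        profs = []
        for _ in range(500):
            up = rng.uniform(5.0, 40.0)
            prev = up  # up amplitude
            curr = 0.6 * prev + rng.normal(0, 0.5)
            curr = max(curr, 0.5)
            base = 50.0
            profs.append(prof((10.0, 20.0),
                              (base, base + prev, base + prev - curr)))
        pairs, corr = switch_pair_analysis(profs)
        r = corr.set_index("scenario").loc["Up-Down", "r"]
        assert r > 0.9

    @given(profiles())
    @settings(max_examples=100, deadline=None)
    def test_scenarios_partition_pairs(self, profile):
        pairs, _ = switch_pair_analysis([profile])
        assert len(pairs) == max(profile.n_switches - 1, 0)


class TestClassification:
    @pytest.mark.parametrize("rates,expected", [
        ((1.0, 10.0, 1.5), "binary"),
        ((1.0, 10.0, 6.0, 3.0), "graded-decrease"),
        ((1.0, 4.0, 9.0), "graded-increase"),
        ((5.0,), "binary"),
        ((1.0, 10.0), "binary"),
        ((1.0, 4.0, 9.0, 3.0, 1.0), "graded-decrease"),
    ])
    def test_rule(self, rates, expected):
        times = tuple(5.0 * (i + 1) for i in range(len(rates) - 1))
        assert classify_cell(prof(times, rates)) == expected

    @given(profiles())
    @settings(max_examples=50, deadline=None)
    def test_deterministic(self, profile):
        assert classify_cell(profile) == classify_cell(profile)


class TestPosteriorPredictive:
    @staticmethod
    def degenerate_ensemble(beta=6.0, delta_m=1.0, n=300):
        params = KineticParams(delta_m, 0.35, 5.0, sigma=1.0)
        p = prof((), (beta,))
        samples = [PosteriorSample(p, params, i, 0.0) for i in range(n)]
        return PosteriorEnsemble("c", samples, n, 0)

    def test_degenerate_posterior_is_poisson(self):
        ens = self.degenerate_ensemble()
        out = posterior_predictive_mrna(ens, t_query=24.0, n_draws=5000, seed=0)
        counts = out["counts"]
        kmax = counts.max() + 1
        emp = np.bincount(counts, minlength=kmax) / len(counts)
        theo = stats.poisson(6.0).pmf(np.arange(kmax))
        tv = 0.5 * np.abs(emp - theo).sum() + 0.5 * (1 - theo.sum())
        assert tv < 0.05
        assert out["mean"] == pytest.approx(6.0, rel=0.05)

    def test_two_seeds_agree(self):
        ens = self.degenerate_ensemble()
        a = posterior_predictive_mrna(ens, 24.0, n_draws=200, seed=1)
        b = posterior_predictive_mrna(ens, 24.0, n_draws=200, seed=2)
        assert stats.ks_2samp(a["counts"], b["counts"]).pvalue > 0.01

    def test_t_query_outside_window_rejected(self):
        ens = self.degenerate_ensemble()
        with pytest.raises(ValueError):
            posterior_predictive_mrna(ens, 100.0, seed=0)

    def test_matches_generator_truth(self):
        # ground-truth mRNA from the SSA vs the posterior-predictive law
        from pulseswitch.simulate import ssa_simulate

        params = KineticParams(1.0, 0.35, 5.0, sigma=1.0)
        p = prof((), (6.0,))
        truth_counts = []
        for s in range(200):
            path = ssa_simulate(p, params, t_end=4.0, seed=s)
            truth_counts.append(path.at(np.array([4.0]))[0][0])
        ens = self.degenerate_ensemble()
        out = posterior_predictive_mrna(ens, 4.0, n_draws=2000, seed=3)
        sem = np.std(truth_counts) / np.sqrt(len(truth_counts))
        assert out["mean"] == pytest.approx(np.mean(truth_counts),
                                            abs=4 * sem)


class TestTraceCorrelation:
    @staticmethod
    def traces_from(values_list, dt=0.25):
        n = len(values_list[0])
        t = np.arange(n) * dt
        return [LuminescenceTrace(f"c{i}", t, np.asarray(v, dtype=float))
                for i, v in enumerate(values_list)]

    def test_identical_traces_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(50, 5, 96)
        coeffs, summary = pairwise_trace_correlation(
            self.traces_from([v, v.copy(), v.copy()]), horizon_h=20.0)
        assert np.allclose(coeffs.r, 1.0)

    def test_antiphase_sinusoids_r_minus_one(self):
        t = np.arange(96) * 0.25
        a = np.sin(2 * np.pi * t / 4.0)
        coeffs, _ = pairwise_trace_correlation(self.traces_from([a, -a]),
                                               horizon_h=20.0)
        assert np.allclose(coeffs.r, -1.0)

    def test_independent_noise_median_near_zero(self):
        rng = np.random.default_rng(1)
        traces = self.traces_from(rng.normal(0, 1, size=(50, 96)))
        coeffs, summary = pairwise_trace_correlation(traces, horizon_h=20.0)
        assert np.abs(summary.median_r).max() < 0.1

    def test_zero_variance_pairs_skipped(self):
        rng = np.random.default_rng(2)
        flat = np.zeros(96)
        noisy = rng.normal(0, 1, 96)
        coeffs, summary = pairwise_trace_correlation(
            self.traces_from([flat, noisy, rng.normal(0, 1, 96)]),
            horizon_h=4.0)
        assert (summary.n_skipped == 2).all()

    def test_mismatched_grids_rejected(self):
        t1 = LuminescenceTrace("a", np.arange(10.0), np.ones(10))
        t2 = LuminescenceTrace("b", np.arange(12.0), np.ones(12))
        with pytest.raises(ValueError, match="common sampling grid"):
            pairwise_trace_correlation([t1, t2])


class TestPopulationRate:
    def test_constant_cohort_flat(self):
        out = population_rate_trajectory([prof((), (5.0,))] * 4)
        assert np.allclose(out.mean_rate, 5.0)

    def test_two_level_mean(self):
        out = population_rate_trajectory([prof((), (2.0,)), prof((), (8.0,))])
        assert np.allclose(out.mean_rate, 5.0)

    def test_stationary_generator_trend_slope_zero(self):
        # exchangeable levels around a uniform switch time: E[beta(t)] is
        # constant, so the fitted linear trend must be negligible
        rng = np.random.default_rng(5)
        profs = []
        for _ in range(200):
            s = rng.uniform(1.0, 47.0)
            r1, r2 = rng.lognormal(np.log(10.0), 0.5, size=2)
            while r1 == r2:
                r2 *= 1.0001
            profs.append(prof((s,), (r1, r2)))
        out = population_rate_trajectory(profs)
        res = stats.linregress(out.time_h, out.mean_rate)
        # total drift over the window is small relative to the mean level
        assert abs(res.slope) * 48.0 < 0.15 * out.mean_rate.mean()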