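"""Group-level statistics: effects, screening, bootstrap, ANOVA, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from itclab.analysis import (
    bootstrap_correlation_test,
    bootstrap_mean_test,
    effect_measures,
    mad_filter,
    mixed_anova,
    p_immediate_ratio,
    performance_slope,
    quintile_bin_association,
    quintile_bins,
    windowed_accuracy,
)
from itclab.model import DiscountParams, FitResult
from tests.conftest import random_offer_fixture


def fake_fit(k, unique=True):
    p = DiscountParams(k=k, mu=1e-3)
    return FitResult(params=p, log_likelihood=-100.0, n_starts=1,
                     converged=True, unique=unique, start_optima=((p, -100.0),))


class TestPImmediateRatio:
    def test_fractions(self):
        rng = np.random.default_rng(0)
        trials = random_offer_fixture(20, rng)
        expected = sum(t.choice == "immediate" for t in trials) / 20
        assert p_immediate_ratio(trials) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            p_immediate_ratio([])


class TestEffectMeasures:
    def test_identity_gives_zero(self):
        rng = np.random.default_rng(1)
        trials = random_offer_fixture(10, rng)
        m = effect_measures(fake_fit(0.01), fake_fit(0.01), trials, trials)
        assert m.delta_log_k == 0.0
        assert m.delta_p_immediate == 0.0

    def test_one_decade_reduction(self):
        rng = np.random.default_rng(2)
        trials = random_offer_fixture(10, rng)
        m = effect_measures(fake_fit(0.01), fake_fit(0.001), trials, trials)
        assert m.delta_log_k == pytest.approx(1.0)

    def test_nonunique_fit_rejected(self):
        rng = np.random.default_rng(3)
        trials = random_offer_fixture(10, rng)
        with pytest.raises(ValueError):
            effect_measures(fake_fit(0.01, unique=False), fake_fit(0.01),
                            trials, trials)


class TestMadFilter:
    def test_flags_gross_outlier(self):
        mask = mad_filter([-2.0, -2.1, -1.9, -2.05, 1.0])
        assert mask.tolist() == [True, True, True, True, False]

    def test_identical_values_keep_everything(self):
        assert mad_filter([1.0, 1.0, 1.0]).all()

    def test_values_within_one_mad_kept(self):
        assert mad_filter([0.0, 0.5, -0.5, 0.2, -0.2]).all()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            mad_filter([1.0, 2.0])


class TestBootstrapMeanTest:
    def test_identical_paired_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bootstrap_mean_test(x, x, paired=True, B=500, seed=0)
        assert res.statistic_observed == 0.0
        assert res.p_value > 0.9

    def test_seeded_determinism_bit_for_bit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        a = bootstrap_mean_test(x, B=2000, seed=7)
        b = bootstrap_mean_test(x, B=2000, seed=7)
        assert a.p_value == b.p_value
        assert a.statistic_observed == b.statistic_observed

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        res = bootstrap_mean_test(x, y, paired=False, B=2000, seed=1)
        assert res.p_value < 0.01
        assert res.cohens_d > 1.0

    def test_observed_t_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=15), rng.normal(size=15)
        res_p = bootstrap_mean_test(x, y, paired=True, B=100, seed=0)
        assert res_p.statistic_observed == pytest.approx(
            stats.ttest_rel(x, y).statistic)
        res_2 = bootstrap_mean_test(x, rng.normal(size=20), paired=False,
                                    B=100, seed=0)

    def test_p_value_floor(self):
        x = np.linspace(10, 11, 12)
        res = bootstrap_mean_test(x, B=999, seed=2)
        assert res.p_value >= 1 / 1000

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            bootstrap_mean_test([1.0, 2.0], [1.0], paired=True)


class TestBootstrapCorrelationTest:
    def test_perfect_correlation_minimal_p(self):
        a = np.arange(20.0)
        res = bootstrap_correlation_test(a, a, B=1000, seed=0)
        assert res.statistic_observed == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_anticorrelation(self):
        a = np.arange(20.0)
        res = bootstrap_correlation_test(a, -a, B=1000, seed=0)
        assert res.statistic_observed == pytest.approx(-1.0)
        assert res.p_value < 0.01

    def test_independent_pairs_not_rejected(self):
        rng = np.random.default_rng(8)
        res = bootstrap_correlation_test(rng.normal(size=40),
                                         rng.normal(size=40), B=2000, seed=3)
        assert res.p_value > 0.05

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bootstrap_correlation_test([1, 2, 3, 4], [1, 2, 3])


def make_long(values_by_subject, groups):
    rows = []
    for (subj, (pre, post)), grp in zip(values_by_subject.items(), groups):
        rows.append({"participant_id": subj, "group": grp, "phase": "pre",
                     "log10_k": pre})
        rows.append({"participant_id": subj, "group": grp, "phase": "post",
                     "log10_k": post})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_hand_worked_2x2_fixture(self):
        # group A: subjects (1,3), (3,5); group B: (4,6), (6,4)
        # hand decomposition: grand = 4; SS_type = 8, SS_err_between = 4,
        # SS_time = 2, SS_interaction = 2, SS_err_within = 4
        # => F_type = 4, F_time = 1, F_interaction = 1
        data = make_long({"s1": (1, 3), "s2": (3, 5),
                          "s3": (4, 6), "s4": (6, 4)},
                         ["A", "A", "B", "B"])
        table = mixed_anova(data).set_index("source")
        assert table.loc["type", "SS"] == pytest.approx(8.0)
        assert table.loc["time", "SS"] == pytest.approx(2.0)
        assert table.loc["time*type", "SS"] == pytest.approx(2.0)
        assert table.loc["error(between)", "SS"] == pytest.approx(4.0)
        assert table.loc["error(within)", "SS"] == pytest.approx(4.0)
        assert table.loc["type", "F"] == pytest.approx(4.0)
        assert table.loc["time", "F"] == pytest.approx(1.0)
        assert table.loc["time*type", "F"] == pytest.approx(1.0)
        assert table.loc["type", "df"] == 1
        assert table.loc["error(within)", "df"] == 2

    def test_ss_decomposition_balances(self):
        rng = np.random.default_rng(10)
        data = make_long(
            {f"s{i}": tuple(rng.normal(size=2)) for i in range(24)},
            ["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        table = mixed_anova(data).set_index("source")
        y = data["log10_k"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(ss_total, rel=1e-10)

    def test_matches_pingouin_on_balanced_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        data = make_long(
            {f"s{i}": tuple(rng.normal(i % 3, 1.0, size=2)) for i in range(30)},
            ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        ours = mixed_anova(data).set_index("source")
        theirs = pingouin.mixed_anova(data, dv="log10_k", within="phase",
                                      between="group",
                                      subject="participant_id").set_index("Source")
        assert ours.loc["type", "F"] == pytest.approx(theirs.loc["group", "F"])
        assert ours.loc["time", "F"] == pytest.approx(theirs.loc["phase", "F"])
        assert ours.loc["time*type", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"])

    def test_pure_time_shift_loads_on_time_factor(self):
        rng = np.random.default_rng(12)
        base = {f"s{i}": rng.normal() for i in range(18)}
        data = make_long({s: (v, v + 1.0 + 0.05 * rng.normal())
                          for s, v in base.items()},
                         ["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        table = mixed_anova(data).set_index("source")
        assert table.loc["time", "p"] < 1e-6
        assert table.loc["time*type", "p"] > 0.01

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            data = make_long(
                {f"s{i}": tuple(rng.normal(size=2)) for i in range(15)},
                ["A"] * 5 + ["B"] * 5 + ["C"] * 5)
            t = mixed_anova(data).set_index("source")
            pvals.append(t.loc["time*type", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_phase_raises(self):
        data = make_long({"s1": (1, 2), "s2": (2, 3), "s3": (1, 1)},
                         ["A", "A", "B"])
        data = data.drop(data.index[-1])
        with pytest.raises(ValueError):
            mixed_anova(data)


class TestWindows:
    def test_twenty_trials_give_three_windows(self):
        assert windowed_accuracy(np.ones(20)).n_windows == 3

    def test_all_correct_windows_are_one(self):
        s = windowed_accuracy(np.ones(35))
        assert np.all(s.values == 1.0)

    def test_alternating_trace_gives_half(self):
        s = windowed_accuracy(np.tile([0, 1], 15))
        assert np.all(s.values == 0.5)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            windowed_accuracy(np.ones(9))

    @given(n=st.integers(10, 1000))
    @settings(max_examples=80, deadline=None)
    def test_window_count_formula(self, n):
        s = windowed_accuracy(np.zeros(n))
        assert s.n_windows == (n - 10) // 5 + 1


class TestPerformanceSlope:
    def test_constant_series_zero_slope(self):
        assert performance_slope(windowed_accuracy(np.ones(40))) == pytest.approx(0.0)

    def test_exact_line(self):
        from itclab.analysis import AccuracyWindowSeries
        s = AccuracyWindowSeries(values=np.array([0.5, 0.6, 0.7]))
        assert performance_slope(s) == pytest.approx(0.1)

    def test_single_window_raises(self):
        from itclab.analysis import AccuracyWindowSeries
        with pytest.raises(ValueError):
            performance_slope(AccuracyWindowSeries(values=np.array([0.5])))


class TestQuintileBins:
    def test_length_240(self):
        assert quintile_bins(240) == [(0, 80), (40, 120), (80, 160),
                                      (120, 200), (160, 240)]

    def test_final_bin_right_anchored_when_not_divisible(self):
        bins = quintile_bins(250)
        assert bins[-1] == (250 - 83, 250)
        assert len(bins) == 5

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            quintile_bins(2)

    def test_null_association_near_zero(self):
        rng = np.random.default_rng(14)
        traces = rng.integers(0, 2, size=(40, 240))
        effects = rng.normal(size=40)
        table = quintile_bin_association(traces, effects)
        assert len(table) == 5
        assert (table["r"].abs() < 0.45).all()

    def test_late_bin_effect_raises_late_correlations(self):
        # effects proportional to late-bin accuracy: r must rise across bins
        rng = np.random.default_rng(15)
        p_late = rng.uniform(0.3, 0.9, size=60)
        traces = np.empty((60, 240))
        for i, p in enumerate(p_late):
            probs = np.linspace(0.6, p, 240)
            traces[i] = rng.random(240) < probs
        effects = traces[:, 160:].mean(axis=1) + 0.02 * rng.normal(size=60)
        table = quintile_bin_association(traces, effects)
        assert table["r"].iloc[4] > table["r"].iloc[0]
        assert table["r"].iloc[4] > 0.6
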