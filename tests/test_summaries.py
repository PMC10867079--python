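"""Summaries: exclusions, quantiles, delta plots, CAFs, group averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdmc.simulator import TrialTable, simulate_dataset
from rdmc.summaries import (
    CAF,
    ConditionSummary,
    apply_exclusions,
    caf,
    caf_from_table,
    condition_summary,
    delta_plot,
    delta_plot_from_table,
    delta_sign,
    delta_slope,
    group_quantile_average,
    rt_quantiles,
)


def trials_from_rts(rts, accuracy=None, congruency="congruent"):
    n = len(rts)
    return pd.DataFrame({
        "congruency": congruency,
        "rt_ms": np.asarray(rts, float),
        "accuracy": np.ones(n, int) if accuracy is None else accuracy,
        "censored": False,
    })


def summary(quantiles, accuracy=1.0, n=100):
    q = tuple(float(x) for x in quantiles)
    return ConditionSummary(probs=(0.1, 0.3, 0.5, 0.7, 0.9), quantiles=q,
                            accuracy=accuracy, n_total=n,
                            n_correct=int(round(accuracy * n)))


def brute_force_quantile(xs, p):
    """Independent linear-interpolation order-statistic quantile."""
    xs = sorted(xs)
    h = (len(xs) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestExclusions:
    def test_hand_thresholds(self):
        tab = TrialTable(trials_from_rts([150.0, 250.0, 1300.0]))
        out = apply_exclusions(tab)
        assert out.data["rt_ms"].tolist() == [250.0]
        assert out.meta["exclusions"]["n_dropped"] == 2

    def test_inclusive_bounds(self):
        tab = TrialTable(trials_from_rts([200.0, 1200.0, 199.9, 1200.1]))
        out = apply_exclusions(tab)
        assert sorted(out.data["rt_ms"]) == [200.0, 1200.0]

    def test_identity_when_all_inside(self):
        tab = TrialTable(trials_from_rts([300.0, 400.0, 500.0]))
        out = apply_exclusions(tab)
        assert out.data["rt_ms"].tolist() == [300.0, 400.0, 500.0]

    def test_empty_result_flagged(self):
        tab = TrialTable(trials_from_rts([50.0, 1500.0]))
        with pytest.raises(ValueError, match="excluded"):
            apply_exclusions(tab)


class TestQuantiles:
    def test_hand_interpolation(self):
        rts = np.arange(100, 1001, 100)  # 100..1000
        assert rt_quantiles(rts, [0.5])[0] == pytest.approx(550.0)

    def test_constant_sample(self):
        q = rt_quantiles(np.full(20, 432.0))
        assert np.all(q == 432.0)

    @given(st.lists(st.floats(100, 1000), min_size=2, max_size=40),
           st.sampled_from([0.1, 0.3, 0.5, 0.7, 0.9]))
    @settings(derandomize=True, max_examples=150)
    def test_against_brute_force_oracle(self, xs, p):
        assert rt_quantiles(xs, [p])[0] == pytest.approx(
            brute_force_quantile(xs, p), rel=1e-12, abs=1e-9)

    def test_two_point_sample(self):
        # p=.1 on 2 points interpolates 10% of the way up
        assert rt_quantiles([100.0, 200.0], [0.1])[0] == pytest.approx(
            brute_force_quantile([100.0, 200.0], 0.1))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            rt_quantiles([500.0])

    def test_nondecreasing(self, rng):
        q = rt_quantiles(rng.uniform(200, 800, 101))
        assert np.all(np.diff(q) >= 0)


class TestDeltaPlot:
    def test_identical_summaries_zero_delta(self):
        s = summary([300, 350, 400, 450, 500])
        dp = delta_plot(s, s)
        assert all(d == 0.0 for d in dp.delta)

    def test_shift_invariance(self):
        c = summary([300, 350, 400, 450, 500])
        i = summary([330, 380, 430, 480, 530])
        dp = delta_plot(c, i)
        assert all(d == pytest.approx(30.0) for d in dp.delta)

    def test_hand_subtraction_and_x(self):
        c = summary([300, 350, 400, 450, 500])
        i = summary([330, 370, 410, 450, 490])
        dp = delta_plot(c, i)
        assert list(dp.delta) == pytest.approx([30, 20, 10, 0, -10])
        assert list(dp.x) == pytest.approx([315, 360, 405, 450, 495])

    def test_constant_rt_shift_moves_x_not_delta(self):
        c = summary([300, 350, 400, 450, 500])
        i = summary([330, 370, 410, 450, 490])
        c2 = summary([x + 100 for x in c.quantiles])
        i2 = summary([x + 100 for x in i.quantiles])
        dp, dp2 = delta_plot(c, i), delta_plot(c2, i2)
        assert list(dp2.delta) == pytest.approx(list(dp.delta))
        assert list(dp2.x) == pytest.approx([x + 100 for x in dp.x])

    def test_level_mismatch_rejected(self):
        c = summary([300, 350, 400, 450, 500])
        i = ConditionSummary(probs=(0.25, 0.5, 0.75),
                             quantiles=(330.0, 410.0, 480.0),
                             accuracy=1.0, n_total=10, n_correct=10)
        with pytest.raises(ValueError):
            delta_plot(c, i)

    def test_slope_hand_ols(self):
        c = summary([300, 350, 400, 450, 500])
        i = summary([330, 370, 410, 450, 490])
        dp = delta_plot(c, i)
        assert delta_slope(dp) == pytest.approx(-0.2222, abs=1e-4)
        assert delta_sign(dp) == -1

    def test_slope_degenerate_cases(self):
        flat = summary([300, 350, 400, 450, 500])
        assert delta_slope(delta_plot(flat, flat)) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="degenerate"):
            same_x = ConditionSummary(probs=(0.1, 0.9),
                                      quantiles=(400.0, 400.0),
                                      accuracy=1.0, n_total=10, n_correct=10)
            delta_slope(delta_plot(same_x, same_x))

    def test_quantile_and_bin_mean_modes_agree_in_sign(self, table3_row1):
        from rdmc.presets import RDMC_PRESETS
        for i, name in enumerate(("table3-row1", "table3-row2", "table3-row3")):
            tab = simulate_dataset(RDMC_PRESETS[name], 4000, seed=50 + i)
            sq = delta_slope(delta_plot_from_table(tab, mode="quantile"))
            sb = delta_slope(delta_plot_from_table(tab, mode="bin-mean"))
            assert np.sign(sq) == np.sign(sb), name


class TestCAF:
    def test_all_correct(self):
        acc, counts = caf(trials_from_rts(np.arange(10) + 300.0))
        assert np.all(acc == 1.0)
        assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_hand_binning_errors_at_fastest(self):
        rts = np.arange(10) + 300.0
        accuracy = np.ones(10, int)
        accuracy[:2] = 0  # the two fastest trials are errors
        acc, _ = caf(trials_from_rts(rts, accuracy))
        assert acc.tolist() == [0.0, 1.0, 1.0, 1.0, 1.0]

    def test_alternating_accuracy_near_half(self):
        rts = np.arange(100) + 300.0
        accuracy = np.tile([1, 0], 50)
        acc, _ = caf(trials_from_rts(rts, accuracy))
        assert np.allclose(acc, 0.5)

    def test_remainders_to_fastest_bins(self):
        acc, counts = caf(trials_from_rts(np.arange(12) + 300.0))
        assert counts.tolist() == [3, 3, 2, 2, 2]

    def test_partition_recomposes_accuracy(self, small_table):
        c = caf_from_table(small_table)
        for cond in ("congruent", "incongruent"):
            df = small_table.condition(cond)
            w = np.asarray(c.bin_counts[cond], float)
            assert w.sum() == len(df)
            recomposed = np.dot(c.accuracy[cond], w) / w.sum()
            assert recomposed == pytest.approx(df["accuracy"].mean())

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            caf(trials_from_rts([300.0, 400.0]))


class TestGroupAverage:
    def test_identical_subjects_unchanged(self):
        s = summary([300, 350, 400, 450, 500], accuracy=0.95)
        g = group_quantile_average([s, s])
        assert list(g.quantiles) == pytest.approx(list(s.quantiles))
        assert g.accuracy == pytest.approx(0.95)

    def test_midpoint_of_two_subjects(self):
        a = summary([300, 350, 400, 450, 500])
        b = summary([400, 450, 500, 550, 600])
        g = group_quantile_average([a, b])
        assert list(g.quantiles) == pytest.approx([350, 400, 450, 500, 550])

    def test_three_subject_hand_average(self):
        subs = [summary([300, 330, 360, 390, 420], accuracy=0.9),
                summary([330, 360, 390, 420, 450], accuracy=0.96),
                summary([360, 390, 420, 450, 480], accuracy=0.99)]
        g = group_quantile_average(subs)
        assert list(g.quantiles) == pytest.approx([330, 360, 390, 420, 450])
        assert g.accuracy == pytest.approx(0.95)

    def test_mismatched_levels_rejected(self):
        a = summary([300, 350, 400, 450, 500])
        b = ConditionSummary(probs=(0.25, 0.5, 0.75),
                             quantiles=(330.0, 410.0, 480.0),
                             accuracy=1.0, n_total=10, n_correct=10)
        with pytest.raises(ValueError):
            group_quantile_average([a, b])
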