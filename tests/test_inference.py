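import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mopane.inference import (
    SeparationError,
    bh_adjust,
    chisq_contingency,
    linear_fit,
    logistic_curve_fit,
    logistic_glm_fit,
    paired_t,
    tukey_hsd,
    two_way_anova,
    welch_t,
)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 2

    def test_constant_shift_has_undefined_t(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])

    def test_matches_hand_formula(self, rng):
        x = rng.normal(5.0, 2.0, size=9)
        y = x + rng.normal(0.5, 1.0, size=9)
        res = paired_t(x, y)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), len(d) - 1)
        assert res.p_value == pytest.approx(p_hand, abs=1e-10)

    def test_transform_recorded(self):
        res = paired_t([10.0, 100.0, 1000.0], [20.0, 90.0, 1100.0], transform="log10")
        assert res.transform == "log10"


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_textbook_toy(self):
        res = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-math.sqrt(1.5), abs=1e-10)  # -1.2247
        assert res.df == pytest.approx(4.0, abs=1e-10)

    def test_hand_formula_on_random_toy(self, rng):
        x = rng.normal(0, 1, size=7)
        y = rng.normal(1, 3, size=5)
        res = welch_t(x, y)
        vx, vy = x.var(ddof=1) / 7, y.var(ddof=1) / 5
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 6 + vy**2 / 4)
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.df == pytest.approx(df_hand, abs=1e-10)
        assert res.df <= 10  # Welch df never exceeds pooled df

    def test_both_groups_constant_and_unequal(self):
        with pytest.raises(ValueError, match="constant"):
            welch_t([2.0, 2.0, 2.0], [3.0, 3.0])


class TestChiSquare:
    def test_uniform_table_is_zero(self):
        res = chisq_contingency([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.df == 1

    def test_diagonal_table_hand_value(self):
        res = chisq_contingency([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0, abs=1e-10)
        assert res.df == 1

    def test_hand_formula_on_random_table(self, rng):
        table = rng.integers(1, 50, size=(3, 4)).astype(float)
        res = chisq_contingency(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        exp = row @ col / table.sum()
        chi2_hand = ((table - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2_hand, abs=1e-10)
        assert res.df == 6

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chisq_contingency([[0, 0], [1, 2]])


def _balanced_2x2(cell_means, reps=2):
    rows = []
    offsets = np.linspace(-0.5, 0.5, reps)
    for (a, b), mu in cell_means.items():
        for r in range(reps):
            rows.append((mu + offsets[r], a, b))
    y, A, B = zip(*rows)
    return np.array(y), list(A), list(B)


class TestTwoWayAnova:
    def test_balanced_design_projection_oracle(self):
        """Type II SS on a balanced 2x2 equals the explicit projection sums."""
        means = {("a1", "b1"): 1.0, ("a1", "b2"): 2.0, ("a2", "b1"): 4.0, ("a2", "b2"): 7.0}
        y, A, B = _balanced_2x2(means, reps=2)
        table = two_way_anova(y, A, B).set_index("term")
        y = np.asarray(y)
        A = np.asarray(A)
        B = np.asarray(B)
        grand = y.mean()
        ss_a = sum(
            (y[A == a].mean() - grand) ** 2 * (A == a).sum() for a in np.unique(A)
        )
        ss_b = sum(
            (y[B == b].mean() - grand) ** 2 * (B == b).sum() for b in np.unique(B)
        )
        cell_mean = {
            (a, b): y[(A == a) & (B == b)].mean()
            for a in np.unique(A)
            for b in np.unique(B)
        }
        ss_int = sum(
            2 * (cell_mean[(a, b)] - y[A == a].mean() - y[B == b].mean() + grand) ** 2
            for a in np.unique(A)
            for b in np.unique(B)
        )
        assert table.loc["A", "sum_sq"] == pytest.approx(ss_a, abs=1e-10)
        assert table.loc["B", "sum_sq"] == pytest.approx(ss_b, abs=1e-10)
        assert table.loc["A:B", "sum_sq"] == pytest.approx(ss_int, abs=1e-10)

    def test_type_I_equals_type_II_when_balanced(self):
        means = {("a1", "b1"): 1.0, ("a1", "b2"): 3.0, ("a2", "b1"): 2.0, ("a2", "b2"): 8.0}
        y, A, B = _balanced_2x2(means, reps=3)
        t1 = two_way_anova(y, A, B, ss_type=1).set_index("term")["sum_sq"]
        t2 = two_way_anova(y, A, B, ss_type=2).set_index("term")["sum_sq"]
        for term in ("A", "B", "A:B"):
            assert t1[term] == pytest.approx(t2[term], abs=1e-10)

    def test_constant_response_rejected(self):
        y = [1.0] * 8
        A = ["a1", "a2"] * 4
        B = ["b1"] * 4 + ["b2"] * 4
        with pytest.raises(ValueError, match="constant"):
            two_way_anova(y, A, B)

    def test_no_interaction_option(self):
        y = [1.0, 2.0, 3.0, 4.5, 2.0, 1.0, 4.0, 3.5]
        A = ["x", "x", "y", "y"] * 2
        B = ["u", "v"] * 4
        table = two_way_anova(y, A, B, include_interaction=False)
        assert set(table["term"]) == {"A", "B", "residual"}


class TestTukey:
    def test_zero_difference_has_p_near_one(self):
        out = tukey_hsd([5.0, 5.0], mse=2.0, n_per_group=4)
        assert out["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_matches_statsmodels_on_raw_data(self, rng):
        """Summary-statistic route agrees with statsmodels' raw-data route."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        k, n = 3, 8
        data = rng.normal(0, 1, size=(k, n)) + np.array([[0.0], [1.0], [2.5]])
        y = data.ravel()
        g = np.repeat([f"g{i}" for i in range(k)], n)
        sm_res = pairwise_tukeyhsd(y, g)
        means = data.mean(axis=1)
        grand = y.mean()
        ss_within = ((data - means[:, None]) ** 2).sum()
        mse = ss_within / (k * (n - 1))
        ours = tukey_hsd(means, mse, n, labels=[f"g{i}" for i in range(k)])
        assert np.allclose(ours["p_adj"].to_numpy(), sm_res.pvalues, atol=1e-8)
        assert np.allclose(ours["mean_diff"].to_numpy(), sm_res.meandiffs, atol=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            tukey_hsd([1.0], mse=1.0, n_per_group=3)


def brute_force_bh(p):
    """Independent step-up implementation: p_(i) * m / i, cumulative min from
    the largest rank down, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(size=rng.integers(1, 20))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_idempotent_and_monotone(self, rng):
        p = rng.random(12)
        adj = bh_adjust(p)
        assert np.allclose(bh_adjust(adj), brute_force_bh(adj), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLogisticGLM:
    def test_symmetric_toy_has_zero_intercept(self):
        x = [-2.0, -1.0, -2.0, -1.0, 1.0, 2.0, 1.0, 2.0]
        y = [0, 0, 1, 1, 0, 1, 1, 0]
        fit = logistic_glm_fit(y, x)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_separated_data_raises(self):
        x = [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]
        y = [0, 0, 0, 1, 1, 1]
        with pytest.raises(SeparationError):
            logistic_glm_fit(y, x)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            logistic_glm_fit([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])

    def test_recovers_simulated_slope_within_2se(self):
        from mopane.synthetic_woodland import simulate_pollarding_dataset

        df = simulate_pollarding_dataset(500, seed=11)
        fit = logistic_glm_fit(df["pollarded"], df["diameter_m"], predictor_name="d")
        assert abs(fit.params["d"] - (-10.0834)) <= 2 * fit.se["d"]


class TestLogisticCurve:
    def test_exact_recovery_on_noise_free_points(self):
        x = np.linspace(-10, 10, 25)
        y = 2.5 / (1 + np.exp(-0.8 * (x - 1.2)))
        fit = logistic_curve_fit(x, y)
        assert fit.params["A"] == pytest.approx(2.5, rel=1e-6)
        assert fit.params["k"] == pytest.approx(0.8, rel=1e-6)
        assert fit.params["x0"] == pytest.approx(1.2, rel=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_exclusions_are_honoured_and_counted(self):
        x = np.linspace(0, 10, 20)
        y = 1.0 / (1 + np.exp(-1.0 * (x - 5.0)))
        y_out = y.copy()
        y_out[[18, 19]] = 0.0  # two corrupted points bottom-right
        fit = logistic_curve_fit(x, y_out, exclude=[18, 19])
        assert fit.params["A"] == pytest.approx(1.0, rel=1e-6)
        assert fit.n_used == 18
        assert fit.n_excluded == 2

    def test_flat_response_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            logistic_curve_fit([1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 2.0, 2.0, 2.0, 2.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="more than 3"):
            logistic_curve_fit([1.0, 2.0, 3.0], [0.1, 0.5, 0.9])


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_fit(x, 2 * x + 1)
        assert fit.params["slope"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_f_statistic_matches_hand_formula(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 0.5 * x + 0.25 + rng.normal(0, 0.1, 30)
        fit = linear_fit(x, y)
        # hand OLS
        xc = x - x.mean()
        slope = (xc * y).sum() / (xc**2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.params["slope"] == pytest.approx(slope, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(intercept, abs=1e-10)
        resid = y - intercept - slope * x
        ss_res = (resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        f_hand = (ss_tot - ss_res) / 1 / (ss_res / 28)
        assert fit.f_stat == pytest.approx(f_hand, rel=1e-10)
        assert fit.f_df == (1, 28)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
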