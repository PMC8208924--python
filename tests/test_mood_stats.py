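"""Mood statistics: means, deltas, IQR fence, regressions, correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchforage import (
    MoodDeltaRegression,
    MoodEffectSpec,
    bonferroni_adjust,
    delta_scores,
    fit_delta_regression,
    generate_mood_deltas,
    hierarchical_compare,
    iqr_outlier_filter,
    mean_mood,
    solve_predictor_correlation,
)


def ratings_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "time_point", "arousal", "valence"])


class TestMeanMood:
    def test_two_point_mean(self):
        df = ratings_frame([("P1", 1, 2, 3), ("P1", 2, 4, 1)])
        assert mean_mood(df, (1, 2)) == (3.0, 2.0)

    def test_single_time_point_is_identity(self):
        df = ratings_frame([("P1", 5, -2, 4)])
        assert mean_mood(df, (5,)) == (-2.0, 4.0)

    def test_missing_time_point_names_participant(self):
        df = ratings_frame([("P7", 1, 0, 0)])
        with pytest.raises(ValueError, match="P7.*time point 2"):
            mean_mood(df, (1, 2))


class TestDeltaScores:
    def test_post_minus_pre(self):
        rec = delta_scores((1, 1), (3, 0), ltd_pre=0.5, ltd_post=-0.5, participant_id="P1")
        assert (rec.delta_arousal, rec.delta_valence, rec.delta_ltd) == (2, -1, -1.0)

    def test_identical_pre_post_all_zero(self):
        rec = delta_scores((2, 2), (2, 2), 1.0, 1.0)
        assert rec.delta_arousal == rec.delta_valence == rec.delta_ltd == 0.0

    def test_undefined_ltd_raises(self):
        with pytest.raises(ValueError, match="undefined LTD"):
            delta_scores((0, 0), (0, 0), None, 1.0)


class TestIQRFence:
    def test_hand_computed_example(self):
        # sorted 1..9,100: Q1=3.25, Q3=7.75 (linear interpolation),
        # fences 3.25-2.2*4.5=-6.65 and 7.75+2.2*4.5=17.65
        vals = list(range(1, 10)) + [100]
        keep = iqr_outlier_filter(vals)
        assert keep.tolist() == [True] * 9 + [False]

    def test_constant_vector_keeps_everything(self):
        assert iqr_outlier_filter([5.0] * 6).all()

    def test_value_exactly_at_fence_is_kept(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + 2.2 * (q3 - q1)
        assert iqr_outlier_filter(vals + [fence]).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_filter([1.0, 2.0, 3.0])

    @settings(max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=5, max_size=40
        ),
        scale=st.floats(min_value=0.1, max_value=50),
        shift=st.floats(min_value=-100, max_value=100),
    )
    def test_mask_invariant_under_positive_affine_maps(self, data, scale, shift):
        from hypothesis import assume

        v = np.asarray(data)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        # points essentially on a fence can flip either way in floats
        for fence in (q1 - 2.2 * iqr, q3 + 2.2 * iqr):
            assume(np.all(np.abs(v - fence) > 1e-6 * (1 + np.abs(fence))))
        base = iqr_outlier_filter(data)
        mapped = iqr_outlier_filter([scale * x + shift for x in data])
        assert base.tolist() == mapped.tolist()


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, expected", [(0.0017, 0.0051), (0.5, 1.0), (0.0, 0.0)]
    )
    def test_times_three_capped(self, p, expected):
        assert bonferroni_adjust([p])[0] == pytest.approx(expected)

    def test_empty_list(self):
        assert bonferroni_adjust([]) == []

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


def planted_frame(n, ba, bv, rho, r2, seed):
    spec = MoodEffectSpec(ba, bv, rho, r2, n)
    deltas, _ = generate_mood_deltas(spec, seed=seed)
    return deltas


class TestDeltaRegression:
    def test_noiseless_orthogonal_recovery_is_exact(self, rng):
        n = 200
        xa = rng.standard_normal(n)
        xv = rng.standard_normal(n)
        xa, xv = (xa - xa.mean()) / xa.std(ddof=1), (xv - xv.mean()) / xv.std(ddof=1)
        xv -= xa * (xa @ xv) / (xa @ xa)  # orthogonalize
        xv /= xv.std(ddof=1)
        y = 0.5 * xa - 0.5 * xv
        df = pd.DataFrame({"delta_arousal": xa, "delta_valence": xv, "delta_ltd": y})
        res = fit_delta_regression(df)
        # betas are standardized: undo the outcome scaling for raw recovery
        sy = y.std(ddof=1)
        assert res.beta["delta_arousal"] * sy == pytest.approx(0.5, abs=1e-10)
        assert res.beta["delta_valence"] * sy == pytest.approx(-0.5, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_standardized_betas_equal_correlation_solution(self):
        df = planted_frame(113, 0.24, -0.33, solve_predictor_correlation(0.24, -0.33, 0.09), 0.09, 11)
        res = fit_delta_regression(df)
        X = df[["delta_arousal", "delta_valence"]].to_numpy()
        y = df["delta_ltd"].to_numpy()
        R = np.corrcoef(X.T)
        r = np.array([np.corrcoef(X[:, 0], y)[0, 1], np.corrcoef(X[:, 1], y)[0, 1]])
        beta = np.linalg.solve(R, r)
        assert res.beta["delta_arousal"] == pytest.approx(beta[0], abs=1e-10)
        assert res.beta["delta_valence"] == pytest.approx(beta[1], abs=1e-10)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame(
            {"delta_arousal": [1.0] * 10, "delta_valence": np.arange(10.0), "delta_ltd": np.arange(10.0)}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            fit_delta_regression(df)

    def test_monte_carlo_recovery_is_unbiased(self):
        rho = solve_predictor_correlation(0.24, -0.33, 0.09)
        betas = []
        for i in range(60):
            df = planted_frame(113, 0.24, -0.33, rho, 0.09, 1000 + i)
            res = fit_delta_regression(df)
            betas.append((res.beta["delta_arousal"], res.beta["delta_valence"]))
        mean = np.mean(betas, axis=0)
        assert mean[0] == pytest.approx(0.24, abs=0.05)
        assert mean[1] == pytest.approx(-0.33, abs=0.05)


class TestHierarchicalCompare:
    def test_f_statistic_matches_residual_sums(self):
        df = planted_frame(150, 0.24, -0.33, solve_predictor_correlation(0.24, -0.33, 0.09), 0.09, 21)
        chosen, comp = hierarchical_compare(df)
        # recompute the nested F from scratch
        import statsmodels.api as sm

        def z(v):
            v = np.asarray(v, float)
            return (v - v.mean()) / v.std(ddof=1)

        xa, xv, y = z(df["delta_arousal"]), z(df["delta_valence"]), z(df["delta_ltd"])
        Xb = sm.add_constant(np.column_stack([xa, xv]))
        Xf = sm.add_constant(np.column_stack([xa, xv, z(xa * xv)]))
        rss_b = sm.OLS(y, Xb).fit().ssr
        rss_f = sm.OLS(y, Xf).fit().ssr
        df_f = len(y) - Xf.shape[1]
        f_manual = (rss_b - rss_f) / (rss_f / df_f)
        assert comp["f_statistic"] == pytest.approx(f_manual, rel=1e-10)

    def test_noise_interaction_prefers_base_model(self):
        picks = []
        for i in range(7):
            df = planted_frame(200, 0.24, -0.33, solve_predictor_correlation(0.24, -0.33, 0.09), 0.09, 300 + i)
            _, comp = hierarchical_compare(df)
            picks.append(comp["chosen"])
        assert picks.count("base") > len(picks) / 2

    def test_true_interaction_selects_full_model(self, rng):
        n = 400
        xa, xv = rng.standard_normal(n), rng.standard_normal(n)
        y = 0.2 * xa + 0.2 * xv + 0.8 * xa * xv + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame({"delta_arousal": xa, "delta_valence": xv, "delta_ltd": y})
        chosen, comp = hierarchical_compare(df)
        assert comp["chosen"] == "full"
        assert "delta_arousal:delta_valence" in chosen.terms


class TestEstimatorInterface:
    def test_fit_from_arrays_and_predict(self, rng):
        n = 300
        X = rng.standard_normal((n, 2))
        y = 0.4 * X[:, 0] - 0.2 * X[:, 1] + 0.1 * rng.standard_normal(n)
        est = MoodDeltaRegression(with_interaction=False).fit(X, y)
        assert est.coef_.shape == (2,)
        pred = est.predict(np.eye(2))
        assert pred[0] == pytest.approx(est.coef_[0])

    def test_auto_mode_exposes_comparison(self):
        df = planted_frame(120, 0.24, -0.33, solve_predictor_correlation(0.24, -0.33, 0.09), 0.09, 5)
        est = MoodDeltaRegression().fit(df)
        assert est.comparison_["chosen"] in {"base", "full"}
        assert est.result_.n == 120

    def test_get_set_params(self):
        est = MoodDeltaRegression(alpha=0.01)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(correction_factor=5.0)
        assert est.correction_factor == 5.0
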