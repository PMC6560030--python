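"""Decision-value regression models, aggregation, and control analyses."""

import numpy as np
import pandas as pd
import pytest

from futurestate.design import generate_design
from futurestate.dvreg import (CategoryRegressionFit, aggregate_and_infer,
                               average_categories, build_correct_rep,
                               build_state1_predictors,
                               fit_decision_regression, per_bin_models,
                               reduced_models, roi_sweep,
                               state_variant_models)
from futurestate.simulate import simulate_behavior


@pytest.fixture(scope="module")
def s1_events(design, behavior):
    from futurestate.design import build_events

    ev = build_events(design, behavior)
    return ev[(ev["state"] == "S1") & ev["of_interest"]].reset_index(drop=True)


@pytest.fixture(scope="module")
def covariate(behavior):
    return build_correct_rep(behavior)


class TestPredictorConstruction:
    def test_binary_indicators_follow_maze_categories(self, design, s1_events,
                                                      covariate):
        m = design.mazes[0]
        X = build_state1_predictors(s1_events, design, covariate, m.s1_category)
        rows = s1_events["maze_id"] == m.maze_id
        assert (X.loc[rows.to_numpy(), "current"] == 1.0).all()
        X2 = build_state1_predictors(s1_events, design, covariate,
                                     m.s3_correct_category)
        assert (X2.loc[rows.to_numpy(), "current"] == 0.0).all()
        assert (X2.loc[rows.to_numpy(), "future"] == 1.0).all()

    def test_interactions_are_products(self, design, s1_events, covariate):
        X = build_state1_predictors(s1_events, design, covariate, "face")
        np.testing.assert_array_equal(X["future_x_rep"],
                                      X["future"] * X["correct_rep"])
        np.testing.assert_array_equal(X["current_x_rep"],
                                      X["current"] * X["correct_rep"])

    def test_unknown_maze_rejected(self, design, covariate):
        bogus = pd.DataFrame({"maze_id": [99], "repetition": [1], "state": ["S1"]})
        with pytest.raises(KeyError):
            build_state1_predictors(bogus, design, covariate, "face")

    def test_zero_covariate_makes_interactions_degenerate(self, design, s1_events):
        zero_cov = pd.Series(0, index=pd.MultiIndex.from_product(
            [range(1, 11), range(1, 5)], names=["maze_id", "repetition"]))
        X = build_state1_predictors(s1_events, design, zero_cov, "face")
        assert (X["future_x_rep"] == 0).all()
        with pytest.raises(np.linalg.LinAlgError):
            fit_decision_regression(np.random.default_rng(0).normal(size=len(X)), X)


class TestFit:
    def test_constructed_coefficients_recovered_exactly(self, design, s1_events,
                                                        covariate):
        X = build_state1_predictors(s1_events, design, covariate, "face")
        y = 0.1 * X["current"] + 0.05 * X["future_x_rep"]
        fit = fit_decision_regression(y.to_numpy(), X, "face")
        assert fit.coefficients["current"] == pytest.approx(0.1, abs=1e-10)
        assert fit.coefficients["future_x_rep"] == pytest.approx(0.05, abs=1e-10)
        for k in ("future", "correct_rep", "current_x_rep"):
            assert fit.coefficients[k] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, design, s1_events, covariate):
        # brute-force oracle: solve (X'X)b = X'y directly
        rng = np.random.default_rng(0)
        X = build_state1_predictors(s1_events, design, covariate, "scene")
        y = rng.normal(size=len(X))
        fit = fit_decision_regression(y, X, "scene")
        Xd = np.column_stack([np.ones(len(X)), X.to_numpy()])
        b = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        got = [fit.intercept] + [fit.coefficients[c] for c in X.columns]
        np.testing.assert_allclose(got, b, atol=1e-10)

    def test_pure_noise_coefficients_center_on_zero(self, design, s1_events,
                                                    covariate):
        rng = np.random.default_rng(1)
        X = build_state1_predictors(s1_events, design, covariate, "object")
        coefs = np.array([
            list(fit_decision_regression(rng.normal(size=len(X)), X)
                 .coefficients.values())
            for _ in range(1000)])
        se = coefs.std(axis=0) / np.sqrt(len(coefs))
        assert np.all(np.abs(coefs.mean(axis=0)) < 2 * se + 1e-3)

    def test_too_few_observations_rejected(self, design, covariate):
        ev = pd.DataFrame({"maze_id": [1] * 5, "repetition": [1] * 5,
                           "state": "S1"})
        X = build_state1_predictors(ev, design, covariate, "face")
        with pytest.raises(ValueError):
            fit_decision_regression(np.zeros(5), X)


class TestReducedAndPerBin:
    def test_orthogonal_signals_unchanged_when_reduced(self, design, s1_events,
                                                       covariate):
        X = build_state1_predictors(s1_events, design, covariate, "face")
        # orthogonalize the future column against everything kept
        y = 0.2 * X["current"].to_numpy()
        full = fit_decision_regression(y, X)
        red = reduced_models(y, X, drop="future")
        assert red.coefficients["current"] == pytest.approx(
            full.coefficients["current"], abs=1e-10)

    def test_omitted_variable_shift_matches_formula(self):
        # classic omitted-variable algebra on a small constructed design
        rng = np.random.default_rng(2)
        n = 200
        x1 = rng.normal(size=n)
        x2 = 0.6 * x1 + 0.8 * rng.normal(size=n)
        y = 1.0 * x1 + 0.5 * x2
        X = pd.DataFrame({"current": x1, "future": x2})
        full = fit_decision_regression(y, X)
        red = reduced_models(y, X, drop="future")
        # delta = beta_future * slope of future on current
        slope = np.polyfit(x1, x2, 1)[0]
        expect = full.coefficients["current"] + 0.5 * slope
        assert red.coefficients["current"] == pytest.approx(expect, abs=1e-8)

    def test_dropping_both_rejected(self, design, s1_events, covariate):
        X = build_state1_predictors(s1_events, design, covariate, "face")
        with pytest.raises(ValueError):
            reduced_models(np.zeros(len(X)), X, drop="both")

    def test_per_bin_future_growth_matches_full_model(self, design, s1_events,
                                                      covariate):
        # algebraic oracle: per-bin coefficient equals main + bin*interaction
        X = build_state1_predictors(s1_events, design, covariate, "face")
        y = (0.3 * X["current"] + 0.1 * X["future"]
             + 0.05 * X["future_x_rep"]).to_numpy()
        bins = per_bin_models(y, X)
        for row in bins.itertuples(index=False):
            assert row.future == pytest.approx(0.1 + 0.05 * row.bin, abs=1e-8)
            assert row.current == pytest.approx(0.3, abs=1e-8)
        assert np.all(np.diff(bins["future"]) > 0)

    def test_bin_zero_future_null_without_pre_exposure_signal(self, design,
                                                              s1_events, covariate):
        X = build_state1_predictors(s1_events, design, covariate, "face")
        y = (0.3 * X["current"] + 0.05 * X["future_x_rep"]).to_numpy()
        bins = per_bin_models(y, X)
        b0 = bins[bins["bin"] == 0]
        assert b0["future"].iloc[0] == pytest.approx(0.0, abs=1e-8)


class TestAggregation:
    def _fit(self, vals, valid=True, cat="face"):
        return CategoryRegressionFit(
            category=cat, coefficients=dict(zip(
                ("current", "future", "correct_rep", "current_x_rep",
                 "future_x_rep"), vals)),
            intercept=0.0, residual_sd=1.0, n_obs=32, valid=valid)

    def test_average_only_over_valid_categories(self):
        fits = [self._fit([1, 0, 0, 0, 1], True, "face"),
                self._fit([3, 0, 0, 0, 3], True, "scene"),
                self._fit([99, 0, 0, 0, 99], False, "object")]
        eff = average_categories(fits)
        assert eff.means["current"] == 2.0
        assert eff.n_valid_categories == 2

    def test_participant_with_no_valid_categories_dropped(self):
        good = [[self._fit(np.random.default_rng(s).normal(size=5))
                 for _ in range(3)] for s in range(4)]
        bad = [[self._fit([9] * 5, valid=False) for _ in range(3)]]
        table, group = aggregate_and_infer(good + bad)
        assert len(table) == 4

    def test_identical_coefficients_flagged_not_infinite(self):
        fits = [[self._fit([1, 1, 1, 1, 1])] for _ in range(5)]
        table, group = aggregate_and_infer(fits)
        assert group["future_x_rep"].degenerate
        assert np.isnan(group["future_x_rep"].t)

    def test_category_relabeling_invariance(self):
        # group stats depend on coefficient values, not category names
        vals = [np.random.default_rng(s).normal(size=5) for s in range(6)]
        a = [[self._fit(v, cat=c) for c in ("face", "scene", "object")]
             for v in vals]
        b = [[self._fit(v, cat=c) for c in ("scene", "object", "face")]
             for v in vals]
        ta, ga = aggregate_and_infer(a)
        tb, gb = aggregate_and_infer(b)
        assert ga["future_x_rep"].t == gb["future_x_rep"].t


class TestStateVariants:
    def test_s2_future_null_when_signal_only_at_s1(self, participant_result):
        r = participant_result
        fits = [state_variant_models(r.dv_table, r.design, r.covariate,
                                     "S2", c) for c in ("face", "scene", "object")]
        vals = [f.coefficients["future_x_rep"] for f in fits]
        assert abs(np.mean(vals)) < 0.15

    def test_planted_s3_suppression_recovered(self, design, behavior):
        from futurestate import decode
        from futurestate.simulate import SimTruth, simulate_patterns

        hits = 0
        for s in range(20):
            truth = SimTruth.default(seed=100 + s, noise_sd=0.3, g_future=0.0,
                                     g_s3_current_slope=-0.15)
            loc, learn = simulate_patterns(design, behavior, truth)
            clfs = decode.train_pairwise(loc, seed=s)
            dv = decode.decision_values(clfs, learn)
            cov = build_correct_rep(behavior)
            vals = [state_variant_models(dv, design, cov, "S3", c)
                    .coefficients["current_x_rep"]
                    for c in ("face", "scene", "object")]
            hits += np.mean(vals) < 0
        assert hits >= 18

    def test_feedback_past_state_type_one_rate(self, design, behavior):
        from futurestate import decode
        from futurestate.simulate import SimTruth, simulate_patterns

        cov = build_correct_rep(behavior)
        vals = []
        for s in range(30):
            truth = SimTruth.default(seed=200 + s, noise_sd=1.0, g_future=0.0)
            loc, learn = simulate_patterns(design, behavior, truth)
            clfs = decode.train_pairwise(loc, seed=s)
            dv = decode.decision_values(clfs, learn)
            vals.append(np.mean([
                state_variant_models(dv, design, cov, "FEEDBACK", c)
                .coefficients["past_s1"] for c in ("face", "scene", "object")]))
        from futurestate.behavior import one_sample_test
        g = one_sample_test(np.array(vals))
        assert g.p > 0.01   # no planted past signal: should not reject

    def test_missing_state_rejected(self, participant_result):
        r = participant_result
        no_s2 = r.dv_table[r.dv_table["state"] != "S2"]
        with pytest.raises(ValueError):
            state_variant_models(no_s2, r.design, r.covariate, "S2", "face")


class TestRoiSweep:
    def test_single_roi_single_row(self):
        t = roi_sweep({"ofc": np.random.default_rng(0).normal(0.1, 0.1, 20)})
        assert len(t) == 1

    def test_planted_roi_ranks_first(self):
        rng = np.random.default_rng(3)
        rois = {f"null{i}": rng.normal(0, 0.1, 25) for i in range(9)}
        rois["target"] = rng.normal(0.2, 0.1, 25)
        t = roi_sweep(rois)
        assert t.iloc[0]["roi"] == "target"

    def test_null_false_positive_rate(self):
        # 29 null regions, many sweeps: ~5% uncorrected positives
        rng = np.random.default_rng(4)
        sig = 0
        total = 0
        for _ in range(50):
            t = roi_sweep({f"r{i}": rng.normal(0, 1, 30) for i in range(29)})
            sig += int(t["sig"].sum())
            total += 29
        rate = sig / total
        assert 0.03 <= rate <= 0.075


def test_future_rep_estimate_increases_with_planted_slope():
    # expectation of the recovered interaction grows with the planted
    # future-state slope (grid of small cohorts per slope)
    from futurestate.pipeline import PipelineConfig, run_cohort

    means = []
    for g in (0.0, 0.05, 0.15):
        vals = [run_cohort(PipelineConfig(seed=500 + s, n_participants=8,
                                          g_future=g))
                .group["future_x_rep"].mean for s in range(8)]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


class TestCorrectRepAlternativeCoding:
    def test_codings_agree_when_always_correct_after_learning(self):
        d = generate_design(seed=3)
        b = simulate_behavior(d, 1.0, 1.0, seed=3)
        obs = build_correct_rep(b, "observed")
        strict = build_correct_rep(b, "correct_only")
        interest = [m.maze_id for m in d.mazes if m.of_interest]
        for mid in interest:
            for rep in (1, 2, 3, 4):
                assert obs[(mid, rep)] == strict[(mid, rep)]
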