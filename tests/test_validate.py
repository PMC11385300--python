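"""Splits, confusion matrices, error rates, scoring rules, K-fold."""

import numpy as np
import pandas as pd
import pytest

from tillage_bbn.discretize import OUTPUT_LABELS
from tillage_bbn.tillage import cases_to_states, fit_tillage_model
from tillage_bbn.validate import (HOLDOUT_PLAN, KFOLD_PLAN,
                                  REFERENCE_CONFUSION_MATRICES,
                                  ConfusionMatrix, SplitPlan, error_rate,
                                  evaluate, kfold_report, score_posteriors,
                                  split)


class TestSplits:
    def test_holdout_sizes_1110_train_330_test(self, default_cases):
        parts = split(default_cases, HOLDOUT_PLAN)
        assert len(parts["train"]) == 37 * 30 == 1110
        assert len(parts["test"]) == 11 * 30 == 330

    def test_kfold_decade_blocks(self, default_cases):
        parts = split(default_cases, KFOLD_PLAN)
        sizes = {lab: df["year"].nunique() for lab, df in parts.items()}
        assert sizes == {"K1": 10, "K2": 10, "K3": 10, "K4": 10, "K5": 8}

    def test_year_outside_plan_rejected(self, default_cases):
        bad = default_cases.copy()
        bad.loc[bad.index[0], "year"] = 1950
        with pytest.raises(ValueError, match="1950"):
            split(bad, HOLDOUT_PLAN)

    def test_empty_block_rejected(self, default_cases):
        train_only = default_cases[default_cases["year"] <= 2011]
        with pytest.raises(ValueError, match="test"):
            split(train_only, HOLDOUT_PLAN)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan("bad", (("a", 2000, 2010), ("b", 2010, 2020)))


class TestErrorRate:
    def test_reference_ghg_matrix_gives_29_39(self):
        assert error_rate(REFERENCE_CONFUSION_MATRICES["ghg"]) == 29.39

    def test_reference_runoff_matrix_gives_33_64(self):
        assert error_rate(REFERENCE_CONFUSION_MATRICES["runoff"]) == 33.64

    def test_reference_yield_matrix_gives_43_94(self):
        assert error_rate(REFERENCE_CONFUSION_MATRICES["yield"]) == 43.94

    def test_reference_matrices_have_330_test_cases(self):
        for cm in REFERENCE_CONFUSION_MATRICES.values():
            assert cm.total == 330

    def test_diagonal_matrix_is_zero_error(self):
        cm = ConfusionMatrix("x", OUTPUT_LABELS, np.diag([5, 5, 5, 5, 5]))
        assert error_rate(cm) == 0.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix("x", OUTPUT_LABELS, np.zeros((5, 5), dtype=int))
        with pytest.raises(ValueError):
            error_rate(cm)


class TestScoringRules:
    def test_perfect_predictor_limits(self):
        posts = np.eye(5)[np.array([0, 2, 4])]
        s = score_posteriors(posts, np.array([0, 2, 4]))
        assert s["logarithmic_loss"] == pytest.approx(0.0)
        assert s["quadratic_loss"] == pytest.approx(0.0)
        assert s["spherical_payoff"] == pytest.approx(1.0)

    def test_uniform_five_state_closed_forms(self):
        posts = np.full((4, 5), 0.2)
        s = score_posteriors(posts, np.array([0, 1, 2, 3]))
        assert s["logarithmic_loss"] == pytest.approx(np.log(5))
        assert s["quadratic_loss"] == pytest.approx(0.8)
        assert s["spherical_payoff"] == pytest.approx(1 / np.sqrt(5))

    def test_three_case_toy_matches_hand_arithmetic(self):
        posts = np.array([[0.7, 0.2, 0.1],
                          [0.1, 0.6, 0.3],
                          [0.25, 0.25, 0.5]])
        actual = np.array([0, 2, 2])
        s = score_posteriors(posts, actual)
        # hand: P_c = 0.7, 0.3, 0.5
        assert s["logarithmic_loss"] == pytest.approx(
            -(np.log(0.7) + np.log(0.3) + np.log(0.5)) / 3)
        sq = [0.54, 0.46, 0.375]
        assert s["quadratic_loss"] == pytest.approx(
            np.mean([1 - 2 * 0.7 + sq[0], 1 - 2 * 0.3 + sq[1],
                     1 - 2 * 0.5 + sq[2]]))
        assert s["spherical_payoff"] == pytest.approx(
            np.mean([0.7 / np.sqrt(sq[0]), 0.3 / np.sqrt(sq[1]),
                     0.5 / np.sqrt(sq[2])]))

    def test_zero_probability_actual_is_floored_and_flagged(self):
        posts = np.array([[1.0, 0.0]])
        s = score_posteriors(posts, np.array([1]))
        assert s["n_floored"] == 1
        assert np.isfinite(s["logarithmic_loss"])


class TestEvaluate:
    def test_matrix_total_and_score_bounds(self, holdout_fit):
        net, schemes, parts = holdout_fit
        test_states = cases_to_states(parts["test"], schemes)
        for target in ("yield", "runoff", "ghg"):
            cm, rep = evaluate(net, test_states, target)
            assert cm.total == len(parts["test"]) == rep.n_cases
            assert 0.0 <= rep.logarithmic_loss
            assert 0.0 <= rep.quadratic_loss <= 2.0
            assert 0.0 <= rep.spherical_payoff <= 1.0
            assert rep.error_rate == error_rate(cm)

    def test_inputs_only_policy_runs(self, holdout_fit):
        net, schemes, parts = holdout_fit
        test_states = cases_to_states(parts["test"].head(30), schemes)
        cm, rep = evaluate(net, test_states, "yield", "inputs_only")
        assert cm.total == 30

    def test_no_leakage_predictions_invariant_within_bands(self, holdout_fit):
        # nudging raw test values without crossing a band boundary must not
        # change a single prediction (schemes/CPTs depend on training only)
        net, schemes, parts = holdout_fit
        test = parts["test"].head(60)
        states = cases_to_states(test, schemes)
        perturbed = test.copy()
        rng = np.random.default_rng(9)
        for var, sch in schemes.items():
            edges = [-np.inf] + list(sch.boundaries) + [np.inf]
            idx = np.searchsorted(sch.boundaries, test[var], side="right")
            lo = np.maximum(np.array(edges)[idx], test[var].min() - 1.0)
            hi = np.minimum(np.array(edges)[idx + 1], test[var].max() + 1.0)
            u = rng.uniform(0.05, 0.95, len(test))
            perturbed[var] = lo + u * np.clip(hi - lo, 0, None)
        pstates = cases_to_states(perturbed, schemes)
        pd.testing.assert_frame_equal(states.reset_index(drop=True),
                                      pstates.reset_index(drop=True))


class TestKfold:
    def test_report_shape_and_average(self, default_cases):
        sub = default_cases[default_cases["experiment"].isin(
            sorted(default_cases["experiment"].unique())[:6])]

        def factory(train):
            return fit_tillage_model(train, prior_weight=1.0)

        report = kfold_report(factory, sub, "yield")
        assert list(report["fold"]) == ["K1", "K2", "K3", "K4", "average", "K5"]
        cv = report[report["fold"].isin(["K1", "K2", "K3", "K4"])]
        avg = report.loc[report["fold"] == "average", "error_rate"].iloc[0]
        assert avg == pytest.approx(cv["error_rate"].mean(), abs=0.01)
        assert report.loc[report["fold"] == "K5", "role"].iloc[0] == "final_test"

    def test_fold_errors_match_manual_rerun_on_small_fixture(self):
        # a by-hand refit/test of the K1 fold must agree with kfold_report
        rng = np.random.default_rng(21)
        years = np.repeat(np.arange(1975, 2023), 2)
        n = len(years)
        df = pd.DataFrame({
            "experiment": ["A", "B"] * (n // 2),
            "year": years,
            "tillage": ["NT", "CT"] * (n // 2),
            "soilscape": ["OC-3%PDPG6", "OC-5%PDPG6"] * (n // 2),
        })
        base = rng.normal(0, 0.05, n)
        for var in ("rainfall", "temperature", "csom", "aws", "interception",
                    "biomass", "runoff", "ghg"):
            df[var] = rng.gamma(5, 10, n)
        df["yield"] = np.where(df["tillage"] == "NT", 100.0, 10.0) + base

        def factory(train):
            return fit_tillage_model(train, prior_weight=1.0)

        report = kfold_report(factory, df, "yield")
        k1 = report.loc[report["fold"] == "K1", "error_rate"].iloc[0]
        # manual rerun of the K1 fold
        train = df[df["year"] > 1984]
        test = df[df["year"] <= 1984]
        net, schemes = factory(train)
        _, rep = evaluate(net, cases_to_states(test, schemes), "yield")
        assert k1 == rep.error_rate
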