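"""Cohort statistics: perseveration scoring, gated t test, logistic models, CV."""

import math

import numpy as np
import pandas as pd
import pytest

from fluencynet import (
    DegenerateDataError,
    FluencyList,
    confusion_summary,
    fit_logistic,
    group_ttest,
    perseveration_rate,
    split_half_cv,
    stepwise_aic,
)


class TestPerseverationRate:
    @pytest.mark.parametrize(
        "items,expected",
        [
            (("dog", "cat", "hamster", "lion"), 0.0),
            (("dog", "cat", "dog", "cat"), 0.5),
            (("dog", "cat", "hamster", "cat", "lion"), 0.2),
        ],
    )
    def test_rates(self, items, expected):
        assert perseveration_rate(FluencyList("p", "l", items)) == pytest.approx(expected)


class TestGroupTTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = group_ttest(x, list(x))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert not res.welch

    def test_welch_branch_matches_hand_formula(self):
        # classic two-group data with very unequal variances
        x = np.array([19.8, 12.4, 32.1, 17.9, 27.6, 23.5, 14.2, 30.0, 21.2, 25.7])
        y = np.array([100.1, 35.2, 55.3, 82.4, 70.9, 44.5, 93.6, 64.8, 28.7, 110.2])
        res = group_ttest(x, y)
        assert res.welch
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        nx_, ny = len(x), len(y)
        t_hand = (x.mean() - y.mean()) / math.sqrt(sx2 / nx_ + sy2 / ny)
        df_hand = (sx2 / nx_ + sy2 / ny) ** 2 / (
            (sx2 / nx_) ** 2 / (nx_ - 1) + (sy2 / ny) ** 2 / (ny - 1)
        )
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == pytest.approx(df_hand)

    def test_variance_gate_type_one_rate(self):
        """With truly equal variances the pooled branch is chosen ~95% of runs."""
        rng = np.random.default_rng(8)
        pooled = sum(
            not group_ttest(rng.normal(0, 1, 50), rng.normal(0.3, 1, 50)).welch
            for _ in range(400)
        )
        assert 0.90 <= pooled / 400 <= 0.99

    def test_double_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            group_ttest([1.0, 1.0, 1.0], [1.0, 1.0])


def _synthetic_table(n=120, signal=2.5, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    diagnosis = np.array(["NC"] * half + ["PAD"] * (n - half))
    strong = np.where(diagnosis == "PAD", signal, 0.0) + rng.normal(0, 1, n)
    strong2 = np.where(diagnosis == "PAD", -signal, 0.0) + rng.normal(0, 1, n)
    noise = rng.normal(0, 1, n)
    return pd.DataFrame(
        {"diagnosis": diagnosis, "strong": strong, "strong2": strong2, "noise": noise}
    )


class TestFitLogistic:
    def test_aic_identity(self):
        table = _synthetic_table()
        fit = fit_logistic(table, ["strong", "noise"])
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.n_parameters)

    def test_direction_of_true_effect(self):
        fit = fit_logistic(_synthetic_table(), ["strong", "strong2"])
        assert fit.params["strong"] > 0 > fit.params["strong2"]
        assert fit.pvalues["strong"] < 0.01

    def test_pure_noise_factor_calibration(self):
        """A null factor should reach p < .05 in roughly 5% of datasets."""
        hits = 0
        n_sims = 150
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            table = pd.DataFrame(
                {
                    "diagnosis": ["PAD" if i % 2 else "NC" for i in range(200)],
                    "noise": rng.normal(0, 1, 200),
                }
            )
            if fit_logistic(table, ["noise"]).pvalues["noise"] < 0.05:
                hits += 1
        assert 0.005 <= hits / n_sims <= 0.12

    def test_outcome_as_factor_flags_separation(self):
        table = _synthetic_table()
        table["leak"] = (table["diagnosis"] == "PAD").astype(float)
        fit = fit_logistic(table, ["leak"])
        assert fit.separation

    def test_missing_factor_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(_synthetic_table(), ["absent"])


class TestStepwiseAIC:
    def test_useless_factor_removed(self):
        table = _synthetic_table(signal=3.0, seed=2)
        fit = stepwise_aic(table, ["strong", "strong2", "noise"],
                           ["strong", "strong2", "noise"])
        assert "noise" not in fit.factors
        assert {"strong", "strong2"} <= set(fit.factors)

    def test_fixed_point_returns_unchanged(self):
        table = _synthetic_table(signal=3.0, seed=3)
        best = stepwise_aic(table, ["strong", "strong2", "noise"],
                            ["strong", "strong2", "noise"])
        again = stepwise_aic(table, list(best.factors),
                             ["strong", "strong2", "noise"])
        assert again.factors == best.factors
        assert again.aic == pytest.approx(best.aic)

    def test_aic_never_above_start(self):
        table = _synthetic_table(seed=4)
        start = ["strong", "strong2", "noise"]
        fit = stepwise_aic(table, start, start)
        assert fit.aic <= fit_logistic(table, start).aic + 1e-9


class TestConfusionSummary:
    def test_perfect_counts(self):
        s = confusion_summary(10, 0, 0, 10)
        assert s.accuracy == 1.0 and s.f1 == 1.0

    def test_undefined_precision_signalled(self):
        s = confusion_summary(0, 3, 0, 5)
        assert math.isnan(s.precision)

    def test_fractional_averaged_counts(self):
        s = confusion_summary(38.11, 2.93, 2.00, 82.98)
        assert s.accuracy == pytest.approx(0.9609, abs=5e-4)


class TestSplitHalfCV:
    def test_separable_table_is_perfect(self):
        table = _synthetic_table(signal=30.0, seed=5)
        cv = split_half_cv(table, ["strong"], n_reps=40,
                           rng=np.random.default_rng(0))
        assert cv.accuracy > 0.97
        assert cv.f1 > 0.97

    def test_label_permutation_near_majority_rate(self):
        rng = np.random.default_rng(6)
        table = _synthetic_table(signal=3.0, seed=6)
        table["diagnosis"] = rng.permutation(table["diagnosis"].to_numpy())
        cv = split_half_cv(table, ["strong", "strong2"], n_reps=150,
                           rng=np.random.default_rng(1))
        assert abs(cv.accuracy - 0.5) < 0.12  # balanced classes: majority ~ 0.5

    def test_seeded_reproducibility_single_rep(self):
        table = _synthetic_table(seed=7)
        cv1 = split_half_cv(table, ["strong"], n_reps=1, rng=np.random.default_rng(3))
        cv2 = split_half_cv(table, ["strong"], n_reps=1, rng=np.random.default_rng(3))
        assert cv1 == cv2

    def test_two_seeds_agree_within_mc_error(self):
        table = _synthetic_table(signal=2.0, seed=8)
        cv1 = split_half_cv(table, ["strong"], n_reps=400, rng=np.random.default_rng(4))
        cv2 = split_half_cv(table, ["strong"], n_reps=400, rng=np.random.default_rng(5))
        assert abs(cv1.accuracy - cv2.accuracy) < 0.02

    def test_stratification_preserves_class_ratio(self):
        table = _synthetic_table(seed=9)
        cv = split_half_cv(table, ["strong"], n_reps=20, rng=np.random.default_rng(6))
        # test halves hold half of each class: PAD test count = misses + hits
        assert cv.hits + cv.misses == pytest.approx(30.0)
        assert cv.false_alarms + cv.correct_rejections == pytest.approx(30.0)
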