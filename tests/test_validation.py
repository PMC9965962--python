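"""Tests of the validation machinery: screen, split, PRESS, agreement."""

import numpy as np
import pandas as pd
import pytest

from paee.equations import fit_ols
from paee.validation import (
    bland_altman,
    filter_outliers,
    paired_t,
    press_statistics,
    pure_error,
    split_every_third,
    validate_equation,
)

from _reference import press_by_refitting


class TestFilterOutliers:
    def test_identical_values_remove_nothing(self):
        data = pd.DataFrame({"a": [5.0] * 6, "b": np.arange(6.0)})
        with pytest.warns(UserWarning, match="zero variance"):
            kept, removed = filter_outliers(data)
        assert len(removed) == 0 and len(kept) == 6

    def test_single_five_sigma_row_removed(self):
        gen = np.random.default_rng(5)
        data = pd.DataFrame({"a": gen.normal(0, 1, 50)})
        data.loc[25, "a"] = 5 * data["a"].std()
        kept, removed = filter_outliers(data)
        assert list(removed.index) == [25]

    def test_planted_extremes_in_96_row_table_removed_exactly(self):
        """Eight planted extreme rows, one per column, are the screen's
        only catches in a 96-row table of bounded draws."""
        gen = np.random.default_rng(21)
        n, cols = 96, 8
        z = gen.normal(size=(n, cols))
        z = np.clip(z, -2.8, 2.8)
        planted = list(range(8))
        for row, col in zip(planted, range(cols)):
            z[row, col] = 8.0
        data = pd.DataFrame(z, columns=[f"c{i}" for i in range(cols)])
        kept, removed = filter_outliers(data)
        assert sorted(removed.index) == planted
        assert len(kept) == n - 8

    def test_single_pass_uses_full_input_moments(self):
        # one huge value inflates the SD enough to shelter a 4-sigma row
        data = pd.DataFrame({"a": [0.0] * 30 + [4.0] + [100.0]})
        data["b"] = np.linspace(0, 1, 32)
        kept, removed = filter_outliers(data, columns=["a"])
        assert 30 in kept.index  # the 4.0 survives the inflated threshold
        assert 31 in removed.index


class TestSplitEveryThird:
    @staticmethod
    def _cohort(n_boys, n_girls, seed=0):
        gen = np.random.default_rng(seed)
        rows = [
            {"participant_id": f"B{i:03d}", "sex_code": 1,
             "age": float(gen.uniform(11, 14))}
            for i in range(n_boys)
        ] + [
            {"participant_id": f"G{i:03d}", "sex_code": 0,
             "age": float(gen.uniform(11, 14))}
            for i in range(n_girls)
        ]
        return pd.DataFrame(rows)

    def test_study_group_sizes(self):
        split = split_every_third(self._cohort(41, 38))
        counts = split["group"].value_counts()
        assert counts["cross_validation"] == 25  # 13 boys + 12 girls
        assert counts["validation"] == 54

    def test_fewer_than_three_go_to_validation(self):
        split = split_every_third(self._cohort(2, 0))
        assert (split["group"] == "validation").all()

    def test_invariant_to_row_permutation(self):
        cohort = self._cohort(10, 9, seed=3)
        base = split_every_third(cohort).set_index("participant_id")["group"]
        shuffled = cohort.sample(frac=1.0, random_state=9)
        perm = split_every_third(shuffled).set_index("participant_id")["group"]
        assert base.sort_index().equals(perm.sort_index())

    @pytest.mark.parametrize("n", [1, 3, 7, 12, 41])
    def test_one_sex_yields_floor_n_over_3(self, n):
        split = split_every_third(self._cohort(n, 0))
        assert (split["group"] == "cross_validation").sum() == n // 3


class TestPureError:
    def test_perfect_prediction_is_zero(self):
        assert pure_error([0.3, 0.4], [0.3, 0.4]) == 0.0

    def test_hand_arithmetic(self):
        assert pure_error([0.5, 0.1], [0.4, 0.2]) == pytest.approx(0.1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pure_error([1.0], [1.0, 2.0])

    def test_tracks_generating_residual_sd(self):
        """In a well-specified simulation, pure error estimates sigma."""
        gen = np.random.default_rng(15)
        sigma = 0.13
        errors = []
        for _ in range(200):
            pred = gen.uniform(0, 1, 25)
            obs = pred + gen.normal(0, sigma, 25)
            errors.append(pure_error(obs, pred))
        mean_pe = float(np.mean(errors))
        assert mean_pe == pytest.approx(sigma, rel=0.05)


class TestPress:
    def test_closed_form_equals_explicit_refits(self, rng):
        x = rng.normal(size=(12, 2))
        y = x @ [0.5, -0.2] + rng.normal(0, 0.3, 12)
        data = pd.DataFrame(x, columns=["a", "b"])
        data["paee"] = y
        result = press_statistics(data, ["a", "b"])
        assert result.press == pytest.approx(press_by_refitting(x, y), abs=1e-10)

    def test_perfect_linear_dataset_gives_zero_press(self):
        x = np.linspace(0, 1, 12)
        data = pd.DataFrame({"x": x, "paee": x})
        result = press_statistics(data, ["x"])
        assert result.press == pytest.approx(0.0, abs=1e-20)
        assert result.press_r2_pct == pytest.approx(100.0)

    def test_press_r2_below_fitted_r2(self, regression_dataset):
        fitted = fit_ols(regression_dataset, ["cpm"])
        result = press_statistics(regression_dataset, ["cpm"])
        assert result.press_r2_pct <= fitted.r2_pct

    def test_press_r2_bounded_by_r2_on_random_small_datasets(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 25))
            x = rng.normal(size=n)
            data = pd.DataFrame({"x": x, "paee": 0.4 * x + rng.normal(0, 1, n)})
            fitted = fit_ols(data, ["x"])
            result = press_statistics(data, ["x"])
            assert result.press_r2_pct <= fitted.r2_pct + 1e-9


class TestBlandAltman:
    def test_identical_series(self):
        bias, sd, (lo, hi), _ = bland_altman([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert bias == 0.0 and sd == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_arithmetic(self):
        bias, sd, (lo, hi), pairs = bland_altman([0.4, 0.6], [0.3, 0.3])
        assert bias == pytest.approx(0.2)
        assert sd == pytest.approx(0.141421, abs=1e-5)
        assert lo == pytest.approx(0.2 - 1.96 * sd)
        assert hi == pytest.approx(0.2 + 1.96 * sd)
        assert list(pairs["difference"]) == pytest.approx([0.1, 0.3])

    def test_limits_reconstruct_from_bias_and_sd(self, rng):
        a = rng.normal(0.4, 0.2, 30)
        b = a + rng.normal(0.05, 0.1, 30)
        bias, sd, (lo, hi), _ = bland_altman(a, b)
        assert lo == pytest.approx(bias - 1.96 * sd, rel=1e-12)
        assert hi == pytest.approx(bias + 1.96 * sd, rel=1e-12)

    def test_bias_coverage_under_unbiased_simulation(self):
        """|bias| < 2 SE(bias) at the nominal normal rate."""
        gen = np.random.default_rng(31)
        n, reps = 25, 400
        hits = 0
        for _ in range(reps):
            a = gen.normal(0.4, 0.2, n)
            b = a + gen.normal(0.0, 0.1, n)
            bias, sd, _, _ = bland_altman(a, b)
            hits += abs(bias) < 2 * sd / np.sqrt(n)
        rate = hits / reps
        expected = 0.9545
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(rate - expected) < 3.5 * se


class TestPairedT:
    def test_zero_variance_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])

    def test_symmetric_differences_give_t_zero(self):
        out = paired_t([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_type_one_error_calibrated_at_five_percent(self):
        gen = np.random.default_rng(8)
        n, reps = 25, 10_000
        d = gen.normal(0, 1, size=(reps, n))
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        from scipy import stats

        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
        rate = float((p < 0.05).mean())
        assert 0.04 <= rate <= 0.06


class TestValidateEquation:
    def test_composition_on_well_specified_simulation(self, regression_dataset):
        train = regression_dataset.iloc[:150]
        holdout = regression_dataset.iloc[150:]
        eq = fit_ols(train, ["cpm"])
        report = validate_equation(eq, holdout)
        assert report.n == len(holdout)
        assert report.correlation_r > 0.5
        assert report.p_value > 0.001  # no systematic difference
        assert np.isfinite(report.pure_error)
        assert report.loa_upper == pytest.approx(
            report.bias + 1.96 * report.sd_diff
        )

    def test_identical_predictions_degenerate_flagged(self):
        from paee.equations import FittedEquation

        data = pd.DataFrame({"cpm": [100.0, 200, 300], "paee": [0.1, 0.2, 0.3]})
        eq = FittedEquation(
            predictors=["cpm"], coefficients={"intercept": 0.0, "cpm": 0.001},
            r=1.0, r2_pct=100.0, rmse=0.0, n=3,
        )
        report = validate_equation(eq, data)
        assert report.pure_error == 0.0
        assert report.bias == 0.0
        assert np.isnan(report.p_value)
        assert any("degenerate" in note for note in report.notes)

    def test_significant_correlation_at_cross_group_size(self):
        """With the study's signal-to-noise, n=25 reliably detects the
        criterion/predicted correlation."""
        from paee.equations import FittedEquation
        from scipy import stats

        gen = np.random.default_rng(13)
        eq = FittedEquation(
            predictors=["cpm"], coefficients={"intercept": -0.112, "cpm": 0.001},
            r=0.8, r2_pct=64.0, rmse=0.13, n=54,
        )
        significant = 0
        reps = 200
        for _ in range(reps):
            cpm = np.clip(gen.normal(400, 170, 25), 5, None)
            data = pd.DataFrame(
                {"cpm": cpm, "paee": 0.001 * cpm - 0.112 + gen.normal(0, 0.13, 25)}
            )
            report = validate_equation(eq, data)
            t = report.correlation_r * np.sqrt(23 / (1 - report.correlation_r**2))
            significant += (
                report.correlation_r > 0 and 2 * stats.t.sf(t, 23) < 0.05
            )
        assert significant / reps >= 0.95
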