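"""Confusion metrics, McNemar tests, and feature-stability statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qemgdx import (
    ClassModel,
    confusion,
    discordant_pairs,
    feature_stability,
    mcnemar,
    round_half_up,
    separation_t,
    stability_ratio,
)
from qemgdx.evaluate import MismatchedStudySetError, UndefinedTestError


def pairs_from_counts(nn, nx, xn, xx):
    """(true, assigned) pairs: nn Normative→Normative, nx Normative→NSAP, ..."""
    return (
        [("Normative", "Normative")] * nn
        + [("Normative", "NSAP")] * nx
        + [("NSAP", "Normative")] * xn
        + [("NSAP", "NSAP")] * xx
    )


class TestConfusion:
    def test_mupt_level_counts(self):
        """900/1168 correct Normative and 193/266 correct NSAP."""
        cm = confusion(pairs_from_counts(900, 268, 73, 193))
        assert round_half_up(cm.specificity) == 0.771
        assert round_half_up(cm.sensitivity) == 0.726
        assert round_half_up(cm.performance) == 0.559

    def test_mean_distance_style_counts(self):
        cm = confusion(pairs_from_counts(38, 1, 5, 11))
        assert round_half_up(cm.specificity) == 0.974
        assert round_half_up(cm.sensitivity) == 0.688
        assert round_half_up(cm.performance) == 0.670

    def test_perfect_predictions(self):
        cm = confusion(pairs_from_counts(10, 0, 0, 5))
        assert cm.performance == 1.0
        assert cm.overall_accuracy == 1.0

    def test_performance_product_before_rounding(self):
        # 0.559 only arises from the unrounded product 0.770548×0.725564;
        # rounding the factors first would give 0.771×0.726 = 0.560
        cm = confusion(pairs_from_counts(900, 268, 73, 193))
        assert cm.performance == pytest.approx((900 / 1168) * (193 / 266))

    def test_performance_bounded_below_min_class_accuracy(self):
        cm = confusion(pairs_from_counts(8, 2, 3, 7))
        assert 0.0 <= cm.performance <= min(cm.per_class_accuracy.values())

    @given(
        st.integers(1, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50)
    )
    def test_performance_monotone_in_each_class_accuracy(self, nn, nx, xn, xx):
        cm = confusion(pairs_from_counts(nn, nx, xn, xx))
        improved = confusion(pairs_from_counts(nn + 1, nx, xn, xx + 1))
        # one more correct item in each class cannot decrease the product
        assert improved.performance >= cm.performance

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([])

    def test_text_rendering_includes_counts(self):
        text = confusion(pairs_from_counts(36, 3, 2, 14)).to_text("Vote")
        assert "36" in text
        assert "0.808" in text  # unrounded product 0.8077, half-up display


class TestDiscordantPairs:
    def triples(self, correctness, prefix="s"):
        return [
            (f"{prefix}{i}", "NSAP", "NSAP" if ok else "Normative")
            for i, ok in enumerate(correctness)
        ]

    def test_all_correct_both(self):
        a = self.triples([True] * 5)
        counts = discordant_pairs(a, a)
        assert counts == (5, 0, 0, 0)

    def test_single_improvement(self):
        a = self.triples([False, True, True])
        b = self.triples([True, True, True])
        counts = discordant_pairs(a, b)
        assert counts.improved == 1
        assert counts.degraded == 0

    def test_counts_partition_n(self):
        rng = np.random.default_rng(4)
        a = self.triples(rng.random(40) < 0.7)
        b = self.triples(rng.random(40) < 0.5)
        counts = discordant_pairs(a, b)
        assert sum(counts) == 40

    def test_order_independent_keying(self):
        a = self.triples([True, False, True])
        b = self.triples([False, True, True])
        assert discordant_pairs(a, list(reversed(b))) == discordant_pairs(a, b)

    def test_mismatched_sets_rejected(self):
        a = self.triples([True, True])
        b = self.triples([True, True], prefix="t")
        with pytest.raises(MismatchedStudySetError):
            discordant_pairs(a, b)


class TestMcNemar:
    def test_balanced_discordant_pairs(self):
        """(4,4): continuity-corrected χ² is 1/(α+β) = 0.125, OR = 1."""
        result = mcnemar(4, 4)
        assert result.chi2 == pytest.approx(0.125)
        assert result.p_two_tailed == pytest.approx(0.72, abs=0.005)
        assert result.odds_ratio == pytest.approx(1.0)

    def test_near_balanced_pairs(self):
        """(4,3): |α−β|−1 = 0, so χ² = 0 and p = 1; OR = 4/3."""
        result = mcnemar(4, 3)
        assert result.chi2 == 0.0
        assert result.p_two_tailed == 1.0
        assert result.odds_ratio == pytest.approx(4 / 3)

    def test_no_discordant_pairs_undefined(self):
        with pytest.raises(UndefinedTestError):
            mcnemar(0, 0)

    def test_zero_degraded_infinite_odds(self):
        result = mcnemar(3, 0)
        assert np.isinf(result.odds_ratio)
        assert result.ci95 is None

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_symmetry_in_chi2_and_inverted_odds(self, a, b):
        if a + b == 0:
            return
        fwd = mcnemar(a, b)
        rev = mcnemar(b, a)
        assert fwd.chi2 == rev.chi2
        assert fwd.p_two_tailed == rev.p_two_tailed
        if a > 0 and b > 0:
            assert fwd.odds_ratio == pytest.approx(1.0 / rev.odds_ratio)

    def test_large_imbalance_significant(self):
        result = mcnemar(20, 2)
        assert result.chi2 == pytest.approx((20 - 2 - 1) ** 2 / 22)
        assert result.p_two_tailed < 0.01


class TestFeatureStability:
    def make_fold_models(self, fold_means, fold_vars):
        """fold_means/fold_vars: dict class -> (n_folds, d) arrays."""
        n_folds = next(iter(fold_means.values())).shape[0]
        folds = []
        for f in range(n_folds):
            fold = {}
            for lab in ("Normative", "NSAP"):
                fold[lab] = ClassModel(
                    lab, fold_means[lab][f], np.diag(fold_vars[lab][f]), 0.5
                )
            folds.append(fold)
        return folds

    def test_statistics_from_known_folds(self):
        rng = np.random.default_rng(0)
        means = {
            "Normative": rng.normal(0, 1, size=(10, 3)),
            "NSAP": rng.normal(1, 1, size=(10, 3)),
        }
        variances = {
            lab: rng.uniform(0.5, 2.0, size=(10, 3)) for lab in means
        }
        table = feature_stability(self.make_fold_models(means, variances))
        for lab in means:
            np.testing.assert_allclose(
                table[f"{lab}_mean"], means[lab].mean(axis=0)
            )
            np.testing.assert_allclose(
                table[f"{lab}_sd_of_fold_means"], means[lab].std(axis=0, ddof=1)
            )
            np.testing.assert_allclose(
                table[f"{lab}_mean_fold_sd"],
                np.sqrt(variances[lab]).mean(axis=0),
            )
            np.testing.assert_allclose(
                table[f"{lab}_psi"],
                np.sqrt(variances[lab]).mean(axis=0)
                / means[lab].std(axis=0, ddof=1),
            )
        expected_t = np.abs(
            means["Normative"].mean(0) - means["NSAP"].mean(0)
        ) / np.sqrt(
            (
                np.sqrt(variances["Normative"]).mean(0) ** 2
                + np.sqrt(variances["NSAP"]).mean(0) ** 2
            )
            / 10
        )
        np.testing.assert_allclose(table["t"], expected_t)

    def test_identical_class_means_give_zero_t(self):
        means = {lab: np.tile([1.0, 2.0], (4, 1)) for lab in ("Normative", "NSAP")}
        # wiggle fold means slightly so sd_of_fold_means > 0, but keep
        # classes identical to each other
        means = {
            lab: m + np.arange(4)[:, None] * 0.01 for lab, m in means.items()
        }
        variances = {lab: np.ones((4, 2)) for lab in means}
        table = feature_stability(self.make_fold_models(means, variances))
        np.testing.assert_allclose(table["t"], 0.0, atol=1e-12)

    def test_constant_fold_means_give_infinite_psi_with_warning(self):
        means = {
            "Normative": np.tile([1.0], (3, 1)),
            "NSAP": np.tile([2.0], (3, 1)),
        }
        variances = {lab: np.ones((3, 1)) for lab in means}
        with pytest.warns(RuntimeWarning, match="infinite"):
            table = feature_stability(self.make_fold_models(means, variances))
        assert np.isinf(table["Normative_psi"].iloc[0])

    def test_t_magnitude_is_sign_free(self):
        assert separation_t(1.0, 3.0, 1.0, 1.0, 10) == separation_t(
            3.0, 1.0, 1.0, 1.0, 10
        )

    def test_stability_ratio_scalar(self):
        assert stability_ratio(0.5, 0.1) == pytest.approx(5.0)
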