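"""Folding, gene combination, stringency rules, regressions, SNaPshot math."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aeikit import (
    GeneAEI,
    call_permissive,
    call_stringent_2sd,
    call_stringent_sdthird,
    combine_gene,
    compare_methods_regression,
    concordance_counts,
    fold_ratio,
    fold_raw,
    logistic_aei_predictor,
    snapshot_normalize,
)


class TestFoldRatio:
    def test_basic_fold_and_logit(self):
        r = fold_ratio(20, 10)
        assert r.raw_ratio == pytest.approx(2.0)
        assert r.folded_ratio == pytest.approx(2.0)
        assert r.logit_score == pytest.approx(math.log(2))

    def test_reciprocal_folds_identically(self):
        assert fold_ratio(10, 20).folded_ratio == pytest.approx(2.0)
        assert fold_ratio(10, 20).log10_ratio == pytest.approx(-math.log10(2))

    def test_balanced_counts(self):
        r = fold_ratio(10, 10)
        assert r.folded_ratio == 1.0
        assert r.logit_score == 0.0

    def test_zero_count_is_an_error(self):
        with pytest.raises(ValueError, match="filter_sites"):
            fold_ratio(10, 0)
        with pytest.raises(ValueError):
            fold_ratio(0, 10)

    @given(st.integers(1, 1000), st.integers(1, 1000))
    def test_folding_symmetry_exact(self, a, b):
        assert fold_ratio(a, b).folded_ratio == fold_ratio(b, a).folded_ratio
        assert fold_ratio(a, b).logit_score == fold_ratio(b, a).logit_score
        assert fold_ratio(a, b).folded_ratio >= 1.0


class TestCombineGene:
    def test_reciprocal_pair_combines_to_two(self):
        g = combine_gene([fold_raw(2.0), fold_raw(0.5)])
        assert g.mean_folded == pytest.approx(2.0)
        assert g.n_obs == 2

    def test_single_observation_has_no_sd(self):
        g = combine_gene([3.1])
        assert g.mean_folded == pytest.approx(3.1)
        assert g.sd_folded is None
        assert g.het_q == pytest.approx(0.0)

    def test_hand_arithmetic_mean_and_sd(self):
        g = combine_gene([2.0, 4.0])
        assert g.mean_folded == pytest.approx(3.0)
        assert g.sd_folded == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_identical_copies_have_zero_sd(self):
        g = combine_gene([2.5] * 5)
        assert g.mean_folded == pytest.approx(2.5)
        assert g.sd_folded == pytest.approx(0.0)
        assert g.het_q == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_gene([])

    def test_het_q_is_log_scale_dispersion(self):
        g = combine_gene([1.0, 10.0])
        # log10 values 0 and 1, mean 0.5 -> Q = 0.25 + 0.25
        assert g.het_q == pytest.approx(0.5)


def _gene(mean, sd, n=2):
    return GeneAEI(gene="G", sample_id="S", n_obs=n, mean_folded=mean,
                   sd_folded=sd, mean_log10=math.log10(mean), het_q=0.0)


class TestStringencyRules:
    @pytest.mark.parametrize(
        "mean, n, expected",
        [(2.0, 2, True), (5.0, 1, False), (1.99, 4, False), (2.0, 1, False)],
    )
    def test_permissive(self, mean, n, expected):
        g = _gene(mean, 0.1 if n > 1 else None, n)
        assert call_permissive(g) is expected

    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(2.5, 0.4, True), (2.0, 0.5, False), (1.5, 0.0, True), (3.0, 0.75, True),
         (3.0, 0.76, False)],
    )
    def test_stringent_2sd(self, mean, sd, expected):
        assert call_stringent_2sd(_gene(mean, sd)) is expected

    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(3.0, 0.9, True), (3.0, 1.2, False), (1.8, 0.1, False), (2.0, 2 / 3, True)],
    )
    def test_stringent_sdthird(self, mean, sd, expected):
        assert call_stringent_sdthird(_gene(mean, sd)) is expected

    def test_single_observation_ineligible_for_stringent_calls(self):
        g = _gene(5.0, None, n=1)
        assert call_stringent_2sd(g) is False
        assert call_stringent_sdthird(g) is False

    def test_stringent_2sd_implies_mean_at_least_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            g = _gene(float(rng.uniform(1, 5)), float(rng.uniform(0, 2)))
            if call_stringent_2sd(g):
                assert g.mean_folded >= 1.5


class TestCompareMethodsRegression:
    def test_identity_data(self):
        pairs = [(x, x) for x in (0.1, 0.2, 0.3, 0.5)]
        fit = compare_methods_regression(pairs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.predicted_fold(3.0) == pytest.approx(3.0)

    def test_noise_free_exact_recovery(self):
        x = np.linspace(0.0, 0.7, 20)
        pairs = list(zip(x, 0.65 * x + 0.01))
        fit = compare_methods_regression(pairs)
        assert fit.slope == pytest.approx(0.65, abs=1e-12)
        assert fit.intercept == pytest.approx(0.01, abs=1e-12)

    def test_parameter_recovery_under_noise(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 0.8, size=500)
        y = 0.6 * x + rng.normal(0, 0.02, size=500)
        fit = compare_methods_regression(list(zip(x, y)))
        assert fit.slope == pytest.approx(0.6, abs=0.02)

    def test_predicted_fold_evaluates_the_line(self):
        fit = compare_methods_regression([(0.0, 0.0), (0.5, 0.3), (1.0, 0.6)])
        assert fit.predicted_fold(3.0) == pytest.approx(10 ** (0.6 * math.log10(3)))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_methods_regression([(0.2, 0.1), (0.2, 0.3), (0.2, 0.2)])
        with pytest.raises(ValueError):
            compare_methods_regression([(0.1, 0.2)])


def _logistic_panel(n, beta0=-2.0, beta1=3.0, seed=5):
    rng = np.random.default_rng(seed)
    logit_score = rng.exponential(0.5, size=n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * logit_score)))
    labels = rng.random(n) < p
    return pd.DataFrame({"logit_score": logit_score}), labels


class TestLogisticPredictor:
    def test_coefficient_recovery_within_two_se(self):
        features, labels = _logistic_panel(200)
        fit = logistic_aei_predictor(features, labels)
        assert not fit.separation
        est, se = fit.params["logit_score"], fit.bse["logit_score"]
        assert abs(est - 3.0) < 2 * se

    def test_all_labels_identical_is_degenerate(self):
        features, _ = _logistic_panel(50)
        with pytest.raises(ValueError, match="identical"):
            logistic_aei_predictor(features, np.ones(50, dtype=bool))

    def test_too_few_records_rejected(self):
        features, labels = _logistic_panel(8)
        with pytest.raises(ValueError):
            logistic_aei_predictor(features, labels)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        labels = x > 0.5
        fit = logistic_aei_predictor(pd.DataFrame({"logit_score": x}), labels)
        assert fit.separation
        assert fit.aic is None

    def test_aic_supports_model_comparison(self):
        features, labels = _logistic_panel(500, seed=9)
        rng = np.random.default_rng(10)
        features["noise"] = rng.normal(size=len(features))
        base = logistic_aei_predictor(features, labels, ["logit_score"])
        aug = logistic_aei_predictor(features, labels, ["logit_score", "noise"])
        assert base.aic is not None and aug.aic is not None
        # one useless covariate cannot beat the generating model by much
        assert aug.aic > base.aic - 2.0


class TestSnapshotNormalize:
    @pytest.mark.parametrize(
        "cdna, gdna, expected", [(2.0, 1.0, 2.0), (1.6, 0.8, 2.0), (1.0, 1.0, 1.0)]
    )
    def test_gdna_bias_cancels(self, cdna, gdna, expected):
        assert snapshot_normalize(cdna, gdna) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            snapshot_normalize(0.0, 1.0)
        with pytest.raises(ValueError):
            snapshot_normalize(1.0, -2.0)


def test_concordance_counts():
    a = [2.0, 1.8, 1.2, 1.0, 3.0]
    b = [1.7, 1.3, 1.1, 1.2, 2.5]
    both_above, n_above, both_below, n_below = concordance_counts(a, b)
    assert (both_above, n_above) == (2, 3)
    assert (both_below, n_below) == (2, 2)
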