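import itertools

import numpy as np
import pytest

from exomir import ContrastSpec
from exomir.errors import ValidationError
from exomir.preprocess import cpm_normalize
from exomir.univariate import (
    auroc,
    delong_ci,
    fit_logistic_univariate,
    loo_cv,
    predict_proba,
    roc_curve,
    univariate_panel,
)


class TestLogisticFit:
    def test_separable_input_flags_separation(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = (x > 0).astype(float)
        fit = fit_logistic_univariate(x, y)
        assert fit.slope > 0
        assert fit.separated

    def test_constant_predictor_collapses_to_base_rate(self):
        fit = fit_logistic_univariate([5, 5, 5, 5], [0, 1, 0, 1])
        assert fit.slope == 0.0
        assert fit.intercept == pytest.approx(0.0)
        assert not fit.separated

    def test_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(-1 + 2 * x)))
        y = (rng.uniform(size=2000) < p).astype(float)
        fit = fit_logistic_univariate(x, y)
        assert fit.intercept == pytest.approx(-1.0, abs=0.15)
        assert fit.slope == pytest.approx(2.0, abs=0.15)

    def test_matches_statsmodels_on_well_conditioned_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-x))).astype(float)
        fit = fit_logistic_univariate(x, y)
        ref = sm.GLM(y, np.column_stack([np.ones_like(x), x]),
                     family=sm.families.Binomial()).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic_univariate([1, 2, 3], [1, 1, 1])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 21))
            y = np.zeros(n)
            y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            scores = rng.integers(0, 6, size=n).astype(float)  # force ties
            pos = scores[y == 1]
            neg = scores[y == 0]
            oracle = np.mean(
                [(1.0 if a > b else 0.5 if a == b else 0.0)
                 for a, b in itertools.product(pos, neg)]
            )
            assert auroc(scores, y) == pytest.approx(oracle)

    def test_equals_trapezoid_area_under_roc(self, rng):
        scores = rng.normal(size=30)
        y = (rng.uniform(size=30) < 0.5).astype(float)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        curve = roc_curve(scores, y)
        area = np.trapezoid(curve.tpr, curve.fpr)
        assert auroc(scores, y) == pytest.approx(area)

    def test_logistic_fit_orients_the_score(self, rng):
        # in-sample LR probability AUROC = max(A, 1-A) of the raw predictor
        x = rng.normal(size=40)
        y = (rng.uniform(size=40) < 1 / (1 + np.exp(x))).astype(float)  # negative slope
        raw_a = auroc(x, y)
        fit = fit_logistic_univariate(x, y)
        model_a = auroc(predict_proba(fit, x), y)
        assert model_a == pytest.approx(max(raw_a, 1 - raw_a))


class TestDelongCi:
    def test_perfect_separation_gives_degenerate_interval(self):
        lo, hi = delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_clipped_to_unit_range(self, rng):
        pos = rng.normal(3, 1, size=8)
        neg = rng.normal(0, 1, size=8)
        lo, hi = delong_ci(np.r_[pos, neg], np.r_[np.ones(8), np.zeros(8)])
        assert 0.0 <= lo <= hi <= 1.0

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (10, 40, 160):
            w = []
            for _ in range(40):
                pos = rng.normal(1.19, 1, size=n)
                neg = rng.normal(0, 1, size=n)
                lo, hi = delong_ci(np.r_[pos, neg], np.r_[np.ones(n), np.zeros(n)])
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValidationError):
            delong_ci([1, 2, 3], [1, 0, 0])


class TestLooCv:
    def test_separable_clusters_have_zero_misclassification(self):
        x = np.array([1, 2, 3, 4, 11, 12, 13, 14], dtype=float)
        y = np.r_[np.zeros(4), np.ones(4)]
        cost, mis = loo_cv(x, y)
        assert mis == 0.0
        assert 0.0 <= cost <= 1.0

    def test_constant_predictor_closed_form(self):
        # each fold predicts the training base rate: (y - p_hat)^2 = 16/49
        cost, mis = loo_cv(np.full(8, 5.0), np.array([0, 1] * 4, dtype=float))
        assert cost == pytest.approx(16 / 49)
        assert mis == 1.0  # every held-out sample sits on the wrong side

    def test_needs_at_least_four_samples(self):
        with pytest.raises(ValidationError):
            loo_cv([1, 2, 3], [0, 1, 0])


class TestUnivariatePanel:
    def test_panel_on_planted_cohort(self, default_cohort, gbm_hc_contrast):
        matrix, meta, truth = default_cohort
        expr = cpm_normalize(matrix)
        strong = [f"mir_{i:04d}" for i, fc in truth.signed_fc.items() if fc == 3.0]
        weak_null = [m for m in matrix.mirna_ids
                     if int(m.split("_")[1]) not in truth.de_index_set][:3]
        records = univariate_panel(expr, meta, strong + weak_null, gbm_hc_contrast)
        assert [r.mirna_id for r in records] == strong + weak_null  # order kept
        by_id = {r.mirna_id: r for r in records}
        for mid in strong:
            assert by_id[mid].auroc >= 0.9
        for r in records:
            assert 0 <= r.ci_low <= r.auroc <= r.ci_high <= 1
            assert 0 <= r.loo_cost <= 1

    def test_unknown_id_named_in_error(self, default_cohort, gbm_hc_contrast):
        matrix, meta, _ = default_cohort
        expr = cpm_normalize(matrix)
        with pytest.raises(ValidationError, match="mir_nope"):
            univariate_panel(expr, meta, ["mir_nope"], gbm_hc_contrast)

    def test_null_mirna_ci_usually_covers_half(self, gbm_hc_contrast):
        from exomir import generate_counts, null_design

        covered = 0
        reps = 40
        for s in range(reps):
            m, meta, _ = generate_counts(null_design(seed=1000 + s, n_mirna=5))
            expr = cpm_normalize(m)
            rec = univariate_panel(expr, meta, [m.mirna_ids[0]], gbm_hc_contrast)[0]
            covered += rec.ci_low <= 0.5 <= rec.ci_high
        assert covered / reps >= 0.9
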