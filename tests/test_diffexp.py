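import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exomir import (
    ContrastSpec,
    SyntheticDesign,
    generate_counts,
    run_contrast,
)
from exomir.diffexp import (
    bh_adjust,
    estimate_common_dispersion,
    nb_exact_test,
    signed_fold_change,
    student_t_test,
    wilcoxon_rank_sum,
)
from exomir.errors import ValidationError
from exomir.io import CountMatrix


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "case_mean, control_mean, expected_display",
        [
            (25291.6, 8522.6, 3.0),
            (223.1, 753.2, -3.3),
            (73535.3, 142796.9, -2.0),
            (90.1, 234.8, -2.5),
        ],
    )
    def test_display_convention(self, case_mean, control_mean, expected_display):
        ratio, display = signed_fold_change(case_mean, control_mean)
        assert display == expected_display
        assert ratio == pytest.approx(case_mean / control_mean)

    def test_identity(self):
        ratio, display = signed_fold_change(7.0, 7.0)
        assert ratio == 1.0 and display == 1.0

    def test_zero_mean_instructs_pseudo_offset(self):
        with pytest.raises(ValidationError, match="pseudo-offset"):
            signed_fold_change(0.0, 5.0)

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_display_never_in_open_unit_interval(self, ratio):
        _, display = signed_fold_change(ratio * 10.0, 10.0)
        assert display >= 1.0 or display <= -1.0


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all 3 ranks extreme: 2 of C(6,3)=20 assignments as extreme, x2 sided
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=0.05)

    def test_all_identical_values_warn(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_rank_sum([5, 5], [5, 5]) == 1.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=6) + 0.5
        p0 = wilcoxon_rank_sum(x, y)
        assert wilcoxon_rank_sum(np.exp(x), np.exp(y)) == pytest.approx(p0)
        assert wilcoxon_rank_sum(3 * x + 1, 3 * y + 1) == pytest.approx(p0)

    def test_exact_matches_full_enumeration(self, rng):
        # independent oracle: enumerate every case/control rank assignment
        for n1, n2 in [(3, 4), (4, 4), (5, 5)]:
            pooled = rng.permutation(rng.normal(size=n1 + n2) * 10)
            x, y = pooled[:n1], pooled[n1:]
            p = wilcoxon_rank_sum(x, y)
            ranks = stats.rankdata(pooled)
            u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            mid = n1 * n2 / 2
            count = 0
            total = 0
            for combo in itertools.combinations(range(n1 + n2), n1):
                u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
                total += 1
                if abs(u - mid) >= abs(u_obs - mid) - 1e-9:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-9)


class TestStudentT:
    def test_identical_groups_p_one(self):
        assert student_t_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning):
            assert student_t_test([0, 0], [1, 1]) == 0.0

    def test_matches_pooled_closed_form_and_scipy(self):
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        p = student_t_test(x, y)
        # hand computation: sp2 = 5/3, t = -1/sqrt(sp2/2), df = 6
        t_hand = -1.0 / math.sqrt((5 / 3) / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), 6)
        assert t_hand == pytest.approx(-1.0954, abs=1e-4)
        assert p == pytest.approx(p_hand)
        assert p == pytest.approx(stats.ttest_ind(x, y, equal_var=True).pvalue)


class TestDispersion:
    def _phi_hat(self, dispersion, seed=7):
        d = SyntheticDesign(
            n_case=12, n_control=12, n_mirna=500, dispersion=dispersion, seed=seed
        )
        m, meta, _ = generate_counts(d)
        return estimate_common_dispersion(m, [r.group for r in meta]).phi

    def test_poisson_counts_give_near_zero(self):
        assert self._phi_hat(0.0) <= 0.02

    def test_nb_dispersion_recovered(self):
        assert 0.1 <= self._phi_hat(0.2) <= 0.3

    def test_constant_counts_contribute_zero(self):
        m = CountMatrix.from_counts(
            ["mA"], [f"s{j}" for j in range(6)], np.full((1, 6), 40)
        )
        est = estimate_common_dispersion(m, ["a", "a", "a", "b", "b", "b"])
        assert est.phi == 0.0

    def test_single_sample_group_rejected(self):
        m = CountMatrix.from_counts(["mA"], ["s0", "s1"], np.array([[1, 2]]))
        with pytest.raises(ValidationError):
            estimate_common_dispersion(m, ["a", "b"])


class TestNbExactTest:
    def test_poisson_limit_one_vs_one(self):
        p = nb_exact_test([0], [10], [1000, 1000], phi=0.0)
        assert p == pytest.approx(2 * 0.5**10)

    def test_identical_vectors_give_p_one(self):
        p = nb_exact_test([3, 4, 5], [3, 4, 5], [100] * 6, phi=0.2)
        assert p == pytest.approx(1.0)

    def test_phi_zero_matches_conditional_binomial_oracle(self, rng):
        from scipy.stats import binom

        for _ in range(100):
            n1, n2 = rng.integers(1, 5, size=2)
            total = int(rng.integers(1, 51))
            s1 = int(rng.integers(0, total + 1))
            case = np.zeros(n1, dtype=int)
            case[0] = s1
            ctrl = np.zeros(n2, dtype=int)
            ctrl[0] = total - s1
            p = nb_exact_test(case, ctrl, np.full(n1 + n2, 500.0), phi=0.0)
            pmf = binom.pmf(np.arange(total + 1), total, n1 / (n1 + n2))
            oracle = pmf[pmf <= pmf[s1] * (1 + 1e-12)].sum()
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValidationError):
            nb_exact_test([1.5], [2], [10, 10], phi=0.1)
        with pytest.raises(ValidationError):
            nb_exact_test([1], [2], [10, 10], phi=-0.1)

    def test_large_total_beta_limit_close_to_enumeration(self):
        from scipy.special import logsumexp
        from scipy.stats import betabinom

        s_total, s1 = 30_000, 12_600
        r1 = r2 = 12 / 0.15
        lp = betabinom.logpmf(np.arange(s_total + 1), s_total, r1, r2)
        exact = float(np.exp(logsumexp(lp[lp <= lp[s1] + 1e-8 * abs(lp[s1])])))
        case = np.zeros(12, dtype=int)
        case[0] = s1
        ctrl = np.zeros(12, dtype=int)
        ctrl[0] = s_total - s1
        approx = nb_exact_test(case, ctrl, np.full(24, 1e6), phi=0.15)
        assert approx == pytest.approx(exact, rel=0.05)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_q_dominates_p_and_is_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestRunContrast:
    def test_consensus_rule_and_threshold_monotonicity(self, default_cohort):
        matrix, meta, _ = default_cohort
        loose = run_contrast(matrix, meta, ContrastSpec("GBM", "HC", 2.0, 0.05))
        tight_fc = run_contrast(matrix, meta, ContrastSpec("GBM", "HC", 2.5, 0.05))
        tight_p = run_contrast(matrix, meta, ContrastSpec("GBM", "HC", 2.0, 0.01))
        sel = lambda recs: {r.mirna_id for r in recs if r.consensus}
        assert sel(tight_fc) <= sel(loose)
        assert sel(tight_p) <= sel(loose)

    def test_consensus_requires_all_three_tests(self, default_de_records):
        for r in default_de_records:
            fc_pass = r.ratio >= 2.0 or r.ratio <= 0.5
            expected = fc_pass and max(r.p_exact, r.p_t, r.p_wilcoxon) <= 0.05
            assert r.consensus == expected
            for p, q in [(r.p_exact, r.q_exact), (r.p_t, r.q_t),
                         (r.p_wilcoxon, r.q_wilcoxon)]:
                assert q >= p - 1e-12 and q <= 1.0

    def test_non_raw_matrix_disables_exact_test(self, default_cohort):
        matrix, meta, _ = default_cohort
        soft = CountMatrix(
            matrix.mirna_ids, matrix.sample_ids,
            matrix.counts * 1.0, matrix.library_sizes, is_raw=False,
        )
        records = run_contrast(soft, meta, ContrastSpec("GBM", "HC"))
        assert all(math.isnan(r.p_exact) for r in records)
        assert any(r.consensus for r in records)  # two-test consensus still runs

    def test_small_group_rejected(self, default_cohort):
        matrix, meta, _ = default_cohort
        tiny_meta = [r for r in meta if r.sample_id in ("GBM_01", "HC_01", "HC_02")]
        with pytest.raises(ValidationError):
            run_contrast(matrix.subset_samples([r.sample_id for r in tiny_meta]),
                         tiny_meta, ContrastSpec("GBM", "HC"))
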