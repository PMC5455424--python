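"""Conditional-logit estimation, IQ-OR, concordance, interactions, independence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from conftest import simulate_conditional_sets
from prsmatch.matched import (
    ConditionalLogit,
    MatchedSet,
    Subject,
    bivariable_fit,
    interaction_test,
    matched_concordance,
    matched_sets_from_dataframe,
    spearman_independence,
)


def three_pair_data():
    # within-pair differences (case - control): +1, +1, -1
    X = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
    case = np.array([1, 0, 1, 0, 1, 0], dtype=bool)
    sid = np.array([1, 1, 2, 2, 3, 3])
    return X, case, sid


class TestConditionalLogit:
    def test_three_pair_closed_form(self):
        """Score equation (2 - e^b)/(1 + e^b) = 0 has root b = ln 2."""
        X, case, sid = three_pair_data()
        res = ConditionalLogit(X, case, sid).fit()
        assert res.converged
        assert res.params[0] == pytest.approx(np.log(2.0), abs=1e-8)
        # grid-maximization oracle
        grid = np.linspace(-2, 2, 40001)
        ll = 2 * (grid - np.logaddexp(0, grid)) + (0 - np.logaddexp(0, grid))
        assert grid[np.argmax(ll)] == pytest.approx(np.log(2.0), abs=1e-4)

    def test_flat_likelihood_canonical_root(self):
        X = np.array([1.0, 1.0, 2.0, 2.0, 2.0])
        case = np.array([1, 0, 1, 0, 0], dtype=bool)
        sid = np.array([1, 1, 2, 2, 2])
        with pytest.warns(UserWarning, match="flat"):
            res = ConditionalLogit(X, case, sid).fit()
        assert res.params[0] == 0.0
        assert res.llf == pytest.approx(-(np.log(2) + np.log(3)))

    def test_one_to_one_equals_difference_regression(self, rng):
        """1:1 clogit is intercept-free binary regression on pair differences."""
        X, case, sid = simulate_conditional_sets(rng, 500, 2, beta=0.8)
        res = ConditionalLogit(X, case, sid).fit()

        d = X[case, 0] - X[~case, 0]  # case minus control within pair

        def neg_ll(b):
            return -(np.sum(b * d - np.logaddexp(0.0, b * d)))

        oracle = optimize.minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded",
                                          options={"xatol": 1e-12})
        assert res.params[0] == pytest.approx(oracle.x, abs=1e-6)

    def test_matches_statsmodels_on_1to2_sets(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit as SmCL

        X, case, sid = simulate_conditional_sets(rng, 300, 3, beta=[0.6, -0.4], n_cov=2)
        res = ConditionalLogit(X, case, sid).fit()
        sm_res = SmCL(case.astype(int), X, groups=sid).fit(disp=False)
        assert res.params == pytest.approx(np.asarray(sm_res.params), abs=5e-4)
        assert res.bse == pytest.approx(np.asarray(sm_res.bse), rel=1e-3)
        # Newton lands at least as high on the likelihood as the reference
        assert res.llf >= sm_res.llf - 1e-8
        assert res.llf == pytest.approx(sm_res.llf, abs=1e-5)

    def test_set_level_shift_invariance(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 200, 3, beta=0.5)
        res1 = ConditionalLogit(X, case, sid).fit()
        shifts = rng.normal(scale=5, size=200)[sid]
        res2 = ConditionalLogit(X[:, 0] + shifts, case, sid).fit()
        assert res2.params[0] == pytest.approx(res1.params[0], abs=1e-6)
        assert res2.llf == pytest.approx(res1.llf, abs=1e-8)

    def test_set_level_covariate_rejected(self):
        X, case, sid = three_pair_data()
        arm = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0])  # constant within sets
        with pytest.raises(ValueError, match="within-set variation"):
            ConditionalLogit(np.column_stack([X, arm]), case, sid,
                             names=["x", "arm"])

    def test_separation_reported_not_truncated(self):
        # case always has the strictly larger covariate -> monotone likelihood
        X = np.array([1.0, 0.0] * 30)
        case = np.array([1, 0] * 30, dtype=bool)
        sid = np.repeat(np.arange(30), 2)
        with pytest.warns(UserWarning, match="separation"):
            res = ConditionalLogit(X, case, sid).fit()
        assert not res.converged
        assert res.separated

    def test_two_cases_in_set_rejected(self):
        with pytest.raises(ValueError, match="exactly one case"):
            ConditionalLogit([1.0, 2.0], [True, True], [1, 1])

    def test_wald_size_under_null(self, rng):
        """Type-I error of the Wald test is ~5% over null replicates."""
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            X, case, sid = simulate_conditional_sets(rng, 300, 3, beta=0.0)
            res = ConditionalLogit(X, case, sid).fit()
            rejections += res.pvalues[0] < 0.05
        rate = rejections / n_reps
        tol = 3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert rate == pytest.approx(0.05, abs=tol)

    def test_ci_coverage_at_true_beta(self, rng):
        beta_true = 0.7
        covered = 0
        n_reps = 200
        for _ in range(n_reps):
            X, case, sid = simulate_conditional_sets(rng, 250, 3, beta=beta_true)
            res = ConditionalLogit(X, case, sid).fit()
            lo, hi = res.conf_int()[0]
            covered += lo <= beta_true <= hi
        assert 0.90 <= covered / n_reps <= 0.995


class TestIqOr:
    def test_null_coefficient_gives_unity(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 50, 2, beta=0.0)
        res = ConditionalLogit(X, case, sid).fit()
        res.params[0] = 0.0
        assert res.iq_or(X[~case, 0]).estimate == pytest.approx(1.0)

    def test_formula_example(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 50, 2, beta=0.5)
        res = ConditionalLogit(X, case, sid).fit()
        res.params[0] = 1.5
        res.cov[0, 0] = 0.4**2
        # control quartiles forced to -0.2 and 0.3 via a crafted vector
        vals = np.array([-0.2, -0.2, -0.2, 0.3, 0.3, 0.3])
        iq = res.iq_or(vals)
        assert iq.iqr == pytest.approx(0.5)
        assert iq.estimate == pytest.approx(np.exp(0.75), abs=1e-9)
        assert iq.ci_low == pytest.approx(np.exp(0.5 * (1.5 - 1.96 * 0.4)), rel=1e-3)
        assert iq.ci_high == pytest.approx(np.exp(0.5 * (1.5 + 1.96 * 0.4)), rel=1e-3)
        assert (round(iq.estimate, 3), round(iq.ci_low, 2), round(iq.ci_high, 2)) == (
            2.117, 1.43, 3.13)

    def test_location_invariance(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 300, 3, beta=0.6)
        res1 = ConditionalLogit(X, case, sid).fit()
        iq1 = res1.iq_or(X[~case, 0])
        res2 = ConditionalLogit(X + np.log(2), case, sid).fit()
        iq2 = res2.iq_or(X[~case, 0] + np.log(2))
        assert iq2.estimate == pytest.approx(iq1.estimate, rel=1e-6)

    def test_degenerate_iqr_warns(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 50, 2, beta=0.2)
        res = ConditionalLogit(X, case, sid).fit()
        with pytest.warns(UserWarning, match="degenerate"):
            iq = res.iq_or(np.ones(10))
        assert iq.estimate == 1.0


class TestMatchedConcordance:
    def test_case_always_highest(self):
        sid = [1, 1, 1, 2, 2]
        case = [True, False, False, True, False]
        score = [5.0, 1.0, 2.0, 9.0, 3.0]
        assert matched_concordance(sid, case, score) == 1.0

    def test_all_ties(self):
        assert matched_concordance([1, 1, 2, 2], [True, False, True, False],
                                   [1.0, 1.0, 1.0, 1.0]) == 0.5

    def test_worked_example(self):
        sid = [1, 1, 1, 2, 2]
        case = [True, False, False, True, False]
        score = [2.0, 1.0, 3.0, 5.0, 4.0]
        assert matched_concordance(sid, case, score) == pytest.approx(2.0 / 3.0)

    @settings(max_examples=300, deadline=None)
    @given(data=st.data())
    def test_brute_force_pair_counting(self, data):
        n_sets = data.draw(st.integers(1, 6))
        scores = []
        sid, case = [], []
        for s in range(n_sets):
            m = data.draw(st.integers(1, 4))
            vals = data.draw(
                st.lists(st.integers(0, 5), min_size=m + 1, max_size=m + 1)
            )
            sid += [s] * (m + 1)
            case += [True] + [False] * m
            scores += vals
        expected_num = expected_den = 0.0
        for s in range(n_sets):
            idx = [i for i, v in enumerate(sid) if v == s]
            c = scores[idx[0]]
            for i in idx[1:]:
                expected_den += 1
                if scores[i] < c:
                    expected_num += 1
                elif scores[i] == c:
                    expected_num += 0.5
        got = matched_concordance(sid, case, [float(v) for v in scores])
        assert got == pytest.approx(expected_num / expected_den)

    def test_per_set_average_variant(self):
        sid = [1, 1, 1, 2, 2]
        case = [True, False, False, True, False]
        score = [2.0, 1.0, 3.0, 5.0, 4.0]
        assert matched_concordance(sid, case, score, per_set_average=True) == pytest.approx(0.75)


class TestInteraction:
    def test_duplicated_groups_give_zero_interaction(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 150, 3, beta=0.5)
        X2 = np.concatenate([X[:, 0], X[:, 0]])
        case2 = np.concatenate([case, case])
        sid2 = np.concatenate([sid, sid + 1000])
        group = np.concatenate([np.zeros(case.size), np.ones(case.size)])
        it = interaction_test(X2, group, sid2, case2)
        assert it.beta_interaction == pytest.approx(0.0, abs=1e-6)

    def test_recovers_group_difference(self, rng):
        # effect 0.9 in group B only
        Xa, ca, sa = simulate_conditional_sets(rng, 400, 3, beta=0.0)
        Xb, cb, sb = simulate_conditional_sets(rng, 400, 3, beta=0.9)
        X = np.concatenate([Xa[:, 0], Xb[:, 0]])
        case = np.concatenate([ca, cb])
        sid = np.concatenate([sa, sb + 10_000])
        group = np.repeat(["A", "B"], ca.size)
        it = interaction_test(X, group, sid, case)
        se = it.se_interaction
        assert it.beta_interaction == pytest.approx(0.9, abs=3 * se)

    def test_single_level_rejected(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 20, 2, beta=0.1)
        with pytest.raises(ValueError, match="2 levels"):
            interaction_test(X[:, 0], np.zeros(case.size), sid, case)

    def test_null_rejection_rate(self, rng):
        """p_het is uniform when both groups share the true effect."""
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            Xa, ca, sa = simulate_conditional_sets(rng, 100, 3, beta=0.5)
            Xb, cb, sb = simulate_conditional_sets(rng, 100, 2, beta=0.5)
            X = np.concatenate([Xa[:, 0], Xb[:, 0]])
            case = np.concatenate([ca, cb])
            sid = np.concatenate([sa, sb + 10_000])
            group = np.concatenate([np.zeros(ca.size), np.ones(cb.size)])
            rejections += interaction_test(X, group, sid, case).p_het < 0.05
        rate = rejections / n_reps
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_reps))


class TestBivariable:
    def test_combined_close_to_full_for_unit_coefficients(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 800, 3, beta=[1.0, 1.0], n_cov=2)
        bi = bivariable_fit(X[:, 0], X[:, 1], sid, case)
        assert bi.chi2_two >= bi.chi2_combined - 1e-9
        # the 1-df product-score fit captures nearly all of the 2-df fit
        assert bi.chi2_two - bi.chi2_combined < 6.0

    def test_constant_second_covariate_reduces_to_univariable(self, rng):
        X, case, sid = simulate_conditional_sets(rng, 200, 3, beta=0.5)
        uni = ConditionalLogit(X[:, 0], case, sid).fit()
        shifts = np.ones(case.size) * 0.3  # set-level constant
        with pytest.raises(ValueError, match="within-set variation"):
            bivariable_fit(X[:, 0], shifts, sid, case)
        # combining with a constant changes nothing in the 1-parameter fit
        bi_comb = ConditionalLogit(X[:, 0] + shifts, case, sid).fit()
        assert bi_comb.params[0] == pytest.approx(uni.params[0], abs=1e-8)

    def test_null_chi2_mean_matches_df(self, rng):
        chi2_two, chi2_one = [], []
        for _ in range(150):
            X, case, sid = simulate_conditional_sets(rng, 120, 3, beta=[0.0, 0.0], n_cov=2)
            bi = bivariable_fit(X[:, 0], X[:, 1], sid, case)
            chi2_two.append(bi.chi2_two)
            chi2_one.append(bi.chi2_combined)
        assert np.mean(chi2_two) == pytest.approx(2.0, abs=0.5)
        assert np.mean(chi2_one) == pytest.approx(1.0, abs=0.35)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(12.0)
        assert spearman_independence(x, x)[0] == pytest.approx(1.0)
        assert spearman_independence(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self, rng):
        hits = 0
        for _ in range(40):
            x, y = rng.normal(size=600), rng.normal(size=600)
            rho, _ = spearman_independence(x, y)
            hits += abs(rho) < 0.1
        assert hits >= 38  # |rho| < 0.1 in ~99% of replicates at n=600

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_independence(np.ones(12), np.arange(12.0))


class TestMatchedSetContainer:
    def test_dataframe_round_trip_and_invariants(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d", "e"],
                "set_id": ["s1", "s1", "s1", "s2", "s2"],
                "is_case": [True, False, False, True, False],
                "trial": ["t"] * 5,
                "arm": ["placebo"] * 3 + ["tamoxifen"] * 2,
                "age_entry": [50.0, 51.0, 49.0, 60.0, 59.0],
            }
        )
        sets = matched_sets_from_dataframe(df)
        assert [s.size for s in sets] == [3, 2]
        with pytest.raises(ValueError, match="trial/arm"):
            MatchedSet(
                "x",
                Subject("a", "x", True, trial="t1", arm="placebo"),
                (Subject("b", "x", False, trial="t2", arm="placebo"),),
            )
        with pytest.raises(ValueError, match="exactly one case"):
            matched_sets_from_dataframe(df.assign(is_case=[True, True, False, True, False]))
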