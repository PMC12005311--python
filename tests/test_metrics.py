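import numpy as np
import pandas as pd
import pytest

from fibrodefer.metrics import (
    InsufficientDataError, apri, deferral_audit, delong_compare,
    empirical_auc, fib4, matched_op_comparison, obuchowski_compare,
    obuchowski_index, render_rate, round_half_up, sens_spec,
)


def brute_force_auc(scores, truth):
    """Oracle: enumerate all positive/negative pairs, ties count one half."""
    pos = scores[truth.astype(bool)]
    neg = scores[~truth.astype(bool)]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example(self):
        assert empirical_auc([0.8, 0.6, 0.4, 0.7], [1, 1, 0, 0]) == 0.75

    def test_perfect_separation(self):
        assert empirical_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_pair_enumeration_and_sklearn(self, n):
        rng = np.random.default_rng(n)
        scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
        truth = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            truth[0] = 1 - truth[0]
        ours = empirical_auc(scores, truth)
        assert ours == pytest.approx(brute_force_auc(scores, truth), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert ours == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(InsufficientDataError):
            empirical_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores_give_null_result(self):
        s = [0.1, 0.8, 0.4, 0.9, 0.3]
        t = [0, 1, 0, 1, 1]
        z, p = delong_compare(s, s, t)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(60), rng.random(60)
        t = rng.integers(0, 2, 60)
        z1, p1 = delong_compare(a, b, t)
        z2, p2 = delong_compare(b, a, t)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 2, 300)
        good = t + rng.normal(0, 0.3, 300)
        junk = rng.random(300)
        z, p = delong_compare(good, junk, t)
        assert z > 3 and p < 0.01


class TestObuchowski:
    def test_binary_truth_reduces_to_auc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.random(n)
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                truth[0] = 1 - truth[0]
            rep = obuchowski_index(scores, truth, ci=None)
            assert rep.estimate == pytest.approx(
                empirical_auc(scores, truth), abs=1e-15
            )

    def test_three_category_worked_example(self):
        scores = np.array([0.1, 0.3, 0.3, 0.5])
        truth = np.array([0, 0, 1, 2])
        rep = obuchowski_index(scores, truth, weighting="equal", ci=None)
        assert rep.estimate == pytest.approx(11 / 12)

    def test_stage_monotone_scores_give_one(self):
        truth = np.repeat([0, 1, 2, 3, 4], 6)
        scores = truth * 2.0 + 1.0
        assert obuchowski_index(scores, truth, ci=None).estimate == 1.0

    def test_prevalence_weighting_matches_manual(self):
        scores = np.array([0.1, 0.3, 0.3, 0.5])
        truth = np.array([0, 0, 1, 2])
        # weights 2*1, 2*1, 1*1 on pairwise AUCs 0.75, 1, 1
        expected = (2 * 0.75 + 2 * 1 + 1 * 1) / 5
        rep = obuchowski_index(scores, truth, weighting="prevalence", ci=None)
        assert rep.estimate == pytest.approx(expected)

    def test_jackknife_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 5, 120)
        scores = truth + rng.normal(0, 1.0, 120)
        rep = obuchowski_index(scores, truth)
        lo, hi = rep.ci
        assert lo <= rep.estimate <= hi and 0 <= lo and hi <= 1

    def test_single_category_errors(self):
        with pytest.raises(InsufficientDataError):
            obuchowski_index([0.1, 0.2], [2, 2], ci=None)

    def test_difference_test_null_on_identical_measures(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 3, 80)
        scores = truth + rng.normal(0, 0.8, 80)
        res = obuchowski_compare(scores, scores, truth)
        assert res["difference"] == 0.0 and res["p"] == 1.0

    def test_difference_permutation_agrees_in_direction(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 3, 90)
        good = truth + rng.normal(0, 0.5, 90)
        junk = rng.random(90)
        jack = obuchowski_compare(good, junk, truth)
        perm = obuchowski_compare(good, junk, truth, method="permutation", B=300)
        assert jack["p"] < 0.05 and perm["p"] < 0.05

    def test_equivalence_requires_margin(self):
        with pytest.raises(ValueError):
            obuchowski_compare([1, 2, 3], [1, 2, 3], [0, 1, 2], mode="equivalence")

    def test_equivalence_tost_on_near_identical_measures(self):
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 3, 150)
        a = truth + rng.normal(0, 0.5, 150)
        b = a + rng.normal(0, 0.02, 150)
        res = obuchowski_compare(a, b, truth, mode="equivalence", margin=0.05)
        assert res["p"] == max(res["p_lower"], res["p_upper"])
        assert res["equivalent"]


class TestSensSpec:
    def test_printed_fraction_rendering(self):
        # 74/94 prints 0.79; 33/36 prints 0.92
        assert render_rate(74, 94) == "0.79"
        assert render_rate(33, 36) == "0.92"

    def test_point_estimates_and_counts(self):
        truth = np.array([1] * 94 + [0] * 36)
        calls = np.array([1] * 74 + [0] * 20 + [0] * 33 + [1] * 3)
        s, p = sens_spec(calls, truth, ci_method="none")
        assert s.estimate == pytest.approx(74 / 94)
        assert (s.extra["numerator"], s.extra["denominator"]) == (74, 94)
        assert p.estimate == pytest.approx(33 / 36)

    def test_degenerate_class_ci_collapses(self):
        truth = np.ones(20, dtype=bool)
        s, _ = sens_spec(np.ones(20, dtype=bool), truth, B=200, seed=0)
        assert s.estimate == 1.0 and s.ci == (1.0, 1.0)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 150).astype(bool)
        calls = truth ^ (rng.random(150) < 0.2)
        s, p = sens_spec(calls, truth, B=500, seed=1)
        assert s.ci[0] <= s.estimate <= s.ci[1]
        assert p.ci[0] <= p.estimate <= p.ci[1]

    def test_half_up_rounding(self):
        assert round_half_up(0.785, 2) == 0.79
        assert round_half_up(0.625, 2) == 0.63
        assert round_half_up(81.25, 1) == 81.3


class TestMatchedOP:
    def test_zero_reference_sensitivity_maximises_specificity(self):
        truth = np.array([1, 1, 0, 0, 0])
        ref = np.zeros(5, dtype=bool)  # sens 0
        scores = np.array([0.9, 0.8, 0.3, 0.2, 0.1])
        res = matched_op_comparison(ref, scores, truth, fix="sensitivity")
        assert res["feasible"] and res["specificity"] == 1.0

    def test_self_comparison_delta_nonnegative(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 2, 100)
        scores = truth + rng.normal(0, 0.7, 100)
        ref = scores > 0.5
        for fix in ("sensitivity", "specificity"):
            res = matched_op_comparison(ref, scores, truth, fix=fix)
            assert res["feasible"] and res["delta"] >= -1e-12

    def test_matches_exhaustive_search(self):
        truth = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.6, 0.4, 0.5, 0.3, 0.1])
        ref = np.array([1, 1, 0, 1, 0, 0], dtype=bool)  # sens 2/3, spec 2/3
        res = matched_op_comparison(ref, scores, truth, fix="sensitivity")
        # exhaustive: thresholds giving sens >= 2/3 and max spec
        best = (-1, None)
        for thr in np.concatenate([[-np.inf], np.unique(scores)]):
            calls = scores > thr
            sens = calls[truth == 1].mean()
            spec = (~calls[truth == 0]).mean()
            if sens >= 2 / 3 and spec > best[0]:
                best = (spec, thr)
        assert res["specificity"] == pytest.approx(best[0])

    def test_infeasible_reported_not_raised(self):
        truth = np.array([1, 1, 0, 0])
        ref = np.array([1, 1, 0, 0], dtype=bool)  # sens 1, spec 1
        scores = np.array([0.1, 0.2, 0.8, 0.9])   # inverted candidate
        res = matched_op_comparison(ref, scores, truth, fix="sensitivity")
        assert res["feasible"] is False or res["delta"] <= 0


class TestDeferralAudit:
    @staticmethod
    def _log(y_hat, decision, final):
        return pd.DataFrame({
            "case_id": range(len(y_hat)), "y_hat": y_hat,
            "routed": "", "advantages": "", "decision": decision,
            "final_stage": final,
        })

    def test_no_deferrals_is_full_adoption(self):
        log = self._log([1, 2], ["adopt_ai", "adopt_ai"], [1, 2])
        audit = deferral_audit(log, [1, 2])
        assert audit == {"n": 2, "n_deferred": 0, "n_positive_impact": 0,
                         "adoption_pct": 100.0}

    def test_positive_impact_reader_corrects_ai(self):
        # AI S2, reader S4, truth S4 -> positive
        log = self._log([2], ["defer"], [4])
        assert deferral_audit(log, [4])["n_positive_impact"] == 1

    def test_reader_farther_from_truth_not_positive(self):
        # AI S3, reader S1, truth S4 -> |1-4| > |3-4|
        log = self._log([3], ["defer"], [1])
        assert deferral_audit(log, [4])["n_positive_impact"] == 0

    def test_equal_distance_tie_not_positive(self):
        # AI S3, reader S1, truth S2: both distance 1, reader wrong -> no
        log = self._log([3], ["defer"], [1])
        assert deferral_audit(log, [2])["n_positive_impact"] == 0

    def test_adoption_percentage_rounding(self):
        n, d = 192, 36
        log = self._log([0] * n, ["defer"] * d + ["adopt_ai"] * (n - d), [0] * n)
        assert deferral_audit(log, [0] * n)["adoption_pct"] == 81.3

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            deferral_audit(self._log([0], ["adopt_ai"], [0]), [0, 1])


class TestSerumMarkers:
    def test_apri_arithmetic(self):
        assert apri(40, 100) == pytest.approx(0.4)
        assert apri(0, 100) == 0.0

    def test_fib4_arithmetic(self):
        assert fib4(60, 40, 100, 25) == pytest.approx(4.8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            apri(40, 0)
        with pytest.raises(ValueError):
            fib4(60, 40, 100, 0)

    def test_vectorised_over_cohort(self, small_cohort):
        a = apri(small_cohort["ast"], small_cohort["plt"])
        f = fib4(small_cohort["age"], small_cohort["ast"],
                 small_cohort["plt"], small_cohort["alt"])
        assert a.shape == f.shape == (len(small_cohort),)
        assert np.all(a > 0) and np.all(f > 0)
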