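import itertools

import numpy as np
import pandas as pd
import pytest

from hepaplan._exceptions import ValidationError
from hepaplan import risk_stats
from hepaplan.risk_stats import (
    auroc,
    collinearity_check,
    delong_test,
    rank_sum_test,
    rank_tests,
    stepwise_logistic_aic,
    youden_threshold,
)


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: ties score one half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = (-2.0, -1.0)
    for thr in np.concatenate([scores - 1e-9, scores + 1e-9,
                               [scores.min() - 1, scores.max() + 1]]):
        pred = scores >= thr
        sens = pred[labels].mean()
        spec = (~pred[~labels]).mean()
        best = max(best, (sens + spec - 1.0, spec))
    return best


class TestAuroc:
    def test_perfect_separation(self):
        res = auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_three_vs_three_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.7]
        labels = [0, 0, 0, 1, 1, 1]
        res = auroc(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_null_simulation(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.random(1000) < 0.5
        assert abs(auroc(scores, labels).auc - 0.5) < 0.05

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        a1 = auroc(scores, labels).auc
        a2 = auroc(np.exp(3 * scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([1, 2, 3], [1, 1, 1])

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(size=80) + rng.random(80)
        labels = rng.random(80) < 0.3
        res = auroc(scores, labels)
        assert res.ci_lo <= res.auc <= res.ci_hi
        assert 0.0 <= res.ci_lo and res.ci_hi <= 1.0


class TestYouden:
    def test_perfect_separation(self):
        res = youden_threshold([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.youden_j == pytest.approx(1.0)
        assert 3 < res.threshold < 10

    def test_toy_six_scores_brute_force(self):
        scores = [0.2, 0.3, 0.5, 0.5, 0.7, 0.9]
        labels = [0, 0, 1, 0, 1, 1]
        res = youden_threshold(scores, labels)
        j_best, spec_best = brute_force_youden(scores, labels)
        assert res.youden_j == pytest.approx(j_best, abs=1e-12)
        assert res.specificity == pytest.approx(spec_best, abs=1e-12)

    def test_all_equal_scores(self):
        res = youden_threshold([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.youden_j == pytest.approx(0.0)

    def test_random_sets_match_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = youden_threshold(scores, labels)
            j_best, _ = brute_force_youden(scores, labels)
            assert res.youden_j == pytest.approx(j_best, abs=1e-12)


class TestDeLong:
    def test_identical_scores(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        res = delong_test(scores, scores.copy(), labels)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_monotone_equivalent_scores(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        res = delong_test(scores, np.exp(scores), labels)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_informative_vs_noise(self, rng):
        n = 400
        labels = rng.random(n) < 0.5
        good = labels + 0.5 * rng.normal(size=n)
        noise = rng.normal(size=n)
        res = delong_test(good, noise, labels)
        assert res.p < 0.01
        assert res.auc_a > res.auc_b

    def test_mismatched_lengths(self, rng):
        with pytest.raises(ValidationError):
            delong_test([1, 2, 3], [1, 2], [0, 1, 1])


class TestStepwise:
    def test_null_predictor_rarely_selected(self, rng):
        # AIC admits a pure-noise term iff its LR statistic exceeds 2, which
        # under the null happens with P(chi2_1 > 2) ~ 0.157
        picked = 0
        reps = 40
        for _ in range(reps):
            x = pd.DataFrame({"noise": rng.normal(size=200)})
            y = (rng.random(200) < 0.3).astype(float)
            res = stepwise_logistic_aic(x, y, candidates=("noise",))
            picked += "noise" in res.selected
        assert picked / reps < 0.35  # well below chance, near the 0.157 theory

    def test_informative_predictor_selected(self, rng):
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(2.0 * x)))
        y = (rng.random(300) < p).astype(float)
        X = pd.DataFrame({"signal": x, "decoy": rng.normal(size=300)})
        res = stepwise_logistic_aic(X, y)
        assert "signal" in res.selected

    def test_degenerate_one_class(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValidationError):
            stepwise_logistic_aic(X, np.array([1.0, 1.0]))

    def test_never_worse_than_intercept_only(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(120, 4)), columns=list("abcd"))
            y = (r.random(120) < 0.4).astype(float)
            res = stepwise_logistic_aic(X, y)
            assert res.aic <= res.trace[0]["aic"] + 1e-9

    def test_aic_trace_monotone(self, rng):
        x = rng.normal(size=250)
        p = 1 / (1 + np.exp(-(1.5 * x - 0.5)))
        y = (rng.random(250) < p).astype(float)
        X = pd.DataFrame({"x": x, "z": rng.normal(size=250)})
        res = stepwise_logistic_aic(X, y)
        aics = [t["aic"] for t in res.trace]
        assert all(a > b for a, b in zip(aics, aics[1:]))


class TestCollinearity:
    def test_orthogonal_predictors(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "s1": np.sin(2 * np.pi * t / n),
                "s2": np.cos(2 * np.pi * t / n),
                "s3": np.sin(4 * np.pi * t / n),
            }
        )
        vif = collinearity_check(X)
        assert np.allclose(vif["vif"], 1.0, atol=1e-9)
        assert not vif["flagged"].any()

    def test_duplicated_column_flagged(self, rng):
        x = rng.normal(size=50)
        vif = collinearity_check(pd.DataFrame({"a": x, "b": x}))
        assert vif["flagged"].all()
        assert np.isinf(vif["vif"]).all() or (vif["vif"] > 1e6).all()

    def test_constant_column_infinite(self, rng):
        vif = collinearity_check(
            pd.DataFrame({"c": np.ones(30), "x": rng.normal(size=30)})
        ).set_index("predictor")
        assert np.isinf(vif.loc["c", "vif"])
        assert bool(vif.loc["c", "flagged"])

    def test_vif_grows_as_noise_shrinks(self, rng):
        x = rng.normal(size=200)
        noise = rng.normal(size=200)
        vifs = []
        for sigma in (1.0, 0.3, 0.1, 0.03):
            X = pd.DataFrame({"x1": x, "x2": x + sigma * noise})
            v = collinearity_check(X).set_index("predictor").loc["x2", "vif"]
            vifs.append(v)
        assert all(a < b for a, b in zip(vifs, vifs[1:]))


def exact_rank_sum_p(x, y):
    """Enumeration oracle: all assignments of pooled values to group sizes."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        us.append(
            sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in g1 for b in g2)
        )
    us = np.asarray(us)
    ge = np.mean(us >= u_obs)
    le = np.mean(us <= u_obs)
    return min(1.0, 2 * min(ge, le))


class TestRankTests:
    def test_exact_p_three_vs_three(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res["p"] == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(5):
            x = rng.permutation(20)[: int(rng.integers(3, 6))].astype(float)
            y = rng.permutation(40)[20:][: int(rng.integers(3, 6))].astype(float) + 0.25
            res = rank_sum_test(x, y)
            assert res["p"] == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    def test_identical_groups_null_centre(self):
        res = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["p"] > 0.9

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([1.0], [2.0, 3.0])

    def test_monotone_pair_spearman_one(self, cohort200):
        from hepaplan.synthetic_data import preop_table
        from scipy import stats

        pre = preop_table(cohort200)
        rho, _ = stats.spearmanr(pre["ct1_ms"], pre["ct1_ms"] ** 3)
        assert rho == pytest.approx(1.0)

    def test_cohort_rank_tests(self, cohort200):
        from hepaplan.synthetic_data import preop_table

        out = rank_tests(preop_table(cohort200))
        assert out["wilcoxon_los"]["p"] < 0.05  # generator builds in the effect
        assert out["wilcoxon_los"]["median_high"] > out["wilcoxon_los"]["median_normal"]
        assert out["spearman"]["pdff_vs_steatosis"]["rho"] > 0.5
        assert out["spearman"]["ct1_vs_ballooning"]["rho"] > 0.2


class TestPredictorMatrix:
    def test_build_and_eligibility(self, cohort200):
        from hepaplan.scores import score_cohort
        from hepaplan.synthetic_data import preop_table

        panel = score_cohort(cohort200)
        pm = risk_stats.build_predictor_matrix(panel, preop_table(cohort200))
        assert pm.eligible.sum() > 50
        resected = 1.0 - pm.frame["log_flr"].apply(np.exp) / 100.0
        assert (resected[pm.eligible] >= 0.10 - 1e-9).all()

    def test_missing_candidate_marks_ineligible(self, cohort200):
        from hepaplan.scores import score_cohort
        from hepaplan.synthetic_data import preop_table

        panel = score_cohort(cohort200)
        pre = preop_table(cohort200).copy()
        pre.loc[pre.index[:5], "bmi"] = np.nan
        pm = risk_stats.build_predictor_matrix(panel, pre)
        assert not pm.eligible[:5].any()
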