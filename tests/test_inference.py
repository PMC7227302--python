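"""Statistical engine: rank-sum oracle, LDA geometry, ROC identities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coascreen.config import PipelineConfig
from coascreen.errors import EmptyGroupError
from coascreen.features import FEATURES
from coascreen.inference import (
    compare_groups,
    lda_fit,
    loocv,
    operating_point,
    roc_curve,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_ranksum_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) over all C(n, n_a) equally
    likely assignments of the pooled values to group A, capped at 1.
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for idx in itertools.combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        us.append(u)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def mann_whitney_auc(scores, labels):
    """AUROC as the normalised midrank Mann-Whitney U (pairwise count)."""
    s1 = scores[labels == 1]
    s0 = scores[labels == 0]
    wins = sum((x > y) + 0.5 * (x == y) for x in s1 for y in s0)
    return wins / (len(s1) * len(s0))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

class TestWilcoxonRankSum:
    def test_textbook_extreme_case(self):
        # fully separated 3v3: the most extreme of C(6,3)=20 assignments,
        # two-sided p = 2/20
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_empty_group_refused(self):
        with pytest.raises(EmptyGroupError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_all_small_problems(self):
        """Exact agreement with full enumeration for every split with
        n_a + n_b <= 8 over random tie-free samples."""
        rng = np.random.default_rng(0)
        for n in range(2, 9):
            for na in range(1, n):
                for _ in range(3):
                    pooled = rng.permutation(rng.uniform(0, 1, n))
                    a, b = pooled[:na], pooled[na:]
                    assert wilcoxon_rank_sum(a, b) == pytest.approx(
                        enumerate_ranksum_p(a, b), abs=1e-12
                    )

    @given(
        st.lists(st.integers(-50, 50), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(-50, 50), min_size=2, max_size=6, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, a, b):
        """p depends on the pooled data only through ranks."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        p1 = wilcoxon_rank_sum(a, b)
        f = lambda x: np.exp(x / 25.0)  # strictly increasing, tie-preserving
        p2 = wilcoxon_rank_sum(f(a), f(b))
        assert p1 == pytest.approx(p2, abs=1e-12)


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

def _toy_features(n=6, shift_dmrf=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for grp, phase, pids in (
        ("coa", "pre", range(n)),
        ("coa", "post", range(n)),
        ("control", "none", range(n)),
    ):
        for i in pids:
            row = {"patient_id": f"{grp}{i}", "phase": phase, "group": grp}
            for f in FEATURES:
                u = rng.normal(5, 0.3)
                l = rng.normal(5, 0.3)
                if f == "mrf" and grp == "coa" and phase == "pre":
                    l += shift_dmrf
                row[f"{f}_u"], row[f"{f}_l"] = u, l
                row[f"d_{f}"] = u - l
            rows.append(row)
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_contrast_feature_sets(self):
        feats = _toy_features()
        pre = compare_groups(feats, "pre_vs_control")
        paired = compare_groups(feats, "pre_vs_post")
        assert len(pre) == 12
        assert len(paired) == 4
        assert {c.feature_name for c in paired} == {"d_arr", "d_arf", "d_mrr", "d_mrf"}

    def test_quartiles_bracket_median(self):
        for c in compare_groups(_toy_features(), "pre_vs_control"):
            assert c.group_a_q1 <= c.group_a_median <= c.group_a_q3
            assert 0 < c.p_value <= 1

    def test_large_dmrf_shift_detected(self):
        feats = _toy_features(n=12, shift_dmrf=2.0, seed=1)
        comps = {c.feature_name: c for c in compare_groups(feats, "pre_vs_control")}
        assert comps["d_mrf"].p_value < 0.01
        assert comps["d_mrr"].p_value > 0.05

    def test_empty_group_refused(self):
        feats = _toy_features()
        with pytest.raises(EmptyGroupError):
            compare_groups(feats[feats.group == "coa"], "pre_vs_control")

    def test_missing_site_patient_excluded_from_feature(self):
        feats = _toy_features(n=5)
        feats.loc[feats.index[0], "d_mrf"] = np.nan  # one pre-op patient lacks a site
        comps = compare_groups(feats, "pre_vs_control")
        assert all(np.isfinite(c.p_value) for c in comps)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

class TestLDA:
    def test_separable_training_accuracy(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        rule = lda_fit(X, y)
        assert np.array_equal(rule.predict(X), y)

    def test_class_swap_negates_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 10 + [1] * 10)
        s1 = lda_fit(X, y).score(X)
        s2 = lda_fit(X, 1 - y).score(X)
        np.testing.assert_allclose(s1, -s2, atol=1e-10)

    def test_weight_direction_matches_closed_form(self):
        """With known Gaussian classes the learned direction is parallel to
        pooled_cov^-1 (mu1 - mu0) to within 1 degree at n = 10^4."""
        rng = np.random.default_rng(5)
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        mu0, mu1 = np.array([0.0, 0.0]), np.array([1.0, 0.5])
        L = np.linalg.cholesky(cov)
        X0 = rng.normal(size=(10_000, 2)) @ L.T + mu0
        X1 = rng.normal(size=(10_000, 2)) @ L.T + mu1
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(10_000, int), np.ones(10_000, int)]
        w = lda_fit(X, y).weights
        w_true = np.linalg.solve(cov, mu1 - mu0)
        cos = w @ w_true / (np.linalg.norm(w) * np.linalg.norm(w_true))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_matches_sklearn_decision_boundary(self):
        """Cross-check predictions against scikit-learn's LDA."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        rule = lda_fit(X, y)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        Xt = rng.normal(size=(200, 2))
        agree = np.mean(rule.predict(Xt) == sk.predict(Xt))
        assert agree >= 0.99

    def test_singular_covariance_ridge_warns(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning):
            rule = lda_fit(X, y)
        assert np.all(np.isfinite(rule.weights))

    def test_single_class_refused(self):
        with pytest.raises(EmptyGroupError):
            lda_fit(np.zeros((4, 2)), np.zeros(4, int))


# ---------------------------------------------------------------------------
# ROC / operating point
# ---------------------------------------------------------------------------

class TestROC:
    def test_perfect_ranking(self):
        _, auc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_curve([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert auc == 0.5

    def test_partial_ranking_pair_count(self):
        # labels (0,0,1,1) with scores (3,1,2,4): 3 of 4 pairs won
        _, auc = roc_curve([3, 1, 2, 4], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_curve_monotone(self):
        rng = np.random.default_rng(2)
        roc, _ = roc_curve(rng.normal(size=30), rng.integers(0, 2, 30) | np.r_[1, np.zeros(29, int)])
        assert np.all(np.diff(roc["fpr"]) >= 0)
        assert np.all(np.diff(roc["tpr"]) >= 0)

    def test_auroc_equals_mann_whitney_u(self):
        """Trapezoidal AUROC == normalised midrank U on 100 random score
        sets, including ties."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(6, 30)
            scores = np.round(rng.normal(size=n), rng.integers(0, 3))
            labels = np.zeros(n, int)
            labels[rng.choice(n, rng.integers(2, n - 1), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            _, auc = roc_curve(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_one_class_refused(self):
        with pytest.raises(EmptyGroupError):
            roc_curve([1, 2], [1, 1])


class TestOperatingPoint:
    def test_perfect_classifier(self):
        roc, _ = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        sens, spec, _ = operating_point(roc)
        assert (sens, spec) == (1.0, 1.0)

    def test_screening_constraint_selection(self):
        """Among candidate thresholds the screen picks maximum sensitivity
        subject to specificity >= 0.90."""
        roc = pd.DataFrame(
            {
                "fpr": [0.0, 1 - 0.94, 0.5],
                "tpr": [0.3, 0.61, 0.9],
                "threshold": [3.0, 2.0, 1.0],
            }
        )
        sens, spec, thr = operating_point(roc, min_specificity=0.90)
        assert sens == pytest.approx(0.61)
        assert spec == pytest.approx(0.94)
        assert thr == 2.0

    def test_unconstrained_reduces_to_max_sensitivity(self):
        roc = pd.DataFrame(
            {"fpr": [0.0, 0.2, 1.0], "tpr": [0.2, 0.8, 1.0],
             "threshold": [3.0, 2.0, 1.0]}
        )
        sens, _, _ = operating_point(roc, min_specificity=0.0)
        assert sens == 1.0

    def test_infeasible_constraint_falls_back_with_warning(self):
        roc = pd.DataFrame(
            {"fpr": [0.5, 0.8], "tpr": [0.5, 0.9], "threshold": [2.0, 1.0]}
        )
        with pytest.warns(UserWarning):
            sens, spec, _ = operating_point(roc, min_specificity=0.9)
        assert spec == 0.5


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def _screening_features(n_coa, n_ctl, shift, seed=0, sd=0.1):
    rng = np.random.default_rng(seed)
    rows = []
    for grp, phase, n in (("coa", "pre", n_coa), ("control", "none", n_ctl)):
        for i in range(n):
            mrf_u = rng.normal(-2.6, sd)
            mrf_l = rng.normal(-2.6, sd) + (shift if grp == "coa" else 0.0)
            rows.append(
                {"patient_id": f"{grp}{i}", "phase": phase, "group": grp,
                 "mrf_u": mrf_u, "mrf_l": mrf_l}
            )
    return pd.DataFrame(rows)


class TestLOOCV:
    def test_fold_count_equals_patients(self):
        feats = _screening_features(2, 2, shift=5.0)
        res = loocv(feats)
        assert len(res.fold_predictions) == 4

    def test_separable_features_perfect_accuracy(self):
        feats = _screening_features(8, 8, shift=1.0, sd=0.01)  # +100 sigma
        res = loocv(feats)
        assert res.accuracy == 1.0
        assert res.auroc == 1.0

    def test_affine_feature_rescaling_invariance(self):
        """LDA decisions are equivariant under feature-wise affine maps."""
        feats = _screening_features(8, 8, shift=0.3, seed=4)
        res1 = loocv(feats)
        feats2 = feats.assign(mrf_u=5 * feats.mrf_u + 3, mrf_l=0.5 * feats.mrf_l - 7)
        res2 = loocv(feats2)
        assert res1.accuracy == res2.accuracy
        assert res1.auroc == pytest.approx(res2.auroc, abs=1e-12)

    def test_too_few_patients_refused(self):
        with pytest.raises(EmptyGroupError):
            loocv(_screening_features(1, 5, shift=1.0))
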