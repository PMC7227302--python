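"""Group statistics and the LOOCV LDA screening classifier.

Group contrasts follow the study design exactly: all twelve features
(four slopes x upper site, lower site, upper-minus-lower delta) are
compared between pre-operative coarctation patients and controls, the
same between post-operative patients and controls, and the four deltas
are compared within coarctation patients pre- vs post-repair.  Each
contrast uses the two-sided Wilcoxon rank-sum (Mann-Whitney) test with
no multiple-testing correction (a Benjamini-Hochberg option exists
behind a config flag); summaries are medians with 1st/3rd quartiles
(linear-interpolation convention).

Screening uses a two-class linear discriminant on the per-patient
(MRF_upper, MRF_lower) pair, evaluated by leave-one-out cross-validation
stratified by patient: each fold trains on all other patients and
scores the held-out one, so no patient ever contributes to the model
that classifies them.  Pooled fold scores give the ROC curve; the AUROC
equals the normalised Mann-Whitney U of the scores.  The suggested
operating point maximises sensitivity subject to specificity >= 0.90 —
for newborn screening a low false-positive rate is preferred even at
the cost of sensitivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import EmptyGroupError
from .features import DELTA_COLUMNS, SITE_COLUMNS

logger = logging.getLogger(__name__)

ALL_FEATURE_COLUMNS = SITE_COLUMNS + DELTA_COLUMNS

CONTRASTS = ("pre_vs_control", "post_vs_control", "pre_vs_post")


@dataclass(frozen=True)
class GroupComparison:
    """One feature's two-group summary and rank-sum p-value."""

    feature_name: str
    group_a_median: float
    group_a_q1: float
    group_a_q3: float
    group_b_median: float
    group_b_q1: float
    group_b_q3: float
    p_value: float
    significant: bool
    alpha: float


@dataclass
class ScreeningResult:
    """LOOCV output: per-fold predictions, ROC, AUROC, operating point."""

    fold_predictions: pd.DataFrame  # patient_id, true_label, predicted, score
    accuracy: float
    roc_points: pd.DataFrame        # fpr, tpr, threshold
    auroc: float
    operating_point: tuple[float, float, float]  # sensitivity, specificity, thr


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the combined sample size is
    <= 20 and there are no ties, otherwise the normal approximation with
    tie and continuity corrections.  Two samples with all values
    identical give p = 1 by convention.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyGroupError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return float(med), float(q1), float(q3)


def _contrast_frames(
    features: pd.DataFrame, contrast: str
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...]]:
    if contrast == "pre_vs_control":
        a = features[(features.group == "coa") & (features.phase == "pre")]
        b = features[features.group == "control"]
        cols = ALL_FEATURE_COLUMNS
    elif contrast == "post_vs_control":
        a = features[(features.group == "coa") & (features.phase == "post")]
        b = features[features.group == "control"]
        cols = ALL_FEATURE_COLUMNS
    elif contrast == "pre_vs_post":
        a = features[(features.group == "coa") & (features.phase == "pre")]
        b = features[(features.group == "coa") & (features.phase == "post")]
        cols = DELTA_COLUMNS
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return a, b, cols


def compare_groups(
    features: pd.DataFrame,
    contrast: str,
    cfg: PipelineConfig | None = None,
) -> list[GroupComparison]:
    """Rank-sum comparison of every feature for one study contrast.

    ``features`` is the per-patient table (one row per patient x phase).
    Group contrasts test all twelve features; the pre-vs-post contrast
    tests the four upper-minus-lower deltas.  Patients with a missing
    value for a feature (absent site) are excluded from that feature's
    test only.  Significance is flagged at the contrast's alpha with no
    multiplicity correction unless ``cfg.bh_correction`` is set.
    """
    cfg = cfg or PipelineConfig()
    a, b, cols = _contrast_frames(features, contrast)
    if len(a) == 0 or len(b) == 0:
        raise EmptyGroupError(f"contrast {contrast}: a group is empty")
    alpha = {
        "pre_vs_control": cfg.alpha_preop,
        "post_vs_control": cfg.alpha_postop,
        "pre_vs_post": cfg.alpha_paired,
    }[contrast]
    out: list[GroupComparison] = []
    pvals: list[float] = []
    for col in cols:
        xa = a[col].dropna().to_numpy(float)
        xb = b[col].dropna().to_numpy(float)
        if len(xa) == 0 or len(xb) == 0:
            raise EmptyGroupError(f"feature {col}: no data in a group")
        p = wilcoxon_rank_sum(xa, xb)
        med_a, q1_a, q3_a = _quartiles(xa)
        med_b, q1_b, q3_b = _quartiles(xb)
        pvals.append(p)
        out.append(GroupComparison(col, med_a, q1_a, q3_a,
                                   med_b, q1_b, q3_b, p, p < alpha, alpha))
    if cfg.bh_correction:
        adj = _benjamini_hochberg(np.array(pvals))
        out = [
            GroupComparison(c.feature_name, c.group_a_median, c.group_a_q1,
                            c.group_a_q3, c.group_b_median, c.group_b_q1,
                            c.group_b_q3, float(p), p < alpha, alpha)
            for c, p in zip(out, adj)
        ]
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular form of a contrast's comparisons (one row per feature)."""
    return pd.DataFrame([c.__dict__ for c in comparisons])


@dataclass(frozen=True)
class LinearDecisionRule:
    """LDA rule: score(x) = w . x - threshold, higher score => COA."""

    weights: np.ndarray
    threshold: float

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.weights - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) > 0).astype(int)


def lda_fit(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6
) -> LinearDecisionRule:
    """Two-class LDA with pooled covariance and equal priors.

    ``y`` is 0 (control) / 1 (COA).  The weight vector is
    ``pooled_cov^-1 (mu_1 - mu_0)`` and the threshold places the decision
    boundary at the midpoint of the projected class means (equal
    priors).  A singular pooled covariance is ridge-regularised with
    ``ridge`` on the diagonal, with a warning.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    if set(np.unique(y)) != {0, 1}:
        raise EmptyGroupError("LDA needs both classes in the training data")
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    pooled = (
        (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    ) / max(n0 + n1 - 2, 1)
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance: ridge-regularising")
        pooled = pooled + ridge * np.eye(pooled.shape[0])
        w = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return LinearDecisionRule(weights=w, threshold=threshold)


def _screening_table(features: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    """One pre-operative feature vector per patient for classification."""
    coa = features[(features.group == "coa") & (features.phase == "pre")]
    ctl = features[features.group == "control"]
    table = pd.concat([coa, ctl], ignore_index=True)
    table = table.dropna(subset=list(cols))
    table = table.assign(label=(table.group == "coa").astype(int))
    return table


def loocv(
    features: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> ScreeningResult:
    """Leave-one-out cross-validation of the LDA screen, one fold per patient.

    Each patient contributes exactly one pre-operative feature vector
    (controls their single session); each fold trains on all other
    patients and scores the held-out one.  Accuracy is the fraction of
    correctly classified folds; pooled decision scores feed the ROC.
    """
    cfg = cfg or PipelineConfig()
    cols = tuple(cfg.classifier_features)
    table = _screening_table(features, cols)
    if (table.label == 1).sum() < 2 or (table.label == 0).sum() < 2:
        raise EmptyGroupError("LOOCV needs >= 2 patients per class")
    X = table[list(cols)].to_numpy(float)
    y = table["label"].to_numpy(int)
    scores = np.empty(len(table))
    preds = np.empty(len(table), dtype=int)
    for i in range(len(table)):
        mask = np.ones(len(table), bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            raise EmptyGroupError("a fold's training set lost a class")
        rule = lda_fit(X[mask], y[mask], ridge=cfg.lda_ridge)
        scores[i] = rule.score(X[i : i + 1])[0]
        preds[i] = int(scores[i] > 0)
    folds = pd.DataFrame(
        {
            "patient_id": table["patient_id"].to_numpy(),
            "true_label": y,
            "predicted_label": preds,
            "decision_score": scores,
        }
    )
    accuracy = float(np.mean(preds == y))
    roc, auroc = roc_curve(scores, y)
    op = operating_point(roc, min_specificity=cfg.min_specificity)
    return ScreeningResult(folds, accuracy, roc, auroc, op)


def roc_curve(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct score and trapezoidal AUROC.

    Ties are handled by thresholding at distinct scores only, which
    makes the trapezoidal area equal the midrank Mann-Whitney U
    statistic normalised by ``n1 * n0``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EmptyGroupError("ROC needs both classes")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[labels == 0] >= t).mean() for t in thresholds])
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    auroc = float(np.trapezoid(tpr, fpr))
    return roc, auroc


def operating_point(
    roc: pd.DataFrame, min_specificity: float = 0.90
) -> tuple[float, float, float]:
    """Pick the ROC threshold for a screening test.

    Among thresholds with specificity >= ``min_specificity``, return the
    one maximising sensitivity (ties broken toward higher specificity).
    If no threshold qualifies, return the maximum-specificity point with
    a warning.
    """
    if len(roc) == 0:
        raise EmptyGroupError("empty ROC")
    sens = roc["tpr"].to_numpy(float)
    spec = 1.0 - roc["fpr"].to_numpy(float)
    thr = roc["threshold"].to_numpy(float)
    ok = spec >= min_specificity
    if not ok.any():
        warnings.warn("no threshold meets the specificity constraint")
        i = int(np.argmax(spec))
        return float(sens[i]), float(spec[i]), float(thr[i])
    # maximise sensitivity, then specificity
    best = np.lexsort((spec, sens))
    best = [i for i in best if ok[i]]
    i = best[-1]
    return float(sens[i]), float(spec[i]), float(thr[i])
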