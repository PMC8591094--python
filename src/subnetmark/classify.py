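"""SVM classification on subnetwork scores, evaluation metrics, PCA QC.

The classifier is a maximum-margin linear SVM (C = 1 by default) on the
subnetwork score matrix, case = positive class. Evaluation reports the
confusion counts and the standard identities

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)

plus the AUC of the decision values with a DeLong 95% confidence interval
(or a seeded bootstrap interval on request). PCA of the score matrix gives
an unsupervised look at sample separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from subnetmark.data_io import ValidationError
from subnetmark.scoring import SubnetworkScoreMatrix

POSITIVE = "case"


@dataclass
class ClassifierEval:
    """Confusion counts with the derived metrics; missing metrics stay None."""

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int) -> "ClassifierEval":
        total = tp + fn + fp + tn
        return cls(
            tp=tp, fn=fn, fp=fp, tn=tn,
            accuracy=(tp + tn) / total if total else None,
            sensitivity=tp / (tp + fn) if tp + fn else None,
            specificity=tn / (fp + tn) if fp + tn else None,
        )

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
        }
        if self.auc_ci is not None:
            out["auc_ci_low"], out["auc_ci_high"] = self.auc_ci
        return out


def _features_labels(scores: SubnetworkScoreMatrix, labels: dict[str, str]):
    samples = [s for s in scores.sample_ids if s in labels]
    if len(samples) < len(scores.sample_ids):
        missing = set(scores.sample_ids) - set(samples)
        raise ValidationError(f"samples without labels: {sorted(missing)[:5]}")
    x = scores.scores[samples].to_numpy().T  # samples x subnetworks
    y = np.array([1 if labels[s] == POSITIVE else 0 for s in samples])
    return x, y, samples


def train_svm(
    scores: SubnetworkScoreMatrix,
    labels: dict[str, str],
    c: float = 1.0,
    tune: bool = False,
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
    cv_folds: int = 5,
    random_state: int = 0,
) -> SVC:
    """Fit a linear-kernel SVM on subnetwork scores (case vs control).

    With ``tune=True`` the regularization constant is grid-searched with
    stratified k-fold cross-validation; otherwise C is fixed (default 1).
    """
    x, y, _ = _features_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    if min(np.bincount(y)) < 2:
        raise ValidationError("need >=2 samples per class")
    if tune:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
        search = GridSearchCV(
            SVC(kernel="linear"), {"C": list(c_grid)}, cv=cv, scoring="accuracy"
        )
        search.fit(x, y)
        return search.best_estimator_
    model = SVC(kernel="linear", C=c)
    model.fit(x, y)
    return model


def evaluate(
    model: SVC,
    scores: SubnetworkScoreMatrix,
    labels: dict[str, str],
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    random_state: int = 0,
) -> ClassifierEval:
    """Confusion-count metrics and AUC (+95% CI) on a labelled cohort.

    A class absent from the cohort leaves its metric (and the AUC) as None
    rather than zero.
    """
    x, y, _ = _features_labels(scores, labels)
    predicted = model.predict(x)
    decision = model.decision_function(x)
    tp = int(np.sum((predicted == 1) & (y == 1)))
    fn = int(np.sum((predicted == 0) & (y == 1)))
    fp = int(np.sum((predicted == 1) & (y == 0)))
    tn = int(np.sum((predicted == 0) & (y == 0)))
    result = ClassifierEval.from_counts(tp, fn, fp, tn)
    if len(np.unique(y)) == 2:
        result.auc = float(_rank_auc(decision, y))
        if ci_method == "delong":
            result.auc_ci = _delong_ci(decision, y)
        elif ci_method == "bootstrap":
            result.auc_ci = _bootstrap_ci(decision, y, n_bootstrap, random_state)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return result


def _rank_auc(decision: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with the tie convention (ties count 1/2)."""
    ranks = stats.rankdata(decision)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _delong_ci(decision: np.ndarray, y: np.ndarray, level: float = 0.95):
    """DeLong variance of the AUC via placement values; Wald interval,
    clipped to [0, 1]."""
    pos = decision[y == 1]
    neg = decision[y == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = stats.norm.ppf(0.5 + level / 2)
    low = min(max(auc - zq * se, 0.0), auc)
    high = max(min(auc + zq * se, 1.0), auc)
    return (float(low), float(high))


def _bootstrap_ci(decision, y, n_bootstrap: int, random_state: int, level: float = 0.95):
    rng = np.random.default_rng(random_state)
    n = len(y)
    aucs = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        aucs.append(_rank_auc(decision[idx], y[idx]))
    lo, hi = np.percentile(aucs, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return (float(lo), float(hi))


def pca_project(
    scores: SubnetworkScoreMatrix, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples in subnetwork-score space.

    Returns per-sample coordinates on the leading 2-3 components and the
    variance-explained ratios (non-increasing).
    """
    x = scores.scores.to_numpy().T
    if x.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(scores.sample_ids, name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, pca.explained_variance_ratio_
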