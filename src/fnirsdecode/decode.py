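"""Linear discriminant decoding with scatter-based feature selection.

The classifier is two-class Fisher LDA written out explicitly: pooled
within-class scatter ``S_w``, discriminant ``w = S_w^-1 (mu1 - mu2)``, bias
at the midpoint of the projected class means (equal priors).  If ``S_w`` is
ill-conditioned (condition number above 1e10) a shrinkage fallback
``S_w <- (1-g) S_w + g tr(S_w)/p I`` with g = 0.1 is applied.

Feature relevance is scored from the eigen-decomposition of the within-class
scatter: each feature's loading on the S_w^-1/2-whitened class-mean
difference (``scatter-eig``, the default; the absolute discriminant loading
``|w_i|`` is selectable).  Subsets of the best 5%..100% (steps of 5%)
features feed the subject-independent evaluation: train on one cohort's
pooled trials, score each held-out cohort subject separately with balanced
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError
from .features import META_COLUMNS

COMPARISONS = {
    "pos_vs_neg": ("positive", "negative"),
    "pos_vs_neu": ("positive", "neutral"),
    "neg_vs_neu": ("negative", "neutral"),
}

#: 5% .. 100% in steps of 5% — 20 subsets, matching the m=120 Bonferroni family
DEFAULT_FRACTIONS = tuple(np.round(np.arange(1, 21) * 0.05, 2))

DEFAULT_SHRINKAGE = 0.1
COND_THRESHOLD = 1e10


@dataclass
class LDAModel:
    w: np.ndarray
    b: float
    class_labels: tuple[str, str]
    mu_pos: np.ndarray  # mean of class_labels[0]
    mu_neg: np.ndarray  # mean of class_labels[1]
    S_w: np.ndarray
    shrinkage: float
    feature_names: tuple[str, ...] | None = None


@dataclass
class FeatureRanking:
    scores: np.ndarray
    order: np.ndarray  # feature indices, descending score, ties -> lower index first
    method: str


@dataclass
class DecodingResult:
    comparison: str
    task: str
    subset_fraction: float
    subject_id: str
    balanced_accuracy_pct: float
    selected_features: tuple[int, ...]


def _class_matrices(X, y, classes):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("X must be (n_trials, n_features) aligned with y")
    present = [c for c in classes if (y == c).sum() > 0]
    if len(present) < 2:
        raise FitError("both classes must be present in y")
    Xa, Xb = X[y == classes[0]], X[y == classes[1]]
    if len(Xa) < 2 or len(Xb) < 2:
        raise FitError("need at least 2 trials per class")
    return X, Xa, Xb


def fit_lda(X, y, classes: tuple[str, str] | None = None,
            shrinkage: float = DEFAULT_SHRINKAGE,
            feature_names=None) -> LDAModel:
    """Fit the two-class discriminant.

    ``classes`` fixes the label order (first label maps to positive decision
    scores); by default the two labels are taken in sorted order.
    """
    y = np.asarray(y)
    if classes is None:
        uniq = sorted(np.unique(y).tolist())
        if len(uniq) != 2:
            raise FitError(f"expected exactly 2 classes, got {uniq}")
        classes = (uniq[0], uniq[1])
    X, Xa, Xb = _class_matrices(X, y, classes)
    mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
    # pooled within-class scatter (unbiased pooled covariance)
    Sa = (Xa - mu_a).T @ (Xa - mu_a)
    Sb = (Xb - mu_b).T @ (Xb - mu_b)
    S_w = (Sa + Sb) / (len(Xa) + len(Xb) - 2)
    used_gamma = 0.0
    p = X.shape[1]
    if p > 1:
        cond = np.linalg.cond(S_w)
    else:
        cond = np.inf if S_w[0, 0] == 0 else 1.0
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        used_gamma = shrinkage
        S_w = (1 - used_gamma) * S_w + used_gamma * (np.trace(S_w) / p) * np.eye(p)
    w = np.linalg.solve(S_w, mu_a - mu_b)
    b = -float(w @ (mu_a + mu_b) / 2.0)
    return LDAModel(w=w, b=b, class_labels=classes, mu_pos=mu_a, mu_neg=mu_b,
                    S_w=S_w, shrinkage=used_gamma,
                    feature_names=tuple(feature_names) if feature_names is not None else None)


def decision_scores(model: LDAModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.w):
        raise ValidationError(
            f"X has {X.shape[-1]} columns, model expects {len(model.w)}"
        )
    return X @ model.w + model.b


def predict(model: LDAModel, X) -> np.ndarray:
    """Labels from the sign of the decision score; ties go to the first label."""
    s = decision_scores(model, X)
    return np.where(s >= 0, model.class_labels[0], model.class_labels[1])


def rank_features(X, y, classes=None, method: str = "scatter-eig") -> FeatureRanking:
    """Relevance scores for every feature, descending order, stable ties.

    ``abs-weight``: |w_i| of the LDA fitted on all features.
    ``scatter-eig``: per-feature loading of the within-scatter-whitened mean
    difference, computed from the eigen-decomposition of S_w
    (|V diag(1/sqrt(l)) V^T (mu1 - mu2)|_i).
    """
    model = fit_lda(X, y, classes=classes)
    if method == "abs-weight":
        scores = np.abs(model.w)
    elif method == "scatter-eig":
        lam, V = np.linalg.eigh(model.S_w)
        lam = np.maximum(lam, 1e-12 * lam.max() if lam.max() > 0 else 1e-12)
        whitened = V @ ((V.T @ (model.mu_pos - model.mu_neg)) / np.sqrt(lam))
        scores = np.abs(whitened)
    else:
        raise ValidationError(f"unknown ranking method {method!r}")
    if not np.isfinite(scores).all():
        raise FitError("non-finite relevance scores")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(scores=scores, order=order, method=method)


def subset_size(fraction: float, n_features: int) -> int:
    """max(1, floor(fraction * n_features)); 5% of 64 -> 3, 20% -> 12, 30% -> 19."""
    if fraction <= 0:
        raise ValidationError("fraction must be positive")
    if fraction > 1:
        raise ValidationError("fraction must be <= 1")
    if n_features < 1:
        raise ValidationError("need at least one feature")
    return max(1, int(np.floor(fraction * n_features + 1e-9)))


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the two per-class recalls, in percent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(y_true)
    if len(labels) != 2:
        raise ValidationError("balanced accuracy needs both classes in y_true")
    recalls = [np.mean(y_pred[y_true == lab] == lab) for lab in labels]
    return 100.0 * float(np.mean(recalls))


def _comparison_slice(table: pd.DataFrame, comparison: str, task: str,
                      normalize: str = "none"):
    if comparison not in COMPARISONS:
        raise ValidationError(f"unknown comparison {comparison!r}")
    a, b = COMPARISONS[comparison]
    sel = table[(table["task"] == task) & (table["condition"].isin([a, b]))]
    if sel.empty:
        raise ValidationError(f"no {comparison} trials for task {task!r}")
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    X = sel[feat_cols].to_numpy(dtype=float)
    y = sel["condition"].to_numpy()
    subjects = sel["subject_id"].to_numpy()
    if normalize == "zscore-subject":
        for s in np.unique(subjects):
            mask = subjects == s
            mu = X[mask].mean(axis=0)
            sd = X[mask].std(axis=0, ddof=0)
            X[mask] = (X[mask] - mu) / np.where(sd > 0, sd, 1.0)
    elif normalize != "none":
        raise ValidationError(f"unknown normalization {normalize!r}")
    return X, y, subjects, feat_cols, (a, b)


def cross_dataset_evaluate(train_table: pd.DataFrame, test_table: pd.DataFrame,
                           comparison: str, task: str,
                           fractions=DEFAULT_FRACTIONS,
                           ranking_method: str = "scatter-eig",
                           normalize: str = "none") -> list[DecodingResult]:
    """Subject-independent evaluation across two cohorts.

    Features are ranked once on the pooled training cohort; for each subset
    fraction an LDA is fitted on the selected training columns and every test
    subject's trials are scored independently with balanced accuracy.
    ``normalize="zscore-subject"`` standardises each subject's features
    before pooling (off by default; no per-subject calibration).
    """
    Xtr, ytr, _, cols_tr, classes = _comparison_slice(train_table, comparison,
                                                      task, normalize)
    Xte, yte, subj_te, cols_te, _ = _comparison_slice(test_table, comparison,
                                                      task, normalize)
    if cols_tr != cols_te:
        raise ValidationError("train and test cohorts have different feature schemas")
    ranking = rank_features(Xtr, ytr, classes=classes, method=ranking_method)
    results: list[DecodingResult] = []
    for frac in fractions:
        k = subset_size(float(frac), Xtr.shape[1])
        sel = ranking.order[:k]
        model = fit_lda(Xtr[:, sel], ytr, classes=classes,
                        feature_names=[cols_tr[i] for i in sel])
        for subject in sorted(pd.unique(subj_te)):
            mask = subj_te == subject
            acc = balanced_accuracy(yte[mask], predict(model, Xte[mask][:, sel]))
            results.append(DecodingResult(
                comparison=comparison, task=task, subset_fraction=float(frac),
                subject_id=str(subject), balanced_accuracy_pct=acc,
                selected_features=tuple(int(i) for i in sel)))
    return results


def loso_cv(table: pd.DataFrame, comparison: str, task: str,
            fractions=DEFAULT_FRACTIONS,
            ranking_method: str = "scatter-eig") -> list[DecodingResult]:
    """Leave-one-subject-out variant: rank + fit on the remaining subjects."""
    subjects = sorted(pd.unique(table["subject_id"]))
    if len(subjects) < 2:
        raise FitError("LOSO needs at least 2 subjects")
    results: list[DecodingResult] = []
    for held_out in subjects:
        train = table[table["subject_id"] != held_out]
        test = table[table["subject_id"] == held_out]
        results.extend(cross_dataset_evaluate(train, test, comparison, task,
                                              fractions, ranking_method))
    return results


def results_to_frame(results: list[DecodingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "comparison": r.comparison,
            "task": r.task,
            "subset_fraction": r.subset_fraction,
            "subject_id": r.subject_id,
            "balanced_accuracy_pct": r.balanced_accuracy_pct,
            "n_selected": len(r.selected_features),
        } for r in results]
    )
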