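"""ROC machinery, multi-model biomarker validation, and biomarker characterization.

Provides the ROC curve / AUC / Youden-index toolkit used throughout the
pipeline, the three-model (logistic regression, random forest, RBF-kernel
SVM) repeated cross-validation of a chosen biomarker set, random-forest
importance of panel members, and expression/correlation characterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .dataio import LipidFeatureTable
from .association import pearson_matrix
from .screening import welch_t

__all__ = [
    "RocCurve",
    "ValidationReport",
    "roc_auc",
    "youden_cutoff",
    "cutoff_curves",
    "evaluate_models",
    "rf_importance",
    "biomarker_characterization",
]


@dataclass
class RocCurve:
    """ROC sweep plus the raw scores/labels it was computed from.

    ``auc`` is the trapezoidal area, which equals the pairwise concordance
    probability with half credit for ties.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def youden_j(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC of continuous *scores* against binary *labels*."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if np.unique(labels).size != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, scores=scores, labels=labels)


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Cutoffs realizing every distinct classification under ``score >= c``.

    Midpoints between consecutive unique scores (so a perfect separator falls
    in the middle of the gap), plus the minimum score (everything positive)
    and a point above the maximum (everything negative).
    """
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    above = u[-1] + (u[-1] - u[0]) / 2.0 if u.size > 1 else u[-1] + 1.0
    return np.concatenate([[u[0]], mids, [above]])


def _confusion_metrics(scores, labels, cutoff, strict: bool = False):
    pred = scores > cutoff if strict else scores >= cutoff
    pos = labels == 1
    tp = np.sum(pred & pos)
    tn = np.sum(~pred & ~pos)
    sens = tp / max(pos.sum(), 1)
    spec = tn / max((~pos).sum(), 1)
    acc = (tp + tn) / labels.size
    return acc, sens, spec


def youden_cutoff(curve: RocCurve) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the higher (more specific) cutoff.  The rule is
    "positive iff score >= cutoff", with candidate cutoffs at midpoints
    between adjacent unique scores.
    """
    if curve.scores is None or curve.labels is None:
        raise ValueError("RocCurve lacks raw scores/labels")
    scores, labels = curve.scores, curve.labels
    best_c, best_j = None, -np.inf
    for c in _candidate_cutoffs(scores):
        _, sens, spec = _confusion_metrics(scores, labels, c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and (best_c is None or c > best_c)):
            best_c, best_j = float(c), float(j)
    return best_c, best_j


def cutoff_curves(scores, labels, step: float = 0.01) -> pd.DataFrame:
    """Accuracy / sensitivity / specificity over a [0, 1] cutoff grid (rule: score >= c)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    rows = [
        (c, *_confusion_metrics(scores, labels, c))
        for c in grid
    ]
    return pd.DataFrame(rows, columns=["cutoff", "accuracy", "sensitivity", "specificity"])


@dataclass
class ValidationReport:
    """Repeated-CV metric distributions per model plus characterization extras."""

    metrics: pd.DataFrame                 # model, repeat, fold, auc, sensitivity, specificity
    cutoff_tables: dict                   # model -> cutoff_curves DataFrame (full-data fit)
    rf_importance: pd.Series | None = None


def _make_models(X: np.ndarray, seed: int) -> dict:
    d = X.shape[1]
    mean_var = float(np.mean(X.var(axis=0))) or 1.0
    gamma = 1.0 / (d * mean_var)
    return {
        "LR": LogisticRegression(C=np.inf, max_iter=1000),
        "RF": RandomForestClassifier(n_estimators=500, random_state=seed % (2**31)),
        "SVM": SVC(kernel="rbf", C=1.0, gamma=gamma),
    }


def _model_scores(name, model, X_train, y_train, X_eval):
    """Continuous positive-class scores; the SVM decision value goes through a
    logistic link calibrated on the training fold (Platt scaling)."""
    if name == "SVM":
        model.fit(X_train, y_train)
        d_train = model.decision_function(X_train).reshape(-1, 1)
        link = LogisticRegression(max_iter=1000)
        link.fit(d_train, y_train)
        d_eval = model.decision_function(X_eval).reshape(-1, 1)
        return link.predict_proba(d_eval)[:, 1], link.predict_proba(d_train)[:, 1]
    model.fit(X_train, y_train)
    return model.predict_proba(X_eval)[:, 1], model.predict_proba(X_train)[:, 1]


def evaluate_models(
    X: pd.DataFrame | np.ndarray,
    y,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> ValidationReport:
    """Repeated stratified CV of LR, RF and RBF-SVM on the biomarker columns.

    Per held-out fold: the AUC of the fold's scores, and sensitivity and
    specificity at the Youden cutoff derived from the *training* predictions
    of that fold (the test fold never chooses its own cutoff).
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if Xa.shape[1] == 1:
        warnings.warn("validating a single biomarker", stacklevel=2)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed % (2**31))
    rows = []
    for split_i, (train, test) in enumerate(cv.split(Xa, y)):
        rep, fold = divmod(split_i, folds)
        for name, model in _make_models(Xa[train], seed).items():
            s_test, s_train = _model_scores(name, model, Xa[train], y[train], Xa[test])
            auc = roc_auc(s_test, y[test]).auc
            cut, _ = youden_cutoff(roc_auc(s_train, y[train]))
            _, sens, spec = _confusion_metrics(s_test, y[test], cut)
            rows.append({"model": name, "repeat": rep, "fold": fold,
                         "auc": auc, "sensitivity": sens, "specificity": spec})
    metrics = pd.DataFrame(rows)

    cutoff_tables = {}
    for name, model in _make_models(Xa, seed).items():
        s_all, _ = _model_scores(name, model, Xa, y, Xa)
        cutoff_tables[name] = cutoff_curves(s_all, y)
    report = ValidationReport(metrics=metrics, cutoff_tables=cutoff_tables)
    if isinstance(X, pd.DataFrame):
        report.rf_importance = rf_importance(X, y, seed=seed)
    return report


def rf_importance(X: pd.DataFrame, y, n_trees: int = 500, seed: int = 0) -> pd.Series:
    """Mean-decrease-in-impurity importance of each biomarker, normalized to sum 1."""
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31))
    rf.fit(X.to_numpy(dtype=float), np.asarray(y, float).ravel())
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=list(X.columns), name="importance")


def biomarker_characterization(table: LipidFeatureTable, biomarkers) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group expression summaries and pairwise correlation of panel members.

    Returns (summary, r, p): per-biomarker group medians/quartiles of log2
    expression with a Welch p-value, plus the pairwise Pearson matrices.
    Low |r| between panel members indicates low redundancy.
    """
    missing = [b for b in biomarkers if b not in set(table.feature_ids)]
    if missing:
        raise KeyError(f"biomarker(s) not in table: {missing}")
    sub = table.subset_features(biomarkers)
    vals = sub.abundances if table.scale == "log2" else np.log2(sub.abundances.where(sub.abundances > 0))
    case = sub.case_mask()
    rows = []
    for b in vals.columns:
        x = vals[b][case].dropna().to_numpy()
        yv = vals[b][~case].dropna().to_numpy()
        _, p = welch_t(x, yv)
        rows.append({
            "biomarker": b,
            "median_case": np.median(x), "q1_case": np.quantile(x, 0.25), "q3_case": np.quantile(x, 0.75),
            "median_control": np.median(yv), "q1_control": np.quantile(yv, 0.25), "q3_control": np.quantile(yv, 0.75),
            "welch_p": p,
        })
    summary = pd.DataFrame(rows).set_index("biomarker")
    r, p = pearson_matrix(vals)
    return summary, r, p
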