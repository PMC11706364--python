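"""The logistic diagnostic panel: fitting, scoring, classification, evaluation.

A panel is a logistic model over a small set of biomarker expression values
(log2 intensities): z = intercept + sum_j coef_j * x_j, p = 1/(1 + e^-z),
with a decision cutoff chosen by Youden's index on the training scores.  A
sample is called positive when p strictly exceeds the cutoff.

:func:`reference_panel` ships the published two-lipid PCOS panel
(PI (18:0/20:3)-H and PE (18:1p/22:6)-H) as a packaged constant for scoring
and demonstration; it is a fixture, not something refit from data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .modeling import RocCurve, roc_auc, youden_cutoff

__all__ = [
    "PanelModel",
    "fit_panel",
    "panel_score",
    "reference_panel",
    "classify",
    "evaluate_panel",
]


@dataclass
class PanelModel:
    intercept: float
    coefficients: dict  # feature_id -> coefficient
    cutoff: float
    converged: bool = True
    separation_flag: bool = False
    annotations: dict = field(default_factory=dict)

    def linear_predictor(self, x) -> np.ndarray:
        """z = intercept + sum_j coef_j * x_j for one sample (mapping/Series) or a DataFrame."""
        if isinstance(x, pd.DataFrame):
            missing = [f for f in self.coefficients if f not in x.columns]
            if missing:
                raise KeyError(f"missing biomarker column(s): {missing}")
            z = np.full(len(x), self.intercept, dtype=float)
            for f, b in self.coefficients.items():
                z += b * x[f].to_numpy(dtype=float)
            return z
        z = self.intercept
        for f, b in self.coefficients.items():
            if f not in x:
                raise KeyError(f"missing biomarker value: {f}")
            z += b * float(x[f])
        return np.float64(z)


def panel_score(model: PanelModel, x):
    """Diagnostic probability p = 1 / (1 + e^-z)."""
    z = model.linear_predictor(x)
    return 1.0 / (1.0 + np.exp(-z))


def classify(model: PanelModel, x):
    """Positive iff p strictly exceeds the cutoff ("exceeded" => strict inequality)."""
    p = panel_score(model, x)
    pos = p > model.cutoff
    if np.ndim(pos) == 0:
        return "positive" if pos else "negative"
    return np.where(pos, "positive", "negative")


def fit_panel(X_train: pd.DataFrame, y_train) -> PanelModel:
    """Maximum-likelihood logistic fit of the panel (Newton, tol 1e-8, <= 100 iterations).

    The decision cutoff is then set by Youden's index on the training scores.
    Complete separation is flagged (coefficients kept at the iteration cap)
    rather than raised.
    """
    y = np.asarray(y_train, float).ravel()
    if np.unique(y).size != 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 samples per class")
    exog = sm.add_constant(X_train.to_numpy(dtype=float), has_constant="add")
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
            params = res.params
        except Exception:
            # Newton blows up under complete separation; cap the coefficients
            # with a barely-regularized fit instead of failing.
            from sklearn.linear_model import LogisticRegression

            capped = LogisticRegression(C=1e4, max_iter=500)
            capped.fit(X_train.to_numpy(dtype=float), y)
            params = np.concatenate([capped.intercept_, capped.coef_[0]])
            separation = True
            converged = False
    if not separation and np.linalg.norm(params) > 1e3:
        separation = True
    if separation:
        warnings.warn("possible complete separation: coefficients capped", stacklevel=2)
    coefs = {f: float(b) for f, b in zip(X_train.columns, params[1:])}
    model = PanelModel(intercept=float(params[0]), coefficients=coefs, cutoff=0.5,
                       converged=converged, separation_flag=separation)
    train_scores = panel_score(model, X_train)
    cutoff, _ = youden_cutoff(roc_auc(train_scores, y))
    model.cutoff = float(np.clip(cutoff, 1e-9, 1 - 1e-9))
    return model


def reference_panel() -> PanelModel:
    """The published two-lipid PCOS diagnostic panel, verbatim.

    z = -19.62541206 + 2.249933588 * x(1033NEG) + 0.634268314 * x(877NEG),
    cutoff 0.83, where 1033NEG is PI (18:0/20:3)-H and 877NEG is
    PE (18:1p/22:6)-H.
    """
    return PanelModel(
        intercept=-19.62541206,
        coefficients={"1033NEG": 2.249933588, "877NEG": 0.634268314},
        cutoff=0.83,
        annotations={"1033NEG": "PI (18:0/20:3)-H", "877NEG": "PE (18:1p/22:6)-H"},
    )


def evaluate_panel(model: PanelModel, X_test: pd.DataFrame, y_test) -> dict:
    """Test-set evaluation at the frozen training-derived cutoff.

    Returns the ROC curve/AUC over the continuous panel scores and accuracy,
    sensitivity and specificity of the strict `p > cutoff` classification.
    """
    y = np.asarray(y_test, float).ravel()
    if np.unique(y).size != 2:
        raise ValueError("test set must contain both classes")
    scores = panel_score(model, X_test)
    curve: RocCurve = roc_auc(scores, y)
    pred = scores > model.cutoff
    pos = y == 1
    tp = np.sum(pred & pos)
    tn = np.sum(~pred & ~pos)
    return {
        "roc": curve,
        "auc": curve.auc,
        "accuracy": float((tp + tn) / y.size),
        "sensitivity": float(tp / pos.sum()),
        "specificity": float(tn / (~pos).sum()),
        "cutoff": model.cutoff,
    }
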