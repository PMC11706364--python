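"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

Implements the orthogonal-projections-to-latent-structures decomposition for
a single binary response: class-orthogonal variation is iteratively removed
from X, then one predictive PLS component is fitted on the filtered matrix.
Supplies R2Y (explained class variance), cross-validated Q2 (predictive
ability), VIP scores normalized so that the mean squared VIP is 1, and a
label-permutation validity test.

All routines operate on a numeric matrix; :func:`fit_oplsda` accepts either a
numpy array or a pandas DataFrame (feature names are then carried through to
the VIP vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "OplsdaModel",
    "PermutationResult",
    "fit_oplsda",
    "predict",
    "compute_vip",
    "cross_validated_q2",
    "permutation_test",
    "top_vip",
]


@dataclass
class PermutationResult:
    n_permutations: int
    permuted_q2: np.ndarray
    permuted_r2y: np.ndarray
    observed_q2: float
    observed_r2y: float
    p_q2: float


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA decomposition (one predictive, ``n_ortho`` orthogonal components)."""

    weights: np.ndarray          # predictive weight vector w (p,)
    loadings: np.ndarray         # predictive loading vector p (p,)
    scores: np.ndarray           # predictive scores t (n,)
    c: float                     # regression of encoded y on t
    ortho_weights: np.ndarray    # (p, n_ortho)
    ortho_loadings: np.ndarray   # (p, n_ortho)
    ortho_scores: np.ndarray     # (n, n_ortho)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2y: float
    feature_names: list | None = None
    kept: np.ndarray | None = None   # boolean mask of non-constant features
    q2: float | None = None
    vip: np.ndarray | None = field(default=None)
    permutation: PermutationResult | None = None

    @property
    def n_ortho(self) -> int:
        return self.ortho_weights.shape[1]


def _prepare(X, y, scale: str):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        names = None
        Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if Xa.shape[0] != ya.size:
        raise ValueError("X and y lengths differ")
    classes = np.unique(ya)
    if classes.size != 2:
        raise ValueError("y must be binary")
    if min((ya == c).sum() for c in classes) < 3:
        raise ValueError("need at least 3 samples per class")
    if Xa.shape[1] < 2:
        raise ValueError("need at least 2 features")
    sd = Xa.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {(~kept).sum()} constant feature(s)", stacklevel=3)
        Xa = Xa[:, kept]
        sd = sd[kept]
        if names is not None:
            names = [n for n, k in zip(names, kept) if k]
    mean = Xa.mean(axis=0)
    if scale == "uv":
        sc = sd
    elif scale == "pareto":
        sc = np.sqrt(sd)
    elif scale in (None, "none"):
        sc = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scale!r}")
    Xc = (Xa - mean) / sc
    y_mean = ya.mean()
    yc = ya - y_mean
    return Xc, yc, mean, sc, y_mean, names, kept


def _opls_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Trygg-Wold style O-PLS for a single response on preprocessed data."""
    n, p = Xc.shape
    if n_ortho >= min(n - 1, p):
        raise ValueError(f"n_ortho={n_ortho} too large for a {n}x{p} matrix")
    Xf = Xc.copy()
    yy = float(yc @ yc)
    if yy == 0:
        raise ValueError("y has no variance")
    Wo = np.zeros((p, n_ortho))
    Po = np.zeros((p, n_ortho))
    To = np.zeros((n, n_ortho))
    for a in range(n_ortho):
        w = Xf.T @ yc
        w /= np.linalg.norm(w)
        t = Xf @ w
        pl = Xf.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:  # no orthogonal variation left
            Wo, Po, To = Wo[:, :a], Po[:, :a], To[:, :a]
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        Wo[:, a], Po[:, a], To[:, a] = w_o, p_o, t_o
    w = Xf.T @ yc
    w /= np.linalg.norm(w)
    t = Xf @ w
    pl = Xf.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    resid = yc - c * t
    r2y = 1.0 - float(resid @ resid) / yy
    return w, pl, t, c, Wo, Po, To, max(0.0, min(1.0, r2y))


def fit_oplsda(X, y, n_ortho: int = 1, scale: str = "uv") -> OplsdaModel:
    """Fit an OPLS-DA model of binary *y* on *X*.

    X is centered and (by default) unit-variance scaled internally; the
    centering/scaling vectors are stored on the model so new samples can be
    projected.  Constant features are dropped with a warning.
    """
    Xc, yc, mean, sc, y_mean, names, kept = _prepare(X, y, scale)
    w, pl, t, c, Wo, Po, To, r2y = _opls_core(Xc, yc, n_ortho)
    model = OplsdaModel(
        weights=w, loadings=pl, scores=t, c=c,
        ortho_weights=Wo, ortho_loadings=Po, ortho_scores=To,
        x_mean=mean, x_scale=sc, y_mean=y_mean, r2y=r2y,
        feature_names=names, kept=kept,
    )
    model.vip = compute_vip(model)
    return model


def predict(model: OplsdaModel, X) -> np.ndarray:
    """Continuous class prediction for new samples (same preprocessing as fit)."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, float)
    if model.kept is not None and X.shape[1] == model.kept.size:
        X = X[:, model.kept]
    Xc = (X - model.x_mean) / model.x_scale
    for a in range(model.n_ortho):
        t_o = Xc @ model.ortho_weights[:, a]
        Xc = Xc - np.outer(t_o, model.ortho_loadings[:, a])
    t = Xc @ model.weights
    return model.c * t + model.y_mean


def compute_vip(model: OplsdaModel) -> np.ndarray:
    """Variable importance for the projection over the predictive component.

    With a single predictive component the sum-of-squares weights cancel and
    VIP_j = sqrt(p) * |w_j| / ||w||, so that sum(VIP^2) = n_features.
    """
    w = np.asarray(model.weights, float)
    if w.size == 0:
        raise ValueError("model has no fitted weights")
    p = w.size
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)


def cross_validated_q2(
    X, y, n_ortho: int = 1, folds: int = 7, seed: int = 0, scale: str = "uv"
) -> float:
    """Q2 = 1 - PRESS/SS from stratified k-fold cross-validation.

    PRESS accumulates out-of-fold squared error of the encoded class variable;
    SS accumulates squared deviation of held-out y from the training-fold mean.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, float)
    ya = np.asarray(y, float).ravel()
    counts = min(np.sum(ya == c) for c in np.unique(ya))
    folds = min(folds, int(counts))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    press = ss = 0.0
    for train, test in skf.split(X, ya):
        model = fit_oplsda(X[train], ya[train], n_ortho=n_ortho, scale=scale)
        Xt = X[test]
        if model.kept is not None and not model.kept.all():
            Xt = Xt[:, model.kept]
            yhat = _predict_kept(model, Xt)
        else:
            yhat = predict(model, Xt)
        press += float(np.sum((ya[test] - yhat) ** 2))
        ss += float(np.sum((ya[test] - ya[train].mean()) ** 2))
    return 1.0 - press / ss


def _predict_kept(model: OplsdaModel, X_kept: np.ndarray) -> np.ndarray:
    Xc = (X_kept - model.x_mean) / model.x_scale
    for a in range(model.n_ortho):
        t_o = Xc @ model.ortho_weights[:, a]
        Xc = Xc - np.outer(t_o, model.ortho_loadings[:, a])
    return model.c * (Xc @ model.weights) + model.y_mean


def permutation_test(
    X, y, n_ortho: int = 1, n_permutations: int = 100, seed: int = 0,
    folds: int = 7, scale: str = "uv",
) -> PermutationResult:
    """Label-permutation validity test of the OPLS-DA model.

    The class labels are permuted uniformly *n_permutations* times and Q2 and
    R2Y recomputed each time; the permutation p-value is

        p_q2 = (#{permuted Q2 >= observed Q2} + 1) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, float)
    ya = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    obs_q2 = cross_validated_q2(X, ya, n_ortho=n_ortho, folds=folds, seed=seed, scale=scale)
    obs_r2y = fit_oplsda(X, ya, n_ortho=n_ortho, scale=scale).r2y
    perm_q2 = np.empty(n_permutations)
    perm_r2y = np.empty(n_permutations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_permutations):
            yp = rng.permutation(ya)
            cv_seed = int(rng.integers(0, 2**31 - 1))
            perm_q2[i] = cross_validated_q2(X, yp, n_ortho=n_ortho, folds=folds, seed=cv_seed, scale=scale)
            perm_r2y[i] = fit_oplsda(X, yp, n_ortho=n_ortho, scale=scale).r2y
    p_q2 = (float(np.sum(perm_q2 >= obs_q2)) + 1.0) / (n_permutations + 1.0)
    return PermutationResult(
        n_permutations=n_permutations, permuted_q2=perm_q2, permuted_r2y=perm_r2y,
        observed_q2=obs_q2, observed_r2y=obs_r2y, p_q2=p_q2,
    )


def top_vip(model: OplsdaModel, k: int = 20) -> pd.Series:
    """The *k* features with largest VIP, descending; ties keep feature order.

    Returns a Series indexed by feature name (or positional index when the
    model was fitted on a bare array).
    """
    vip = model.vip if model.vip is not None else compute_vip(model)
    names = model.feature_names or list(range(vip.size))
    if k > vip.size:
        warnings.warn(f"k={k} exceeds {vip.size} features; returning all", stacklevel=2)
        k = vip.size
    order = np.argsort(-vip, kind="stable")[:k]
    return pd.Series(vip[order], index=[names[i] for i in order], name="vip")
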