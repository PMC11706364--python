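"""Ensemble feature weighting and AUC-accumulation panel selection.

The candidate biomarkers (union of the volcano-screen hits and the top-20
VIP features) are re-ranked by a battery of feature selectors; features that
are consistently highly ranked are rewarded.  Rank-based selectors contribute
a Borda reward (n - rank + 1)/n in [0, 1]; frequency-based selectors (L1
selection frequency over bootstrap resamples) contribute their frequency
directly.  The comprehensive weight of a feature is the mean reward across
selectors.  The panel size is then chosen from the cumulative-AUC curve of a
logistic model on the top-k features: accumulation stops at the first k whose
marginal cross-validated AUC gain falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .dataio import normalize_feature_id
from .screening import standardized_u, welch_t

__all__ = [
    "SelectorRanking",
    "AucAccumulation",
    "candidate_pool",
    "run_selectors",
    "comprehensive_weight",
    "auc_accumulation",
    "select_panel",
]


@dataclass
class SelectorRanking:
    """One selector's verdict: 1-based ranks (kind='rank') or [0,1] scores (kind='score')."""

    name: str
    kind: str  # 'rank' | 'score'
    values: pd.Series


@dataclass
class AucAccumulation:
    ordered_features: list
    cumulative_auc: list
    selected_k: int
    delta: float


def _feature_sort_key(fid) -> tuple:
    try:
        idx, mode = normalize_feature_id(str(fid))
        return (0, idx, mode)
    except ValueError:
        return (1, 0, str(fid))


def candidate_pool(screen: pd.DataFrame, vip: pd.Series, top_k_vip: int = 20) -> list:
    """Union of volcano passes and the top-k VIP features, in stable feature order."""
    passes = list(screen.index[screen["passes"].astype(bool)])
    top = list(vip.sort_values(ascending=False, kind="stable").index[:top_k_vip])
    pool = set(passes) | set(top)
    ordered = [f for f in screen.index if f in pool]
    extras = [f for f in top if f not in set(ordered)]
    if not ordered and not extras:
        raise ValueError(
            "candidate set is empty: relax the volcano thresholds or the VIP cut"
        )
    return ordered + extras


def _ranks_from_scores(scores: pd.Series) -> pd.Series:
    """1-based ranks, rank 1 = highest score; ties keep the input (feature) order."""
    order = np.argsort(-scores.to_numpy(), kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return pd.Series(ranks, index=scores.index)


def run_selectors(
    X: pd.DataFrame,
    y: np.ndarray,
    vip: pd.Series,
    screen: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    n_bootstrap: int = 50,
) -> list[SelectorRanking]:
    """Run the six-selector battery on the candidate matrix *X* (training split only).

    Selectors: |Welch t|, |standardized Mann-Whitney U|, |log2 fold change|,
    VIP, random-forest impurity importance, and selection frequency of an
    L1-penalized logistic model over bootstrap resamples.
    """
    if X.shape[1] == 0:
        raise ValueError("candidate set is empty")
    y = np.asarray(y, float).ravel()
    case = y == 1
    feats = list(X.columns)

    t_scores = pd.Series(
        [abs(welch_t(X[f][case], X[f][~case])[0]) for f in feats], index=feats
    )
    u_scores = pd.Series(
        [abs(standardized_u(X[f][case], X[f][~case])) for f in feats], index=feats
    )
    fc_scores = screen.loc[feats, "log2_fc"].abs().fillna(0.0)
    vip_scores = vip.reindex(feats).fillna(0.0)

    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31))
    rf.fit(X.to_numpy(), y)
    rf_scores = pd.Series(rf.feature_importances_, index=feats)

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(feats))
    idx_case = np.flatnonzero(case)
    idx_ctrl = np.flatnonzero(~case)
    for _ in range(n_bootstrap):
        boot = np.concatenate(
            [rng.choice(idx_case, idx_case.size), rng.choice(idx_ctrl, idx_ctrl.size)]
        )
        lasso = LogisticRegression(
            l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed % (2**31)
        )
        lasso.fit(X.to_numpy()[boot], y[boot])
        counts += (np.abs(lasso.coef_[0]) > 1e-8).astype(float)
    freq = pd.Series(counts / n_bootstrap, index=feats)

    return [
        SelectorRanking("welch_t", "rank", _ranks_from_scores(t_scores)),
        SelectorRanking("mann_whitney_u", "rank", _ranks_from_scores(u_scores)),
        SelectorRanking("log2_fc", "rank", _ranks_from_scores(fc_scores)),
        SelectorRanking("vip", "rank", _ranks_from_scores(vip_scores)),
        SelectorRanking("rf_importance", "rank", _ranks_from_scores(rf_scores)),
        SelectorRanking("l1_frequency", "score", freq),
    ]


def comprehensive_weight(rankings: list[SelectorRanking]) -> pd.DataFrame:
    """Aggregate selector verdicts into the comprehensive weight table.

    Rank selectors reward (n - rank + 1)/n; score selectors pass their score
    through.  The weight is the mean reward; final ranks are 1-based by
    descending weight with ties broken toward the lower feature index.
    """
    if not rankings:
        raise ValueError("no selector rankings given")
    idx = rankings[0].values.index
    for r in rankings[1:]:
        if set(r.values.index) != set(idx):
            raise ValueError(f"selector {r.name!r} covers a different candidate set")
    n = len(idx)
    table = pd.DataFrame(index=idx)
    for r in rankings:
        if r.kind == "rank":
            table[f"reward_{r.name}"] = (n - r.values.reindex(idx) + 1) / n
        elif r.kind == "score":
            table[f"reward_{r.name}"] = r.values.reindex(idx)
        else:
            raise ValueError(f"unknown selector kind {r.kind!r}")
    table["weight"] = table.mean(axis=1)
    sort_keys = sorted(
        range(n), key=lambda i: (-table["weight"].iloc[i], _feature_sort_key(idx[i]))
    )
    ranks = np.empty(n, dtype=int)
    for pos, i in enumerate(sort_keys):
        ranks[i] = pos + 1
    table["rank"] = ranks
    return table.sort_values("rank")


def auc_accumulation(
    X: pd.DataFrame,
    y: np.ndarray,
    weights: pd.DataFrame,
    delta: float = 0.01,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    max_k: int = 10,
) -> AucAccumulation:
    """Cumulative cross-validated AUC of a logistic model on the top-k features.

    selected_k is the smallest k whose marginal gain to k+1 falls below
    *delta* (or the number of evaluated features if the gains never do).
    """
    ordered = list(weights.sort_values("rank").index)
    if not ordered:
        raise ValueError("no candidate features")
    y = np.asarray(y, float).ravel()
    K = min(len(ordered), max_k)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed % (2**31))
    aucs = []
    for k in range(1, K + 1):
        Xi = X[ordered[:k]].to_numpy()
        fold_aucs = []
        for train, test in cv.split(Xi, y):
            lr = LogisticRegression(C=np.inf, max_iter=1000)
            lr.fit(Xi[train], y[train])
            fold_aucs.append(roc_auc_score(y[test], lr.predict_proba(Xi[test])[:, 1]))
        aucs.append(float(np.mean(fold_aucs)))
    selected_k = K
    for k in range(1, K):
        if aucs[k] - aucs[k - 1] < delta:
            selected_k = k
            break
    return AucAccumulation(
        ordered_features=ordered[:K], cumulative_auc=aucs, selected_k=selected_k, delta=delta
    )


def select_panel(acc: AucAccumulation) -> list:
    """The biomarker panel: the selected_k heaviest candidates, descending weight."""
    return list(acc.ordered_features[: acc.selected_k])
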