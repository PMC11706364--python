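"""Lipid-class / clinical-index association analyses: Mantel tests and Pearson matrices.

Differential lipids are aggregated into per-class profiles; each class
profile is related to each clinical index through a Mantel test (distance
matrix correlation with a permutation p-value), and classes or individual
features are related to each other through Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import LipidFeatureTable
from .screening import bh_adjust

__all__ = [
    "class_aggregate",
    "mantel_test",
    "class_clinical_mantel",
    "pearson_matrix",
]


def class_aggregate(table: LipidFeatureTable, feature_ids=None) -> pd.DataFrame:
    """Samples x lipid-classes profile matrix.

    For each class, member features' log2 intensities are summed per sample
    and the column standardized (mean 0, SD 1 with ddof=1).  Classes with no
    member features are omitted.  Typically called on the differential
    feature set only.
    """
    if table.scale != "log2":
        raise ValueError("class_aggregate expects a log2-scale table")
    sub = table if feature_ids is None else table.subset_features(feature_ids)
    cols = {}
    for cls, meta in sub.feature_meta.groupby("lipid_class", sort=True):
        prof = sub.abundances[list(meta.index)].sum(axis=1)
        sd = prof.std(ddof=1)
        if sd == 0:
            warnings.warn(f"class {cls!r} profile is constant; omitted", stacklevel=2)
            continue
        cols[cls] = (prof - prof.mean()) / sd
    return pd.DataFrame(cols, index=sub.abundances.index)


def _check_distance_matrix(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if d.shape[0] < 4:
        raise ValueError(f"{name} must be at least 4x4")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel_test(
    d1, d2, n_permutations: int = 999, seed: int = 0, exact: bool = False
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    r is computed over strictly-lower-triangle entries; significance is
    two-sided on |r| under simultaneous row/column permutation of *d2*:
    p = (#{|r_perm| >= |r|} + 1) / (n_permutations + 1).  With ``exact=True``
    (n <= 7) all n! permutations are enumerated and p = #{|r_perm| >= |r|}/n!.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    _check_distance_matrix(d1, "d1")
    _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same shape")
    n = d1.shape[0]
    tri = np.tril_indices(n, k=-1)
    v1 = d1[tri]
    if v1.std() == 0 or d2[tri].std() == 0:
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(v1, d2[tri])[0, 1])

    def perm_r(perm) -> float:
        dp = d2[np.ix_(perm, perm)]
        return float(np.corrcoef(v1, dp[tri])[0, 1])

    if exact:
        if n > 7:
            raise ValueError("exact enumeration limited to n <= 7")
        count = sum(
            abs(perm_r(list(perm))) >= abs(r_obs) - 1e-12
            for perm in itertools.permutations(range(n))
        )
        return r_obs, count / math.factorial(n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if abs(perm_r(rng.permutation(n))) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, (count + 1) / (n_permutations + 1)


def class_clinical_mantel(
    profiles: pd.DataFrame,
    clinical: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """One Mantel record per (lipid class, clinical index) pair.

    d1 is the Euclidean distance on the class-profile column, d2 the absolute
    difference on the clinical index; samples missing the index are dropped
    (>= 4 required).  BH-adjusted p across all tested pairs is appended.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls in profiles.columns:
        for idx in clinical.columns:
            vals = pd.to_numeric(clinical[idx], errors="coerce")
            ok = vals.notna()
            if ok.sum() < 4:
                warnings.warn(f"index {idx!r}: fewer than 4 observations; skipped", stacklevel=2)
                continue
            prof = profiles.loc[ok.to_numpy(), cls].to_numpy()
            x = vals[ok].to_numpy()
            d1 = np.abs(prof[:, None] - prof[None, :])
            d2 = np.abs(x[:, None] - x[None, :])
            if d2.std() == 0 or d1.std() == 0:
                rows.append({"lipid_class": cls, "index": idx, "r": np.nan, "p": np.nan,
                             "status": "degenerate"})
                continue
            r, p = mantel_test(d1, d2, n_permutations=n_permutations,
                               seed=int(rng.integers(0, 2**31 - 1)))
            rows.append({"lipid_class": cls, "index": idx, "r": r, "p": p, "status": "ok"})
    out = pd.DataFrame(rows)
    if not out.empty:
        ok = out["status"] == "ok"
        out["p_adjusted"] = np.nan
        if ok.any():
            out.loc[ok, "p_adjusted"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def pearson_matrix(A: pd.DataFrame, B: pd.DataFrame | None = None):
    """Pairwise Pearson r (and two-sided p) between columns of A and B.

    Correlations use complete observations per pair (>= 3 required); pairs
    involving a zero-variance column are reported as NaN.  Returns
    ``(r, p)`` DataFrames with A's columns as rows and B's as columns.
    """
    if B is None:
        B = A
    r = pd.DataFrame(np.nan, index=A.columns, columns=B.columns)
    p = pd.DataFrame(np.nan, index=A.columns, columns=B.columns)
    for ca in A.columns:
        for cb in B.columns:
            x = pd.to_numeric(A[ca], errors="coerce")
            y = pd.to_numeric(B[cb], errors="coerce")
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if xv.std() == 0 or yv.std() == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.pearsonr(xv, yv)
            r.loc[ca, cb] = res.statistic
            p.loc[ca, cb] = res.pvalue
    return r, p
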