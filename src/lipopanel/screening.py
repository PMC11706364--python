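"""Univariate screening: group tests, fold changes, BH adjustment, volcano filter.

The volcano rule defining a "differential lipid metabolite" is

    fold change > 2  or  fold change < 0.5,   and   adjusted p < 0.05

with the fold change computed on raw-scale group means (case / control) and
the p-value from a per-feature two-sample test on log2 intensities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import LipidFeatureTable

__all__ = [
    "welch_t",
    "mann_whitney",
    "bh_adjust",
    "apply_volcano_rule",
    "volcano_screen",
    "clinical_table",
]

FC_UP = 2.0
FC_DOWN = 0.5
ALPHA = 0.05


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t test.

    Degenerate case: zero variance in both groups with equal means returns
    ``(0.0, 1.0)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf * np.sign(x.mean() - y.mean()), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration for small tie-free samples (both n <= 20), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def standardized_u(x, y) -> float:
    """Standardized Mann-Whitney statistic z = (U - nm/2) / sd(U); sign = direction of x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    u, _ = mann_whitney(x, y)
    mean_u = n * m / 2.0
    sd_u = np.sqrt(n * m * (n + m + 1) / 12.0)
    return float((u - mean_u) / sd_u) if sd_u > 0 else 0.0


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p) -> np.ndarray:
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def apply_volcano_rule(fold_change, adjusted_p) -> np.ndarray:
    """The differential-lipid filter: (FC > 2 or FC < 0.5) and adjusted p < 0.05.

    Inequalities are strict; an undefined (NaN) fold change never passes.
    """
    fc = np.asarray(fold_change, float)
    ap = np.asarray(adjusted_p, float)
    with np.errstate(invalid="ignore"):
        return ((fc > FC_UP) | (fc < FC_DOWN)) & (ap < ALPHA) & np.isfinite(fc)


def _group_arrays(table: LipidFeatureTable):
    case = table.case_mask()
    if case.all() or not case.any():
        raise ValueError("both groups must be present")
    return table.abundances.loc[case], table.abundances.loc[~case]


def volcano_screen(
    table: LipidFeatureTable, test: str = "welch", adjust: str = "bh"
) -> pd.DataFrame:
    """Per-feature univariate screen of case (EG) vs control (CG).

    Fold change is the ratio of raw-scale group means (case / control);
    p-values come from *test* ("welch" or "mannwhitney") applied to log2
    intensities.  Works on raw tables (log2 taken internally) and on
    log2-scale tables (raw means recovered as means of ``2**x``).

    Returns a DataFrame indexed by feature id with columns mean_case,
    mean_control, fold_change, log2_fc, p_value, adjusted_p, passes.
    """
    Xc, Xg = _group_arrays(table)
    if table.scale == "log2":
        raw_case, raw_ctrl = np.exp2(Xc), np.exp2(Xg)
        log_case, log_ctrl = Xc, Xg
    else:
        raw_case, raw_ctrl = Xc, Xg
        with np.errstate(divide="ignore"):
            log_case = np.log2(Xc.where(Xc > 0))
            log_ctrl = np.log2(Xg.where(Xg > 0))
    mean_case = np.nanmean(raw_case, axis=0)
    mean_ctrl = np.nanmean(raw_ctrl, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctrl > 0, mean_case / mean_ctrl, np.nan)
        log2_fc = np.log2(fc)

    a = log_case.to_numpy()
    b = log_ctrl.to_numpy()
    if test == "welch":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
        pvals = np.asarray(res.pvalue, float)
    elif test == "mannwhitney":
        pvals = np.empty(a.shape[1])
        for j in range(a.shape[1]):
            xj = a[:, j][~np.isnan(a[:, j])]
            yj = b[:, j][~np.isnan(b[:, j])]
            pvals[j] = mann_whitney(xj, yj)[1]
    else:
        raise ValueError(f"unknown test {test!r}")
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    if adjust == "bh":
        adj = bh_adjust(pvals)
    elif adjust == "bonferroni":
        adj = bonferroni_adjust(pvals)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "adjusted_p": adj,
            "passes": apply_volcano_rule(fc, adj),
        },
        index=table.feature_ids,
    )


def clinical_table(table: LipidFeatureTable) -> pd.DataFrame:
    """Per-clinical-index group comparison: mean/min/max per group plus Welch t.

    Mirrors the clinical-characteristics table of a case/control study
    (average with minimum and maximum, Welch-corrected t).
    """
    case = table.case_mask()
    rows = []
    clinical_cols = [c for c in table.sample_meta.columns if c != "group"]
    for col in clinical_cols:
        vals = pd.to_numeric(table.sample_meta[col], errors="coerce")
        x = vals[case].dropna().to_numpy()
        y = vals[~case].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            warnings.warn(f"clinical index {col!r} skipped (too few observations)", stacklevel=2)
            continue
        t, p = welch_t(x, y)
        rows.append(
            {
                "index": col,
                "mean_case": x.mean(), "min_case": x.min(), "max_case": x.max(),
                "mean_control": y.mean(), "min_control": y.min(), "max_control": y.max(),
                "welch_t": t, "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("index") if rows else pd.DataFrame()
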