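"""Missing-value handling, log transformation, and the stratified train/test split."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataio import LipidFeatureTable

__all__ = ["impute_and_log", "split_train_test"]


def impute_and_log(table: LipidFeatureTable, drop_missing_frac: float = 0.5) -> LipidFeatureTable:
    """Drop heavily-missing features, impute the rest, and log2-transform.

    A feature is dropped when it is missing in more than *drop_missing_frac*
    of the samples in **both** groups.  Remaining missing values (and exact
    zeros, which have no log) are imputed with half the feature's minimum
    observed positive value — the standard detection-limit surrogate in
    metabolomics.  The returned table carries ``scale="log2"``.
    """
    if table.scale != "raw":
        raise ValueError("impute_and_log expects a raw-scale table")
    ab = table.abundances.where(table.abundances > 0)  # zeros treated as below detection
    case = table.case_mask()
    miss = ab.isna()
    frac_case = miss.loc[case].mean(axis=0) if case.any() else pd.Series(0.0, index=ab.columns)
    frac_ctrl = miss.loc[~case].mean(axis=0) if (~case).any() else pd.Series(0.0, index=ab.columns)
    keep = ~((frac_case > drop_missing_frac) & (frac_ctrl > drop_missing_frac))
    all_missing = miss.all(axis=0)
    keep &= ~all_missing
    dropped = list(ab.columns[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} feature(s) for excess missingness", stacklevel=2)
    ab = ab.loc[:, keep]
    half_min = ab.min(axis=0) / 2.0
    ab = ab.fillna(half_min)
    out = np.log2(ab)
    return LipidFeatureTable(
        out, table.feature_meta.loc[out.columns].copy(), table.sample_meta.copy(), scale="log2"
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(
    table: LipidFeatureTable, test_fraction: float = 0.25, seed: int = 0
) -> tuple[LipidFeatureTable, LipidFeatureTable]:
    """Group-stratified split; per-group test counts are round(test_fraction * n).

    Rounding is half-up, so 50 controls at 0.25 give 13 test controls.  The
    partition is disjoint and exhaustive, and deterministic given *seed*.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    groups = table.groups
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for g in ("CG", "EG"):
        ids = np.asarray(table.abundances.index[groups == g])
        if ids.size < 4:
            raise ValueError(f"group {g} has fewer than 4 samples")
        n_test = _round_half_up(test_fraction * ids.size)
        n_test = min(max(n_test, 1), ids.size - 1)
        perm = rng.permutation(ids.size)
        test_ids.extend(ids[perm[:n_test]])
    test_set = set(test_ids)
    train_ids = [s for s in table.sample_ids if s not in test_set]
    test_ids = [s for s in table.sample_ids if s in test_set]
    return table.subset_samples(train_ids), table.subset_samples(test_ids)
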