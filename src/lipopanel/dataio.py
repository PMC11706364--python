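"""Core data model and tabular I/O for serum lipidomics feature tables.

The central container is :class:`LipidFeatureTable`: a samples x features
intensity matrix plus per-feature metadata (ion mode, lipid class, annotation)
and per-sample metadata (case/control group and clinical indexes).  Feature
identifiers follow the ``<index><POS|NEG>`` convention of untargeted
lipidomics exports (e.g. ``"1033NEG"``); the prefixed dialect ``"NEG1033"``
is accepted on input and normalized to the suffix form.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LIPID_CLASSES",
    "ION_MODES",
    "GROUPS",
    "CLINICAL_INDEXES",
    "LipidFeatureTable",
    "normalize_feature_id",
    "render_feature_id",
    "read_feature_table",
    "write_feature_table",
]

LIPID_CLASSES = ("TG", "PC", "PE", "PI", "PS", "LPC", "LPE", "SM", "DG", "MGDG", "other")
ION_MODES = ("POS", "NEG")
#: EG = experimental group (PCOS cases), CG = control group.
GROUPS = ("EG", "CG")
CLINICAL_INDEXES = ("Age", "Height", "Weight", "BMI", "LH", "FSH", "LH/FSH", "P", "PRL", "T", "E2")

_PREFIX_RE = re.compile(r"^(POS|NEG)(\d+)$", re.IGNORECASE)
_SUFFIX_RE = re.compile(r"^(\d+)(POS|NEG)$", re.IGNORECASE)


def normalize_feature_id(raw: str) -> tuple[int, str]:
    """Parse a feature identifier into ``(index, ion_mode)``.

    Both dialects seen in lipidomics exports are accepted: the suffix form
    ``"1033NEG"`` and the prefix form ``"NEG1033"``, case-insensitively.

    >>> normalize_feature_id("28POS")
    (28, 'POS')
    >>> normalize_feature_id("NEG877")
    (877, 'NEG')
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("feature id must be a non-empty string")
    s = raw.strip()
    m = _SUFFIX_RE.match(s) or _PREFIX_RE.match(s)
    if m is None:
        raise ValueError(
            f"cannot parse feature id {raw!r}: expected '<integer><POS|NEG>' or '<POS|NEG><integer>'"
        )
    a, b = m.groups()
    if a.isdigit():
        index, mode = int(a), b.upper()
    else:
        index, mode = int(b), a.upper()
    return index, mode


def render_feature_id(index: int, ion_mode: str) -> str:
    """Render the canonical suffix form, e.g. ``render_feature_id(1033, "NEG") == "1033NEG"``."""
    mode = ion_mode.upper()
    if mode not in ION_MODES:
        raise ValueError(f"unknown ion mode {ion_mode!r}")
    return f"{int(index)}{mode}"


def canonical_feature_id(raw: str) -> str:
    """Normalize any accepted dialect to the canonical suffix rendering."""
    return render_feature_id(*normalize_feature_id(raw))


@dataclass
class LipidFeatureTable:
    """Samples x features intensity matrix with aligned metadata.

    Parameters
    ----------
    abundances
        DataFrame indexed by sample id with one column per feature id.
        Missing values are NaN, never 0.  On the raw scale all observed
        values must be non-negative.
    feature_meta
        DataFrame indexed by feature id with columns ``annotation``,
        ``lipid_class`` and ``ion_mode``.
    sample_meta
        DataFrame indexed by sample id with a ``group`` column (``"EG"`` for
        cases, ``"CG"`` for controls) and optional clinical index columns.
    scale
        ``"raw"`` for intensities, ``"log2"`` after log transformation.
    """

    abundances: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.abundances = self.abundances.astype(float)
        if self.abundances.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        canon = [canonical_feature_id(c) for c in self.abundances.columns]
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise ValueError(f"duplicate feature ids after normalization: {dupes}")
        self.abundances.columns = canon
        self.feature_meta = self.feature_meta.copy()
        self.feature_meta.index = [canonical_feature_id(c) for c in self.feature_meta.index]
        if list(self.feature_meta.index) != list(self.abundances.columns):
            if set(self.feature_meta.index) != set(self.abundances.columns):
                raise ValueError("feature metadata does not match abundance columns")
            self.feature_meta = self.feature_meta.loc[self.abundances.columns]
        if "ion_mode" not in self.feature_meta.columns:
            self.feature_meta["ion_mode"] = [
                normalize_feature_id(f)[1] for f in self.feature_meta.index
            ]
        if list(self.sample_meta.index) != list(self.abundances.index):
            if set(self.sample_meta.index) != set(self.abundances.index):
                raise ValueError("sample metadata does not match abundance rows")
            self.sample_meta = self.sample_meta.loc[self.abundances.index]
        bad_groups = set(self.sample_meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}; expected {GROUPS}")
        if self.scale == "raw":
            vals = self.abundances.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("raw abundances must be non-negative (missing is NaN, not negative)")
        self._check_lh_fsh()

    def _check_lh_fsh(self) -> None:
        cols = self.sample_meta.columns
        if not {"LH", "FSH", "LH/FSH"} <= set(cols):
            return
        lh, fsh, ratio = (self.sample_meta[c].astype(float) for c in ("LH", "FSH", "LH/FSH"))
        ok = lh.notna() & fsh.notna() & ratio.notna() & (fsh != 0)
        if ok.any():
            expected = lh[ok] / fsh[ok]
            if not np.allclose(ratio[ok], expected, rtol=1e-3, atol=1e-6):
                raise ValueError("LH/FSH column inconsistent with LH / FSH")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundances.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    @property
    def y(self) -> np.ndarray:
        """Binary class encoding: EG (case) = 1, CG (control) = 0."""
        return (self.groups == "EG").to_numpy(dtype=float)

    def case_mask(self) -> np.ndarray:
        return (self.groups == "EG").to_numpy()

    def subset_samples(self, sample_ids) -> "LipidFeatureTable":
        ids = list(sample_ids)
        return LipidFeatureTable(
            self.abundances.loc[ids].copy(),
            self.feature_meta.copy(),
            self.sample_meta.loc[ids].copy(),
            scale=self.scale,
        )

    def subset_features(self, feature_ids) -> "LipidFeatureTable":
        ids = [canonical_feature_id(f) for f in feature_ids]
        return LipidFeatureTable(
            self.abundances[ids].copy(),
            self.feature_meta.loc[ids].copy(),
            self.sample_meta.copy(),
            scale=self.scale,
        )

    def equals(self, other: "LipidFeatureTable") -> bool:
        return (
            self.abundances.equals(other.abundances)
            and self.feature_meta.equals(other.feature_meta)
            and self.sample_meta.equals(other.sample_meta)
            and self.scale == other.scale
        )


def read_feature_table(
    abundance_path,
    feature_meta_path,
    sample_meta_path,
    zero_as_missing: bool = False,
) -> LipidFeatureTable:
    """Read the three-file CSV set into a validated :class:`LipidFeatureTable`.

    ``abundances.csv`` is samples x features with the sample id in the first
    column; ``features.csv`` and ``samples.csv`` carry the metadata.  Empty
    cells and ``NA`` are read as missing.  With ``zero_as_missing`` imported
    zeros are reinterpreted as below-detection missing values.
    """
    for p in (abundance_path, feature_meta_path, sample_meta_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    scale = "raw"
    sidecar = Path(abundance_path).parent / "table_meta.json"
    if sidecar.exists():
        scale = json.loads(sidecar.read_text()).get("scale", "raw")
    ab = pd.read_csv(abundance_path, index_col=0)
    fm = pd.read_csv(feature_meta_path, index_col=0)
    sm = pd.read_csv(sample_meta_path, index_col=0)
    for df in (ab, fm, sm):
        df.index = df.index.astype(str)
        df.index.name = None
    if zero_as_missing:
        ab = ab.where(ab != 0)
    return LipidFeatureTable(ab, fm, sm, scale=scale)


def write_feature_table(table: LipidFeatureTable, out_dir) -> dict[str, Path]:
    """Write ``abundances.csv``, ``features.csv`` and ``samples.csv`` to *out_dir*.

    Missing cells are written as empty strings (never 0) so the round trip
    through :func:`read_feature_table` is the identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundances": out / "abundances.csv",
        "features": out / "features.csv",
        "samples": out / "samples.csv",
    }
    table.abundances.to_csv(paths["abundances"], index_label="sample_id", na_rep="")
    table.feature_meta.to_csv(paths["features"], index_label="feature_id", na_rep="")
    table.sample_meta.to_csv(paths["samples"], index_label="sample_id", na_rep="")
    # sidecar so the intensity scale survives the round trip
    (out / "table_meta.json").write_text(json.dumps({"scale": table.scale}) + "\n")
    return paths
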