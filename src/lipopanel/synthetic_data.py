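"""Synthetic serum-lipidomics dataset generator with planted differential lipids.

The generator emulates the statistical structure of an unbalanced PCOS
case/control lipidomics study: ~152 cases (EG) vs ~50 controls (CG), ~1100
lipid features split across the common lipid classes, log-normal intensities
with a shared within-class latent factor, a small number of planted
differential features, clinical covariates whose group shifts follow the
hormonal profile of PCOS (LH, T and LH/FSH higher in cases; FSH and Age
lower), and below-detection (MNAR) missingness.

On the log2 scale a feature value is drawn as::

    x_ij = mu_j + lambda * F_{i,class(j)} + delta_j * 1[case_i] + sigma_j * eps_ij

with ``F`` a per-sample, per-class standard-normal latent factor, and the
table is exported on the raw ``2**x`` scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CLINICAL_INDEXES, LipidFeatureTable, render_feature_id

__all__ = ["SyntheticConfig", "generate_dataset", "generate_null_dataset"]

_DEFAULT_CLASS_PROPORTIONS = {
    "TG": 0.25, "PC": 0.15, "PE": 0.12, "PI": 0.06, "PS": 0.05,
    "LPC": 0.06, "LPE": 0.05, "SM": 0.08, "DG": 0.06, "MGDG": 0.04,
    "other": 0.08,
}

# Group means (control, case) and SDs for the clinical indexes; group-mean
# shifts follow the PCOS hormonal profile (cases younger, higher LH/T, lower
# FSH); SDs are plausible choices since only mean (min, max) are typically
# published.  LH/FSH and BMI are derived, not drawn.
_CLINICAL_PARAMS = {
    "Age": ((29.2, 3.5), (26.0, 4.5)),
    "Height": ((156.8, 5.0), (156.6, 5.5)),
    "Weight": ((51.4, 7.0), (52.6, 9.0)),
    "LH": ((6.1, 2.5), (10.7, 6.0)),
    "FSH": ((7.3, 1.8), (5.6, 1.6)),
    "P": ((0.37, 0.25), (0.95, 1.5)),
    "PRL": ((19.2, 8.0), (17.1, 9.0)),
    "T": ((0.27, 0.09), (0.41, 0.15)),
    "E2": ((57.4, 30.0), (59.1, 45.0)),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults are the emulated design."""

    n_case: int = 152
    n_control: int = 50
    n_features: int = 1100
    pos_fraction: float = 0.6
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_PROPORTIONS))
    n_strong: int = 2
    delta_strong: float = 2.0
    n_weak: int = 20
    delta_weak_range: tuple[float, float] = (0.5, 1.5)
    base_mu_range: tuple[float, float] = (10.0, 25.0)
    sigma_range: tuple[float, float] = (0.3, 1.2)
    class_factor_loading: float = 0.5
    clinical_rho: float = 0.4
    #: clinical index -> lipid class whose latent factor it correlates with
    clinical_links: dict = field(default_factory=lambda: {"LH": "PI", "T": "TG"})
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1 or self.n_features < 1:
            raise ValueError("sample and feature counts must be positive")
        if self.n_strong + self.n_weak > self.n_features:
            raise ValueError("n_strong + n_weak exceeds n_features")
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class_proportions must sum to 1 (got {total})")
        for frac in (self.pos_fraction, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not -1.0 <= self.clinical_rho <= 1.0:
            raise ValueError("clinical_rho must lie in [-1, 1]")


def _allocate_classes(config: SyntheticConfig) -> list[str]:
    """Deterministic largest-remainder allocation of features to classes."""
    names = list(config.class_proportions)
    quotas = np.array([config.class_proportions[c] * config.n_features for c in names])
    counts = np.floor(quotas).astype(int)
    remainder = config.n_features - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    classes: list[str] = []
    for name, cnt in zip(names, counts):
        classes.extend([name] * cnt)
    return classes


def _make_feature_meta(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = _allocate_classes(config)
    rng.shuffle(classes)
    modes = np.where(rng.random(config.n_features) < config.pos_fraction, "POS", "NEG")
    ids = [render_feature_id(i + 1, m) for i, m in enumerate(modes)]
    annotations = [f"{cls} species {fid}" for cls, fid in zip(classes, ids)]
    return pd.DataFrame(
        {"annotation": annotations, "lipid_class": classes, "ion_mode": modes}, index=ids
    )


def _plant_markers(config: SyntheticConfig, meta: pd.DataFrame, rng: np.random.Generator):
    """Choose planted feature positions and their log2 shifts.

    The first two strong markers are relabelled as a PI and a PE species in
    negative mode (the classic PCOS panel classes); further planted features
    keep their generated identity.
    """
    n = config.n_features
    free = list(rng.permutation(n))
    panel_identities = [
        ("1033NEG", "NEG", "PI", "PI (18:0/20:3)-H"),
        ("877NEG", "NEG", "PE", "PE (18:1p/22:6)-H"),
    ]
    new_index = list(meta.index)
    strong_pos: list[int] = []
    for fid, mode, cls, annot in panel_identities[: config.n_strong]:
        # reuse the position already carrying this id, otherwise relabel one
        pos = new_index.index(fid) if fid in new_index else free[0]
        new_index[pos] = fid
        meta.iloc[pos, meta.columns.get_indexer(["annotation", "lipid_class", "ion_mode"])] = [
            annot, cls, mode,
        ]
        strong_pos.append(pos)
        free.remove(pos)
    while len(strong_pos) < config.n_strong:
        strong_pos.append(free.pop(0))
    weak_pos = [p for p in free if p not in strong_pos][: config.n_weak]
    meta.index = new_index
    strong_pos = np.asarray(strong_pos, dtype=int)
    weak_pos = np.asarray(weak_pos, dtype=int)
    deltas = np.zeros(n)
    deltas[strong_pos] = config.delta_strong
    lo, hi = config.delta_weak_range
    weak_mag = rng.uniform(lo, hi, size=len(weak_pos))
    weak_sign = rng.choice([-1.0, 1.0], size=len(weak_pos))
    deltas[weak_pos] = weak_mag * weak_sign
    return strong_pos, weak_pos, deltas


def _draw_clinical(
    config: SyntheticConfig,
    rng: np.random.Generator,
    case: np.ndarray,
    class_factors: dict[str, np.ndarray],
    rho: float,
) -> pd.DataFrame:
    n = case.size
    clinical: dict[str, np.ndarray] = {}
    for name, ((mu_cg, sd_cg), (mu_eg, sd_eg)) in _CLINICAL_PARAMS.items():
        noise = rng.standard_normal(n)
        link = config.clinical_links.get(name)
        if link is not None and link in class_factors and rho != 0.0:
            z = rho * class_factors[link] + np.sqrt(1.0 - rho**2) * noise
        else:
            z = noise
        mu = np.where(case, mu_eg, mu_cg)
        sd = np.where(case, sd_eg, sd_cg)
        vals = mu + sd * z
        clinical[name] = np.maximum(vals, 0.01)  # physical quantities stay positive
    clinical["LH/FSH"] = clinical["LH"] / clinical["FSH"]
    clinical["BMI"] = clinical["Weight"] / (clinical["Height"] / 100.0) ** 2
    return pd.DataFrame({k: clinical[k] for k in CLINICAL_INDEXES})


def _generate(config: SyntheticConfig, null: bool):
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_feature_meta(config, rng)
    strong_pos, weak_pos, deltas = _plant_markers(config, meta, rng)
    if null:
        deltas = np.zeros_like(deltas)
    rho = 0.0 if null else config.clinical_rho

    n = config.n_case + config.n_control
    case = np.concatenate([np.zeros(config.n_control, bool), np.ones(config.n_case, bool)])
    sample_ids = [f"CG{i+1:03d}" for i in range(config.n_control)] + [
        f"EG{i+1:03d}" for i in range(config.n_case)
    ]

    mu = rng.uniform(*config.base_mu_range, size=config.n_features)
    sigma = rng.uniform(*config.sigma_range, size=config.n_features)
    # Planted features (strong and weak) get the mid-range noise SD so that a
    # planted effect size is a property of its delta alone and the |delta|
    # ordering is the discriminability ordering — otherwise the sigma lottery
    # could make a "weak" feature a stronger discriminator than a "strong" one
    # and recovery would be unscorable.
    mid_sigma = 0.5 * (config.sigma_range[0] + config.sigma_range[1])
    planted = np.concatenate([strong_pos, weak_pos]).astype(int)
    if planted.size:
        sigma[planted] = mid_sigma

    class_names = sorted(set(meta["lipid_class"]))
    factors = {c: rng.standard_normal(n) for c in class_names}
    class_idx = meta["lipid_class"].to_numpy()
    F = np.column_stack([factors[c] for c in class_idx])

    eps = rng.standard_normal((n, config.n_features))
    log2x = (
        mu[None, :]
        + config.class_factor_loading * F
        + deltas[None, :] * case[:, None].astype(float)
        + sigma[None, :] * eps
    )

    if config.missing_rate > 0:
        thresh = np.quantile(log2x, config.missing_rate, axis=0)
        log2x = np.where(log2x < thresh[None, :], np.nan, log2x)

    abundances = pd.DataFrame(np.exp2(log2x), index=sample_ids, columns=list(meta.index))
    sample_meta = _draw_clinical(config, rng, case, factors, rho)
    sample_meta.index = sample_ids
    sample_meta.insert(0, "group", np.where(case, "EG", "CG"))

    table = LipidFeatureTable(abundances, meta, sample_meta, scale="raw")
    truth = {
        "strong": [meta.index[p] for p in strong_pos],
        "weak": [meta.index[p] for p in weak_pos],
        "deltas": {meta.index[p]: float(deltas[p]) for p in np.concatenate([strong_pos, weak_pos]).astype(int)},
        "clinical_links": dict(config.clinical_links),
        "clinical_rho": rho,
        "seed": config.seed,
        "null": null,
    }
    return table, truth


def generate_dataset(config: SyntheticConfig | None = None) -> tuple[LipidFeatureTable, dict]:
    """Draw a dataset with planted effects; returns ``(table, truth)``.

    ``truth`` records the planted strong/weak feature ids, their log2 shifts,
    and the clinical-link structure, so selection procedures can be scored by
    recovery.
    """
    return _generate(config or SyntheticConfig(), null=False)


def generate_null_dataset(config: SyntheticConfig | None = None) -> LipidFeatureTable:
    """Same generative process with every planted shift and clinical link zeroed."""
    table, _ = _generate(config or SyntheticConfig(), null=True)
    return table


def replace(config: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Functional update of a config (thin wrapper over dataclasses.replace)."""
    return dataclasses.replace(config, **kwargs)
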