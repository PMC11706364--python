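"""End-to-end orchestration: simulate/load -> preprocess -> screen -> OPLS-DA ->
associate -> ensemble select -> validate -> diagnostic panel.

One master seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence.spawn``, so stage outputs are pure functions of
(inputs, config, seed) and the whole run report is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import class_aggregate, class_clinical_mantel
from .dataio import LipidFeatureTable, read_feature_table, write_feature_table
from .ensemble import (auc_accumulation, candidate_pool, comprehensive_weight,
                       run_selectors, select_panel)
from .modeling import evaluate_models
from .oplsda import fit_oplsda, permutation_test, top_vip
from .panel import evaluate_panel, fit_panel, panel_score
from .preprocess import impute_and_log, split_train_test
from .screening import volcano_screen
from .synthetic_data import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

_STAGES = ("simulate", "split", "oplsda", "associate", "select", "validate", "panel")


@dataclasses.dataclass
class PipelineConfig:
    """Defaults mirror the emulated study design; see the methods note."""

    seed: int = 0
    simulate: dict | None = None          # SyntheticConfig overrides, or None to load
    input_dir: str | None = None
    test_fraction: float = 0.25
    drop_missing_frac: float = 0.5
    screen_test: str = "welch"
    screen_adjust: str = "bh"
    n_ortho: int = 1
    q2_folds: int = 7
    n_permutations: int = 100
    mantel_permutations: int = 999
    top_k_vip: int = 20
    selection_delta: float = 0.01
    accumulation_folds: int = 5
    accumulation_repeats: int = 10
    validate_folds: int = 5
    validate_repeats: int = 20
    run_association: bool = True
    run_validation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-2^31 seed per stage from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _load_or_simulate(config: PipelineConfig, seeds: dict):
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", seeds["simulate"])
        sim_cfg = SyntheticConfig(**overrides)
        return generate_dataset(sim_cfg)
    if config.input_dir is None:
        raise ValueError("config needs either a simulate block or an input_dir")
    d = Path(config.input_dir)
    table = read_feature_table(d / "abundances.csv", d / "features.csv", d / "samples.csv")
    return table, None


def run_pipeline(config: PipelineConfig | dict | str | Path, out_dir=None) -> dict:
    """Execute all stages in order; returns the machine-readable run report.

    With *out_dir* set, stage artifacts (the simulated file set, screen table,
    weight table, panel JSON, report JSON) are also written to disk.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(**config)
    seeds = stage_seeds(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- data ------------------------------------------------------------
    table, truth = _load_or_simulate(config, seeds)
    if out is not None:
        write_feature_table(table, out / "data")
        if truth is not None:
            (out / "data" / "truth.json").write_text(json.dumps(truth, indent=2))

    # -- preprocess ------------------------------------------------------
    train_raw, test_raw = split_train_test(table, config.test_fraction, seed=seeds["split"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train = impute_and_log(train_raw, config.drop_missing_frac)
        test = impute_and_log(test_raw, config.drop_missing_frac)
    common = [f for f in train.feature_ids if f in set(test.feature_ids)]
    train = train.subset_features(common)
    test = test.subset_features(common)

    # -- univariate screen ----------------------------------------------
    screen = volcano_screen(train, test=config.screen_test, adjust=config.screen_adjust)
    n_pass = int(screen["passes"].sum())

    # -- OPLS-DA ---------------------------------------------------------
    y_train = train.y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_oplsda(train.abundances, y_train, n_ortho=config.n_ortho)
        perm = permutation_test(
            train.abundances, y_train, n_ortho=config.n_ortho,
            n_permutations=config.n_permutations, seed=seeds["oplsda"],
            folds=config.q2_folds,
        )
    vip = top_vip(model, k=len(model.feature_names))
    top20 = top_vip(model, k=config.top_k_vip)

    # -- association -----------------------------------------------------
    mantel = None
    if config.run_association:
        diff = list(screen.index[screen["passes"]])
        assoc_features = diff if diff else list(top20.index)
        profiles = class_aggregate(train, assoc_features)
        clinical = train.sample_meta.drop(columns=["group"], errors="ignore")
        if not profiles.empty and not clinical.empty:
            mantel = class_clinical_mantel(
                profiles, clinical, n_permutations=config.mantel_permutations,
                seed=seeds["associate"],
            )

    # -- ensemble selection ---------------------------------------------
    candidates = candidate_pool(screen, vip, top_k_vip=config.top_k_vip)
    Xc = train.abundances[candidates]
    rankings = run_selectors(Xc, y_train, vip, screen, seed=seeds["select"])
    weights = comprehensive_weight(rankings)
    acc = auc_accumulation(
        Xc, y_train, weights, delta=config.selection_delta,
        folds=config.accumulation_folds, repeats=config.accumulation_repeats,
        seed=seeds["select"],
    )
    panel_features = select_panel(acc)

    # -- validation ------------------------------------------------------
    validation = None
    if config.run_validation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            validation = evaluate_models(
                train.abundances[panel_features], y_train,
                folds=config.validate_folds, repeats=config.validate_repeats,
                seed=seeds["validate"],
            )

    # -- diagnostic panel ------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pmodel = fit_panel(train.abundances[panel_features], y_train)
    from .modeling import roc_auc

    train_scores = panel_score(pmodel, train.abundances[panel_features])
    train_auc = roc_auc(train_scores, y_train).auc
    test_eval = evaluate_panel(pmodel, test.abundances[panel_features], test.y)

    report = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_train": train.n_samples,
        "n_test": test.n_samples,
        "n_features": train.n_features,
        "screen": {"n_pass": n_pass, "test": config.screen_test, "adjust": config.screen_adjust},
        "oplsda": {
            "r2y": model.r2y,
            "q2": perm.observed_q2,
            "permutation_p_q2": perm.p_q2,
            "n_permutations": perm.n_permutations,
            "top_vip": {str(k): float(v) for k, v in top20.items()},
        },
        "selection": {
            "n_candidates": len(candidates),
            "selected_k": acc.selected_k,
            "cumulative_auc": acc.cumulative_auc,
            "panel": [str(f) for f in panel_features],
        },
        "panel": {
            "intercept": pmodel.intercept,
            "coefficients": pmodel.coefficients,
            "cutoff": pmodel.cutoff,
            "train_auc": train_auc,
            "test_auc": test_eval["auc"],
            "test_accuracy": test_eval["accuracy"],
            "test_sensitivity": test_eval["sensitivity"],
            "test_specificity": test_eval["specificity"],
        },
    }
    if truth is not None:
        recovered = sorted(set(panel_features) & set(truth["strong"]))
        report["truth"] = {
            "strong": truth["strong"],
            "recovered_strong": recovered,
            "panel_equals_planted": set(panel_features) == set(truth["strong"]),
        }
    if mantel is not None and not mantel.empty:
        sig = mantel[(mantel["status"] == "ok") & (mantel["p"] < 0.05)]
        report["association"] = {
            "n_pairs": int(len(mantel)),
            "significant_pairs": [
                {"lipid_class": r.lipid_class, "index": r.index_, "r": r.r, "p": r.p}
                for r in mantel.rename(columns={"index": "index_"}).itertuples()
                if r.status == "ok" and r.p < 0.05
            ],
        }
    if validation is not None:
        med = validation.metrics.groupby("model")[["auc", "sensitivity", "specificity"]].median()
        report["validation"] = {m: {k: float(v) for k, v in row.items()} for m, row in med.iterrows()}
        if validation.rf_importance is not None:
            report["rf_importance"] = {str(k): float(v) for k, v in validation.rf_importance.items()}

    if out is not None:
        screen.to_csv(out / "screen.csv", index_label="feature_id")
        weights.to_csv(out / "weights.csv", index_label="feature_id")
        if mantel is not None:
            mantel.to_csv(out / "mantel.csv", index=False)
        if validation is not None:
            validation.metrics.to_csv(out / "metrics_long.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
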