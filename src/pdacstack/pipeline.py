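"""End-to-end orchestration: simulate -> split -> normalize -> screen ->
train -> stack -> evaluate -> report.

Driven by a YAML config that is schema-checked up front (unknown keys
are named in the error).  Identical config + seed produce a
byte-identical report bundle; every stage logs the seed it consumed.
The validation arm is quarantined structurally: training stages only
ever receive the discovery subset, and no training-stage log line
records a validation label.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .base_learner import DEFAULT_SUBSET_SIZES
from .cohort import assign_split, bridge_normalize, write_cohort
from .comparators import train_rfe_glm_whole, train_tree_comparators
from .evaluation import compare_auc_bootstrap, roc_summary
from .importance import aggregate_importance, importance_long_table
from .screen import screen_features, screen_table
from .simulate import (
    CONTROL_CLASSES,
    SimulationConfig,
    _default_effect_map,
    default_marker_panel,
    generate_bridge_pairs,
    generate_cohort,
)
from .stack import build_reduced_signature, fit_stack, predict_stack, train_ensemble

log = logging.getLogger("pdacstack")

__all__ = ["default_config", "load_config", "build_sim_config", "run_pipeline"]


def default_config() -> dict:
    return {
        "seed": 0,
        "subsampling": "over",
        "prediction_mode": "insample",
        "subset_sizes": list(DEFAULT_SUBSET_SIZES),
        "candidates": None,  # default: all markers + age/gender/bmi/diabetes
        "classes": None,  # default: every control class present
        "simulation": {},  # overrides for SimulationConfig fields
        "normalize": {"enabled": False, "n_bridge": 16},
        "screen": {"enabled": True, "n_boot": 200, "ci": False},
        "comparators": {
            "enabled": False,
            "families": ["random_forest"],
            "n_param_draws": 10,
            "cv": 10,
        },
        "reduced_signature": {"enabled": False, "features": None},
        "importance": {"enabled": True, "n_repeats": 10},
        "evaluation": {"n_boot": 2000, "spec": 0.90},
    }


def _check_schema(cfg: dict, template: dict, path: str = ""):
    for key, val in cfg.items():
        if key not in template:
            raise ValueError(f"unknown config field: {path}{key}")
        if isinstance(template[key], dict) and key != "simulation" and isinstance(val, dict):
            _check_schema(val, template[key], path=f"{path}{key}.")


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _check_schema(user, cfg)
    for key, val in user.items():
        if isinstance(cfg.get(key), dict) and isinstance(val, dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def build_sim_config(overrides: dict, seed: int) -> SimulationConfig:
    """SimulationConfig from config-file overrides.

    When the marker panel is overridden, the default effect map is
    filtered to declared markers unless an explicit map is supplied.
    """
    overrides = copy.deepcopy(overrides or {})
    panel = overrides.pop("marker_panel", None) or default_marker_panel()
    effect = overrides.pop("effect_map", None)
    if effect is None:
        effect = {
            k: v for k, v in _default_effect_map().items() if k[0] in panel
        }
    else:
        effect = {tuple(k.split("::")) if isinstance(k, str) else tuple(k): v
                  for k, v in effect.items()}
    elisa = [m for m in ["CA19-9", "IL6ST", "VWF", "PKM2", "THBS2"] if m in panel]
    kwargs = dict(marker_panel=panel, effect_map=effect, elisa_markers=elisa, seed=seed)
    for key in (
        "n_per_control_class",
        "n_cases",
        "stage_counts",
        "noise_sd",
        "missing_rate",
        "baseline_mean",
        "baseline_sd",
    ):
        if key in overrides:
            kwargs[key] = overrides.pop(key)
    if overrides:
        raise ValueError(f"unknown simulation config fields: {sorted(overrides)}")
    return SimulationConfig(**kwargs).validate()


def _dump_json(obj, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: dict | str | Path, out: str | Path) -> dict:
    """Execute all stages; returns the summary dict written to
    ``summary.json``.  Partial outputs are left in place on failure."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _check_schema(config, default_config())
        merged = default_config()
        for key, val in config.items():
            if isinstance(merged.get(key), dict) and isinstance(val, dict) and key != "simulation":
                merged[key] = {**merged[key], **val}
            else:
                merged[key] = val
        config = merged
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"seed": seed, "stages": {}}

    # --- simulate ------------------------------------------------------
    sim_cfg = build_sim_config(config["simulation"], seed)
    cohort = generate_cohort(sim_cfg, seed)
    write_cohort(cohort, out / "cohort.tsv")
    log.info("simulate: %d samples, seed=%d", len(cohort), seed)
    summary["stages"]["simulate"] = {"n_samples": len(cohort), "seed": seed}

    # --- normalize (bridging) -----------------------------------------
    if config["normalize"]["enabled"]:
        n_bridge = int(config["normalize"]["n_bridge"])
        pairs = generate_bridge_pairs(cohort, n_bridge=n_bridge, seed=seed + 1)
        new_mask = (cohort.data["batch"] == "batch2").to_numpy()
        ref = cohort.subset(~new_mask)
        new = bridge_normalize(cohort.subset(~new_mask), cohort.subset(new_mask), pairs)
        import pandas as pd

        merged_tbl = pd.concat([ref.data, new.data], ignore_index=True)
        cohort.data = merged_tbl.sort_values("sample_id").reset_index(drop=True)
        summary["stages"]["normalize"] = {
            "n_bridge": n_bridge,
            "offsets": {m: float(v) for m, v in new.bridging_offsets_.items()},
        }

    # --- split ---------------------------------------------------------
    split = assign_split(cohort, seed=seed + 2)
    split.to_tsv(out / "split.tsv")
    discovery = split.discovery(cohort)
    validation = split.validation(cohort)
    log.info(
        "split: %d discovery / %d validation (labels of the validation arm "
        "are quarantined until evaluation)",
        len(discovery),
        len(validation),
    )
    summary["stages"]["split"] = {
        "n_discovery": len(discovery),
        "n_validation": len(validation),
        "seed": seed + 2,
    }

    candidates = config["candidates"]
    if candidates is None:
        candidates = list(cohort.marker_names) + ["age", "gender", "bmi", "diabetes"]

    # --- univariate screen --------------------------------------------
    if config["screen"]["enabled"]:
        rows = screen_features(
            discovery,
            candidates,
            validation=None,
            n_boot=int(config["screen"]["n_boot"]),
            seed=seed + 3,
            ci=bool(config["screen"]["ci"]),
        )
        screen_table(rows).to_csv(out / "screen.tsv", sep="\t", index=False)
        summary["stages"]["screen"] = {"n_features": len(rows), "seed": seed + 3}

    # --- base learners + stack ----------------------------------------
    stack = train_ensemble(
        discovery,
        candidates,
        classes=config["classes"],
        subsampling=config["subsampling"],
        seed=seed + 4,
        subset_sizes=config["subset_sizes"],
        prediction_mode=config["prediction_mode"],
    )
    stack.save(out / "stack.json")
    stack.coefficients_table().to_csv(out / "stack-coefficients.tsv", sep="\t", index=False)
    summary["stages"]["train"] = {
        "n_base_learners": len(stack.learners),
        "n_meta_coefficients": 1 + len(stack.meta_coef_),
        "subsampling": config["subsampling"],
        "prediction_mode": config["prediction_mode"],
        "seed": seed + 4,
    }

    # --- comparators ---------------------------------------------------
    comp_scores = {}
    if config["comparators"]["enabled"]:
        comp_cfg = config["comparators"]
        rfe_glm = train_rfe_glm_whole(
            discovery, candidates, subsampling=config["subsampling"], seed=seed + 5,
            subset_sizes=config["subset_sizes"],
        )
        comp_scores["rfe_glm"] = {
            "discovery": rfe_glm.predict_proba(discovery.feature_frame(candidates))[:, 1],
            "validation": rfe_glm.predict_proba(validation.feature_frame(candidates))[:, 1],
        }
        for fam in comp_cfg["families"]:
            tree = train_tree_comparators(
                discovery,
                model_family=fam,
                candidates=candidates,
                n_param_draws=int(comp_cfg["n_param_draws"]),
                subsampling=config["subsampling"],
                seed=seed + 6,
                cv=comp_cfg["cv"],
            )
            comp_scores[fam] = {
                "discovery": tree.predict_proba_cohort(discovery),
                "validation": tree.predict_proba_cohort(validation),
            }
        summary["stages"]["comparators"] = {"models": sorted(comp_scores), "seed": seed + 5}

    # --- reduced signature --------------------------------------------
    if config["reduced_signature"]["enabled"]:
        reduced = build_reduced_signature(
            discovery,
            features=config["reduced_signature"]["features"],
            classes=config["classes"],
            subsampling=config["subsampling"],
            seed=seed + 7,
            subset_sizes=config["subset_sizes"],
            prediction_mode=config["prediction_mode"],
        )
        reduced.save(out / "reduced-stack.json")
        comp_scores["reduced_signature"] = {
            "discovery": reduced.predict_proba(discovery)[:, 1],
            "validation": reduced.predict_proba(validation)[:, 1],
        }

    # --- evaluate ------------------------------------------------------
    n_boot = int(config["evaluation"]["n_boot"])
    spec = float(config["evaluation"]["spec"])
    evaluation = {}
    stack_scores = {}
    for arm, table in (("discovery", discovery), ("validation", validation)):
        p, _odds = predict_stack(stack, table)
        stack_scores[arm] = p
        evaluation[f"stack_{arm}"] = roc_summary(
            p, table.y, spec=spec, n_boot=n_boot, seed=seed + 8
        ).to_dict()
    for name, scores in comp_scores.items():
        for arm, table in (("discovery", discovery), ("validation", validation)):
            evaluation[f"{name}_{arm}"] = roc_summary(
                np.asarray(scores[arm]), table.y, spec=spec, n_boot=n_boot, seed=seed + 8
            ).to_dict()
            cmpres = compare_auc_bootstrap(
                stack_scores[arm], np.asarray(scores[arm]), table.y,
                n_boot=min(n_boot, 2000), seed=seed + 9,
            )
            evaluation[f"stack_vs_{name}_{arm}"] = cmpres.to_dict()
    summary["evaluation"] = evaluation

    # --- importance ----------------------------------------------------
    if config["importance"]["enabled"]:
        table = aggregate_importance(
            stack.learners,
            discovery,
            n_repeats=int(config["importance"]["n_repeats"]),
            seed=seed + 10,
        )
        importance_long_table(table).to_csv(out / "importance.tsv", sep="\t", index=False)
        summary["stages"]["importance"] = {
            "n_features": int(table.shape[0]),
            "seed": seed + 10,
        }

    _dump_json(summary, out / "summary.json")
    return summary
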