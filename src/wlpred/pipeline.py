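"""Pipeline orchestration: simulate -> label -> featurize -> train/select ->
permute -> ensemble -> report, driven by a single structured config.

Data-combination labels concatenate block labels with ``.`` (e.g.
``Diet.16S_B.LC-MS``); the Diet block is always included.  All randomness
flows from the single master seed; re-running with the same config produces
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import labels as lab
from . import postprandial as pp
from . import synthetic as syn
from .permutation import permute_and_evaluate
from .rf import CVConfig, ModelRun, importance_report, mean_metrics, run_cv
from .selection import forward_select

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Raised on invalid pipeline configuration (exit code 2 at the CLI)."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ConfigError("config must set a master seed")
    return cfg


def default_config(seed: int = 42) -> dict:
    """A small self-contained synthetic run exercising every stage."""
    return {
        "seed": seed,
        "synthetic": {
            "n_participants": 50,
            "n_otus": 15,
            "n_metabolites": 10,
            "n_snps": 40,
            "ld_block_size": 8,
            "planted_features": [
                ["16S_B", "otu_0003", 1.2],
                ["LC-MS", "met_0005", 1.0],
                ["ClinicalA", "clin_01", 0.8],
            ],
            "missingness": {"16S_B": 0.1, "LC-MS": 0.1},
        },
        "cv": {"n_shuffles": 10},
        "postpran_representation": "fluc3_50",
        "combinations": [
            {"blocks": ["Diet"]},
            {"blocks": ["Diet", "ClinicalA"]},
            {"blocks": ["Diet", "GRS"]},
            {"blocks": ["Diet", "PostPran"]},
            {
                "blocks": ["Diet", "16S_B"],
                "selection": {
                    "pool_blocks": ["16S_B"],
                    "max_features": 3,
                    "inner_shuffles": 1,
                    "inner_trees": 15,
                    "inner_folds": 3,
                },
            },
            {
                "blocks": ["Diet", "LC-MS"],
                "selection": {
                    "pool_blocks": ["LC-MS"],
                    "max_features": 3,
                    "inner_shuffles": 1,
                    "inner_trees": 15,
                    "inner_folds": 3,
                },
            },
            {
                "blocks": ["Diet", "16S_B", "LC-MS"],
                "selection": {
                    "pool_blocks": ["16S_B", "LC-MS"],
                    "max_features": 3,
                    "inner_shuffles": 1,
                    "inner_trees": 15,
                    "inner_folds": 3,
                },
            },
        ],
        "permutation": None,
        "ensemble": {"auc_threshold": 0.62, "method": "confident_mean", "band": [0.25, 0.75]},
    }


def _combination_label(blocks: list[str]) -> str:
    return ".".join(blocks)


def _build_cv(cfg: dict) -> CVConfig:
    overrides = dict(cfg.get("cv") or {})
    overrides.setdefault("seed", cfg["seed"])
    return CVConfig(**overrides)


def _validate(cfg: dict, block_labels: set[str]) -> None:
    for combo in cfg.get("combinations", []):
        for b in combo["blocks"]:
            if b not in block_labels:
                raise ConfigError(f"combination references undefined block {b!r}")
        sel = combo.get("selection")
        if sel:
            for b in sel.get("pool_blocks", []):
                if b not in combo["blocks"]:
                    raise ConfigError(
                        f"selection pool block {b!r} not part of combination {combo['blocks']}"
                    )


def assemble_matrix(blocks: dict[str, syn.FeatureBlock], names: list[str], sample_ids) -> pd.DataFrame:
    """Column-concatenate blocks restricted to a common sample set."""
    common = [s for s in sample_ids if all(s in blocks[n].data.index for n in names)]
    frames = [blocks[n].data.loc[common] for n in names]
    return pd.concat(frames, axis=1)


def train_combination(
    blocks: dict[str, syn.FeatureBlock],
    labels: pd.Series,
    combo: dict,
    cv: CVConfig,
) -> list[ModelRun]:
    """Train one data combination: plain CV or per-shuffle forward selection.

    With a ``selection`` entry, each shuffle runs forward selection over the
    pool blocks (Diet and other non-pool blocks always included) using a
    reduced inner CV, then fits that shuffle's fold models on the selected
    set; the ModelRun records the shuffle-specific selected features.
    """
    names = list(combo["blocks"])
    if "Diet" in blocks and "Diet" not in names:
        names = ["Diet"] + names
    label = _combination_label(names)
    sel = combo.get("selection")
    labelled_ids = list(labels.index)
    X_all = assemble_matrix(blocks, names, labelled_ids)
    y = labels.loc[X_all.index]
    if sel is None:
        return run_cv(X_all, y, cv, label=label)
    pool_cols = [c for n in sel["pool_blocks"] for c in blocks[n].feature_names]
    always_cols = [c for c in X_all.columns if c not in pool_cols]
    runs: list[ModelRun] = []
    inner = int(sel.get("inner_shuffles", 5))
    for shuffle in range(cv.n_shuffles):
        inner_cv = dataclasses.replace(
            cv,
            seed=cv.shuffle_seed(shuffle),
            n_trees=int(sel.get("inner_trees", cv.n_trees)),
            n_folds=int(sel.get("inner_folds", cv.n_folds)),
        )
        trace = forward_select(
            X_all[pool_cols],
            X_all[always_cols] if always_cols else None,
            y,
            cv=inner_cv,
            max_features=sel.get("max_features", 8),
            inner_shuffles=inner,
            seed=cv.shuffle_seed(shuffle),
        )
        X_sel = X_all[always_cols + trace.selected]
        run = run_cv(X_sel, y, cv, label=label, shuffle_indices=[shuffle])[0]
        run.selected_features = always_cols + trace.selected
        runs.append(run)
    return runs


def _serialize_run(run: ModelRun) -> dict:
    return {
        "label": run.label,
        "shuffle": run.shuffle,
        "sample_ids": list(run.sample_ids),
        "oof_scores": [round(float(s), 10) for s in run.oof_scores],
        "selected_features": run.selected_features,
        "importances": {k: round(float(v), 10) for k, v in run.importances.items()},
        "metrics": {k: round(float(v), 10) for k, v in run.metrics.as_dict().items()},
    }


def run_pipeline(cfg: dict, outdir) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    seed = int(cfg["seed"])

    # --- simulate -----------------------------------------------------------
    synth_cfg = dict(cfg.get("synthetic") or {})
    synth_cfg.setdefault("seed", seed)
    planted = synth_cfg.get("planted_features")
    if planted is not None:
        synth_cfg["planted_features"] = tuple(tuple(p) for p in planted)
    config = syn.SynthConfig(**synth_cfg)
    cohort, truth, blocks, postprandial, complete = syn.simulate_all(config)
    syn.write_cohort(cohort, outdir / "cohort.tsv")
    syn.write_truth(truth, outdir / "ground_truth.tsv")

    # --- label --------------------------------------------------------------
    label_table = lab.label_cohort(cohort)
    lab.write_labels(label_table, outdir / "labels.tsv")
    usable = label_table[label_table["label"] != lab.EXCLUDED]
    n_excluded = len(label_table) - len(usable)
    if n_excluded:
        warnings.append(f"{n_excluded} observation(s) excluded for missing weight")
    y = usable.set_index("sample_id")["label"]

    # --- featurize ----------------------------------------------------------
    rep = cfg.get("postpran_representation", "fluc3_50")
    pp_blocks = pp.featurize_postprandial(postprandial)
    key = {"fluc1": "PostPranFluc1", "auc": "PostPranAUC"}.get(
        rep, f"PostPranFluc{rep.replace('fluc', '').replace('_', '_')}"
    )
    key = key if key in pp_blocks else f"PostPranFluc3_50"
    blocks["PostPran"] = syn.FeatureBlock("PostPran", pp_blocks[key])
    syn.write_blocks(blocks, outdir / "blocks")

    _validate(cfg, set(blocks))

    # --- train --------------------------------------------------------------
    cv = _build_cv(cfg)
    all_runs: list[ModelRun] = []
    metric_rows = []
    for combo in cfg.get("combinations", []):
        runs = train_combination(blocks, y, combo, cv)
        all_runs.extend(runs)
        row = {"combination": runs[0].label, "n_samples": len(runs[0].sample_ids), **mean_metrics(runs)}
        metric_rows.append(row)
        logger.info("trained %s: mean AUC %.3f", runs[0].label, row["roc_auc"])
    metrics_table = pd.DataFrame(metric_rows)
    metrics_table.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    with open(outdir / "model_runs.json", "w") as fh:
        json.dump([_serialize_run(r) for r in all_runs], fh, indent=1)

    # importance reports (15% selection-frequency rule)
    imp_frames = []
    for combo_label in metrics_table["combination"]:
        runs = [r for r in all_runs if r.label == combo_label]
        rep_df = importance_report(runs, min_freq=0.15)
        rep_df.insert(0, "combination", combo_label)
        imp_frames.append(rep_df)
    pd.concat(imp_frames, ignore_index=True).to_csv(
        outdir / "importance.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # --- permute (optional) -------------------------------------------------
    perm_cfg = cfg.get("permutation")
    if perm_cfg:
        combo_label = perm_cfg.get("combination", metric_rows[-1]["combination"])
        runs = [r for r in all_runs if r.label == combo_label]
        X = assemble_matrix(blocks, combo_label.split("."), list(y.index))
        result = permute_and_evaluate(
            X,
            y.loc[X.index],
            cv=cv,
            mode=perm_cfg.get("mode", "retrain_fixed_features"),
            n_perm=int(perm_cfg.get("n_perm", 50)),
            seed=seed,
            reference_runs=runs,
            selected_features=runs[0].selected_features,
            perm_shuffles=int(perm_cfg.get("perm_shuffles", 1)),
        )
        with open(outdir / "permutation.json", "w") as fh:
            json.dump(
                {
                    "mode": result.mode,
                    "p_value": result.p_value,
                    "p_empirical": result.p_empirical,
                    "test_used": result.test_used,
                    "null_aucs": [round(float(a), 10) for a in result.null_aucs],
                    "true_aucs": [round(float(a), 10) for a in result.true_aucs],
                },
                fh,
                indent=1,
            )

    # --- ensemble -----------------------------------------------------------
    ens_cfg = cfg.get("ensemble") or {}
    band = tuple(ens_cfg.get("band", ens.DEFAULT_BAND))
    method = ens_cfg.get("method", "confident_mean")
    try:
        admitted = ens.admit_models(all_runs, ens_cfg.get("auc_threshold", ens.DEFAULT_AUC_THRESHOLD))
    except ValueError as exc:
        warnings.append(str(exc))
        admitted = []
    if admitted:
        scores = ens.ensemble_scores(admitted, method=method, band=band)
        scores.to_csv(outdir / "ensemble_scores.tsv", sep="\t", float_format=FLOAT_FMT)
        try:
            sweep = ens.sweep_thresholds(scores, y)
            sweep.to_csv(outdir / "ensemble_sweep.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        except ValueError as exc:
            warnings.append(f"threshold sweep skipped: {exc}")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "seed": seed,
        "config": cfg,
        "n_observations": int(len(cohort)),
        "n_usable": int(len(usable)),
        "complete_case_n": len(complete),
        "n_models": len(all_runs),
        "n_admitted": len(admitted),
        "python": platform.python_version(),
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir


def report(run_dir) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    lines = []
    warn = []
    metrics_path = run_dir / "metrics.tsv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path, sep="\t")
        lines.append("Model performance (mean over CV shuffles):")
        lines.append(metrics.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    else:
        warn.append("metrics.tsv missing (incomplete run)")
    imp_path = run_dir / "importance.tsv"
    if imp_path.exists():
        imp = pd.read_csv(imp_path, sep="\t")
        lines.append("\nFeature importance (selection frequency >= 15%):")
        lines.append(imp.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    sweep_path = run_dir / "ensemble_sweep.tsv"
    if sweep_path.exists():
        sweep = pd.read_csv(sweep_path, sep="\t")
        lines.append("\nEnsemble threshold sweep:")
        lines.append(sweep.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(
            f"\nSeed {manifest['seed']} | {manifest['n_models']} models trained, "
            f"{manifest['n_admitted']} admitted | complete-case N = {manifest['complete_case_n']}"
        )
        warn.extend(manifest.get("warnings", []))
    for w in warn:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines)
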