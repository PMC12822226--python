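"""End-to-end pipeline runner driven by a JSON run configuration.

Wires simulate/load → preprocess → score → select (→ importance ranking,
intersection and union when a booster is requested, → nearest-centroid
evaluation).  Every stage writes its outputs under the run directory and
records row/column counts, parameters and output checksums in a manifest,
so a rerun with an identical config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io
from .containers import OmicsMatrix
from .core import SDCFEParams, score_features, select_top_fraction, select_top_k
from .metrics import centroid_fit, centroid_predict, confusion, mcc_from_confusion
from .preprocessing import PreprocessConfig, preprocess
from .selection import BoosterConfig, importance_rank, intersect_sets, nonredundant_union
from .simulate import SimulationConfig, simulate_expression

log = logging.getLogger("sdcfe.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(config: dict, key: str) -> Any:
    if key not in config:
        raise KeyError(f"run config is missing required field {key!r}")
    return config[key]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages and return (and write) the manifest.

    ``config`` sections: ``simulate`` (SimulationConfig fields) or
    ``inputs`` (paths ``matrix``/``labels``), optional ``preprocess``
    (PreprocessConfig fields), ``score`` (SDCFEParams fields), ``select``
    (``fraction`` or ``k``), optional ``importance`` (BoosterConfig fields)
    and ``evaluate`` (``cv_folds``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 42))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "outputs": {},
    }

    def finish_stage(name: str, info: dict, files: dict[str, Path]) -> None:
        manifest["stages"][name] = info
        for label, path in files.items():
            manifest["outputs"][label] = {
                "path": str(path.relative_to(out)), "sha256": _sha256(path)
            }
        log.info("stage %s done: %s", name, info)

    # ---- acquire data ----------------------------------------------------
    stage = "simulate" if "simulate" in config else "load"
    try:
        if "simulate" in config:
            sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
            m, y, planted, _ = simulate_expression(sim_cfg)
            io.write_matrix(m, out / "matrix.tsv")
            io.write_labels(y, out / "labels.tsv")
            io.write_json(planted, out / "planted_genes.json")
            finish_stage(
                stage,
                {"n_samples": m.n_samples, "n_features": m.n_features,
                 "n_planted": len(planted)},
                {"matrix": out / "matrix.tsv", "labels": out / "labels.tsv",
                 "planted": out / "planted_genes.json"},
            )
        else:
            inputs = _require(config, "inputs")
            matrix_path = _require(inputs, "matrix")
            labels_path = _require(inputs, "labels")
            m = io.read_matrix(
                matrix_path,
                omics_tag=inputs.get("omics_tag", "other"),
                transpose=bool(inputs.get("transpose", False)),
            )
            labels = io.read_labels(labels_path)
            keep = [s for s in m.sample_ids if s in labels.index]
            if not keep:
                raise ValueError("no overlap between matrix samples and labels")
            m = m.with_values(m.values.loc[keep])
            y = labels.loc[keep]
            finish_stage(stage, {"n_samples": m.n_samples,
                                 "n_features": m.n_features}, {})
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc

    # ---- preprocess ------------------------------------------------------
    if "preprocess" in config:
        stage = "preprocess"
        try:
            pp_cfg = PreprocessConfig(**config["preprocess"])
            m, stats = preprocess(m, pp_cfg)
            io.write_matrix(m, out / "preprocessed.tsv")
            files = {"preprocessed": out / "preprocessed.tsv"}
            if stats is not None:
                io.write_scaling_stats(stats, out / "scaling_stats.json")
                files["scaling_stats"] = out / "scaling_stats.json"
            finish_stage(stage, {"n_samples": m.n_samples,
                                 "n_features": m.n_features}, files)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- score -----------------------------------------------------------
    stage = "score"
    try:
        params = SDCFEParams(**{"seed": seed, **config.get("score", {})})
        table = score_features(m, y, params)
        io.write_score_table(table, out / "scores.tsv")
        finish_stage(stage, {"n_features": len(table),
                             "alpha": params.alpha, "lam": params.lam},
                     {"scores": out / "scores.tsv"})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- select ----------------------------------------------------------
    sdcfe_set = None
    if "select" in config:
        stage = "select"
        try:
            sel = config["select"]
            if "fraction" in sel:
                sdcfe_set = select_top_fraction(table, float(sel["fraction"]))
            elif "k" in sel:
                sdcfe_set = select_top_k(table, int(sel["k"]))
            else:
                raise KeyError("select section needs 'fraction' or 'k'")
            io.write_feature_set(sdcfe_set, out / "sdcfe_features.txt")
            finish_stage(stage, {"n_selected": len(sdcfe_set)},
                         {"sdcfe_features": out / "sdcfe_features.txt"})
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- importance + set algebra ---------------------------------------
    if "importance" in config:
        stage = "importance"
        try:
            bcfg = BoosterConfig(**{"seed": seed, **config["importance"]})
            imp_set = importance_rank(m, y, bcfg)
            io.write_feature_set(imp_set, out / "importance_features.txt")
            files = {"importance_features": out / "importance_features.txt"}
            info: dict[str, Any] = {"n_importance": len(imp_set)}
            if sdcfe_set is not None:
                shared, venn = intersect_sets(imp_set, sdcfe_set)
                union = nonredundant_union(imp_set, sdcfe_set)
                io.write_feature_set(shared, out / "shared_features.txt")
                io.write_feature_set(union, out / "union_features.txt")
                io.write_json(venn.to_dict(), out / "venn.json")
                files.update({
                    "shared_features": out / "shared_features.txt",
                    "union_features": out / "union_features.txt",
                    "venn": out / "venn.json",
                })
                info.update(venn.to_dict())
            finish_stage(stage, info, files)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- evaluate --------------------------------------------------------
    if "evaluate" in config:
        stage = "evaluate"
        try:
            from sklearn.model_selection import StratifiedKFold

            folds = int(config["evaluate"].get("cv_folds", 5))
            feats = list(sdcfe_set) if sdcfe_set is not None else m.feature_ids
            X = m.with_values(m.values[feats])
            y_arr = pd.Series(np.asarray(y, dtype=object),
                              index=m.values.index).astype(str)
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            preds = pd.Series(index=X.values.index, dtype=object)
            for train, test in skf.split(X.values, y_arr.to_numpy()):
                model = centroid_fit(
                    X.with_values(X.values.iloc[train]), y_arr.iloc[train]
                )
                preds.iloc[test] = centroid_predict(
                    model, X.with_values(X.values.iloc[test])
                ).to_numpy()
            cm = confusion(y_arr, preds)
            report = {
                "cv_folds": folds,
                "n_features_used": len(feats),
                "accuracy": float(np.trace(cm.to_numpy()) / cm.to_numpy().sum()),
                "mcc": mcc_from_confusion(cm),
                "classes": list(cm.index),
                "confusion": cm.to_numpy().tolist(),
            }
            io.write_json(report, out / "evaluation.json")
            finish_stage(stage, {"accuracy": report["accuracy"],
                                 "mcc": report["mcc"]},
                         {"evaluation": out / "evaluation.json"})
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
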