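"""End-to-end orchestration: simulate -> extract -> reliability -> train -> evaluate.

Stages hand files to each other in plain formats (CSV / JSON / NIfTI) so each
stage is independently runnable and auditable.  A run manifest records the
config hash and a checksum for every emitted file; rerunning a configured
pipeline skips stages whose outputs are present and hash-intact and
regenerates anything missing or stale, together with everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as rio
from .evaluation import (
    auc,
    auc_ci,
    confusion_metrics,
    correlation_matrix,
    roc_points,
)
from .imaging import traditional_features_table
from .modeling import StackedGradeClassifier
from .params import GroupDistributionParams, default_params
from .phantom import generate_cohort, perturb_mask, split_cohort
from .reliability import reproducibility_report
from .texture import feature_table, load_registry

__all__ = ["RunConfig", "RunManifest", "run_end_to_end",
           "stage_simulate", "stage_extract", "stage_reliability",
           "stage_train", "stage_evaluate"]

STAGES = ["simulate", "extract", "reliability", "train", "evaluate"]


class ModelingConfig(BaseModel):
    n_folds: int = 10
    n_trees: int = 500
    lambda_rule: str = "min"
    naive_stacking: bool = False


class ReliabilityConfig(BaseModel):
    n_subjects: int = 50
    intra_magnitude_px: float = 0.5
    inter_magnitude_px: float = 1.0


class RunConfig(BaseModel):
    """Fully serializable run configuration; config + seed fixes all outputs."""

    seed: int = Field(default=7, ge=0, lt=2 ** 31)
    n_low: int = Field(default=206, ge=0)
    n_high: int = Field(default=58, ge=0)
    ratio_train: float = Field(default=0.75, gt=0.0, lt=1.0)
    stratified: bool = True
    n_bins: int = Field(default=256, ge=2)
    registry_path: Optional[str] = None
    generator: GroupDistributionParams = Field(default_factory=default_params)
    modeling: ModelingConfig = Field(default_factory=ModelingConfig)
    reliability: ReliabilityConfig = Field(default_factory=ReliabilityConfig)
    image_format: str = "nifti"
    write_images: bool = True
    bootstrap_ci: int = 500

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate_json(text)

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Per-stage record of emitted files, checksums and timing."""

    def __init__(self, out_dir: Path, config: RunConfig):
        self.path = Path(out_dir) / "manifest.json"
        self.data = {"config_hash": config.config_hash(), "stages": {}}
        if self.path.exists():
            try:
                old = json.loads(self.path.read_text())
                if old.get("config_hash") == self.data["config_hash"]:
                    self.data = old
            except json.JSONDecodeError:
                pass

    def stage_valid(self, stage: str, out_dir: Path) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or not rec.get("valid"):
            return False
        for fname, digest in rec["files"].items():
            p = Path(out_dir) / fname
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, out_dir: Path, files: List[str],
               seconds: float, valid: bool = True) -> None:
        self.data["stages"][stage] = {
            "valid": valid,
            "seconds": round(seconds, 3),
            "files": {f: _sha256(Path(out_dir) / f) for f in files},
        }
        self.save()

    def invalidate_from(self, stage: str) -> None:
        for s in STAGES[STAGES.index(stage):]:
            if s in self.data["stages"]:
                self.data["stages"][s]["valid"] = False
        self.save()

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, out_dir: Path) -> List[str]:
    phantoms, truth = generate_cohort(cfg.n_low, cfg.n_high,
                                      params=cfg.generator, seed=cfg.seed)
    assignments = split_cohort(truth["patient_id"], truth["grade"],
                               ratio_train=cfg.ratio_train,
                               seed=cfg.seed + 1,
                               stratified=cfg.stratified)
    truth = truth.merge(
        pd.DataFrame([a.__dict__ for a in assignments]), on="patient_id")
    files = ["truth.csv"]
    truth.to_csv(out_dir / "truth.csv", index=False)
    if cfg.write_images:
        img_dir = out_dir / "images"
        for ph in phantoms:
            rio.write_phantom(img_dir, ph, fmt=cfg.image_format)
        suffix = ".nii.gz" if cfg.image_format == "nifti" else ".png"
        for ph in phantoms:
            for part in ("pre", "post", "mask", "necrosis"):
                files.append(f"images/{ph.patient_id}_{part}{suffix}")
    return files


def _load_phantoms(cfg: RunConfig, out_dir: Path):
    truth = pd.read_csv(out_dir / "truth.csv")
    if cfg.write_images:
        return [rio.read_phantom(out_dir / "images", row.patient_id,
                                 row.grade,
                                 sizes_true_cm=(row.transverse_cm,
                                                row.anteroposterior_cm,
                                                row.craniocaudal_cm),
                                 fmt=cfg.image_format)
                for row in truth.itertuples()], truth
    # images not persisted: regenerate deterministically from recorded seeds
    from .phantom import generate_phantom
    phantoms = [generate_phantom(row.grade, cfg.generator, seed=row.seed,
                                 patient_id=row.patient_id)
                for row in truth.itertuples()]
    return phantoms, truth


def stage_extract(cfg: RunConfig, out_dir: Path) -> List[str]:
    phantoms, truth = _load_phantoms(cfg, out_dir)
    registry = load_registry(cfg.registry_path)
    values, validity = feature_table(phantoms, registry=registry,
                                     n_bins=cfg.n_bins)
    values.to_csv(out_dir / "texture_features.csv")
    validity.to_csv(out_dir / "texture_validity.csv")
    trad = traditional_features_table(phantoms, seed=cfg.seed + 2)
    trad.to_csv(out_dir / "traditional_features.csv", index=False)
    (out_dir / "registry.json").write_text(registry.to_json())
    return ["texture_features.csv", "texture_validity.csv",
            "traditional_features.csv", "registry.json"]


def stage_reliability(cfg: RunConfig, out_dir: Path) -> List[str]:
    phantoms, _ = _load_phantoms(cfg, out_dir)
    subset = phantoms[: cfg.reliability.n_subjects]
    registry = load_registry(cfg.registry_path)
    rel = cfg.reliability
    reader1a, _ = feature_table(subset, registry=registry, n_bins=cfg.n_bins)
    masks_1b = [perturb_mask(ph.mask, rel.intra_magnitude_px,
                             seed=cfg.seed + 10 + k)
                for k, ph in enumerate(subset)]
    masks_2 = [perturb_mask(ph.mask, rel.inter_magnitude_px,
                            seed=cfg.seed + 20000 + k)
               for k, ph in enumerate(subset)]
    reader1b, _ = feature_table(subset, registry=registry, n_bins=cfg.n_bins,
                                masks=masks_1b)
    reader2, _ = feature_table(subset, registry=registry, n_bins=cfg.n_bins,
                               masks=masks_2)
    report, _, _ = reproducibility_report(reader1a, reader1b, reader2)
    report.to_csv(out_dir / "reliability.csv")
    return ["reliability.csv"]


def stage_train(cfg: RunConfig, out_dir: Path) -> List[str]:
    texture = pd.read_csv(out_dir / "texture_features.csv",
                          index_col="patient_id")
    trad = pd.read_csv(out_dir / "traditional_features.csv"
                       ).set_index("patient_id")
    truth = pd.read_csv(out_dir / "truth.csv").set_index("patient_id")
    train_ids = truth.index[truth["cohort"] == "training"]
    trad_num = trad.drop(columns=["t_stage"])
    X = pd.concat([texture, trad_num], axis=1)
    model = StackedGradeClassifier(
        texture_cols=list(texture.columns),
        traditional_cols=list(trad_num.columns),
        n_folds=cfg.modeling.n_folds,
        n_trees=cfg.modeling.n_trees,
        lambda_rule=cfg.modeling.lambda_rule,
        naive_stacking=cfg.modeling.naive_stacking,
        random_state=cfg.seed + 3,
    )
    model.fit(X.loc[train_ids], truth.loc[train_ids, "grade"])
    model.save(out_dir / "model.joblib")
    scores = model.predict_scores(X)
    scores["call"] = model.predict(X)
    scores["cohort"] = truth["cohort"]
    scores.index.name = "patient_id"
    scores.to_csv(out_dir / "scores.csv")
    sel = {"texture": model.selected_texture_features_,
           "traditional": model.selected_traditional_features_,
           "threshold": model.threshold_}
    (out_dir / "selected_features.json").write_text(
        json.dumps(sel, indent=1, sort_keys=True))
    return ["model.joblib", "scores.csv", "selected_features.json"]


def stage_evaluate(cfg: RunConfig, out_dir: Path) -> List[str]:
    scores = pd.read_csv(out_dir / "scores.csv", index_col="patient_id")
    truth = pd.read_csv(out_dir / "truth.csv").set_index("patient_id")
    sel = json.loads((out_dir / "selected_features.json").read_text())
    threshold = sel["threshold"]
    model_scores = {"SVM1": "score3", "SVM2": "score6", "SVM3": "score7"}
    # operating points fixed on training data: the stored stacked-model
    # threshold for SVM3, training Youden thresholds for SVM1/SVM2
    train_ids = truth.index[truth["cohort"] == "training"]
    y_train = truth.loc[train_ids, "grade"]
    from .evaluation import youden_threshold
    thresholds = {
        "score3": youden_threshold(scores.loc[train_ids, "score3"], y_train),
        "score6": youden_threshold(scores.loc[train_ids, "score6"], y_train),
        "score7": threshold,
    }
    metrics: Dict[str, Dict] = {}
    files = ["metrics.json"]
    for cohort in ("training", "validation"):
        ids = truth.index[truth["cohort"] == cohort]
        y = truth.loc[ids, "grade"]
        metrics[cohort] = {}
        for name, col in model_scores.items():
            s = scores.loc[ids, col].values
            a = auc(s, y)
            lo, hi = auc_ci(s, y, B=max(cfg.bootstrap_ci, 100),
                            seed=cfg.seed + 4)
            cm = confusion_metrics(s, y, thresholds[col], ci_bootstrap=0)
            metrics[cohort][name] = {
                "auc": a, "auc_ci95": [lo, hi],
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "accuracy": cm.accuracy,
                "fnr": cm.fnr, "fpr": cm.fpr,
                "fnr_cohort": cm.fnr_cohort, "fpr_cohort": cm.fpr_cohort,
            }
            roc = roc_points(scores.loc[ids, col].values, y)
            roc_df = pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr,
                                   "threshold": roc.thresholds})
            fname = f"roc_{name}_{cohort}.csv"
            roc_df.to_csv(out_dir / fname, index=False)
            files.append(fname)
    (out_dir / "metrics.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True))

    # correlation matrix over the selected modeling features
    texture = pd.read_csv(out_dir / "texture_features.csv",
                          index_col="patient_id")
    trad = pd.read_csv(out_dir / "traditional_features.csv"
                       ).set_index("patient_id").drop(columns=["t_stage"])
    cols = [c for c in sel["texture"] if c in texture.columns]
    tab = pd.concat([texture[cols],
                     trad[[c for c in sel["traditional"]
                           if c in trad.columns]]], axis=1)
    if tab.shape[1] >= 2:
        corr = correlation_matrix(tab)
        corr.signed.to_csv(out_dir / "correlation_matrix.csv")
        files.append("correlation_matrix.csv")
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(8, 7))
            im = ax.imshow(corr.absolute.values, vmin=0, vmax=1,
                           cmap="viridis")
            ax.set_xticks(range(len(corr.absolute)))
            ax.set_xticklabels(corr.absolute.columns, rotation=90, fontsize=5)
            ax.set_yticks(range(len(corr.absolute)))
            ax.set_yticklabels(corr.absolute.index, fontsize=5)
            fig.colorbar(im, ax=ax, label="|rho|")
            fig.tight_layout()
            fig.savefig(out_dir / "correlation_heatmap.png", dpi=120)
            plt.close(fig)
            files.append("correlation_heatmap.png")
        except Exception:
            pass
    return files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "reliability": stage_reliability,
    "train": stage_train,
    "evaluate": stage_evaluate,
}


def run_stage(cfg: RunConfig, out_dir, stage: str,
              manifest: Optional[RunManifest] = None) -> RunManifest:
    """Run one stage (verifying upstream outputs) and update the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or RunManifest(out_dir, cfg)
    for upstream in STAGES[: STAGES.index(stage)]:
        if upstream in ("reliability",) and stage != "reliability":
            continue  # reliability is a side report, not a data dependency
        if not manifest.stage_valid(upstream, out_dir):
            raise RuntimeError(
                f"stage {stage!r}: upstream stage {upstream!r} outputs are "
                "missing or do not match the manifest; rerun it first")
    manifest.invalidate_from(stage)
    t0 = time.time()
    try:
        files = _STAGE_FUNCS[stage](cfg, out_dir)
    except Exception:
        manifest.record(stage, out_dir, [], time.time() - t0, valid=False)
        raise
    manifest.record(stage, out_dir, files, time.time() - t0)
    return manifest


def run_end_to_end(cfg: RunConfig, out_dir) -> RunManifest:
    """Execute the full pipeline, reusing hash-intact stage outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out_dir, cfg)
    rerun_downstream = False
    for stage in STAGES:
        if not rerun_downstream and manifest.stage_valid(stage, out_dir):
            continue
        rerun_downstream = True
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](cfg, out_dir)
        except Exception:
            manifest.record(stage, out_dir, [], time.time() - t0, valid=False)
            raise
        manifest.record(stage, out_dir, files, time.time() - t0)
    return manifest
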