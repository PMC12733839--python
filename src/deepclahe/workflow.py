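"""End-to-end desk-scale workflow with a reproducibility manifest.

Runs generate -> train -> enhance -> classify -> compare -> interpret on
synthetic phantoms, writing every artifact under a run directory and
recording seeds, configs and SHA-256 hashes in ``manifest.json``.  A
rerun with the same config reproduces identical hashes; with
``resume=True`` stages whose artifacts already exist are skipped and
only missing (downstream) artifacts are regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import enhancement_ablation, make_backbone
from .compare import enhancement_comparison
from .enhance import STATIC_PARAMS, ClaheConfig, enhance_pipeline
from .interpret import gradcam, localization_score, save_overlay, train_conv_classifier
from .metrics import LossWeights
from .optimize import (ParamNet, TrainConfig, desk_scale_config, load_checkpoint,
                       save_checkpoint, summarize_stage_params, train_param_net)
from .phantom import LESION_STAGES, STAGES, make_dataset, save_sample
from .preprocess import DEFAULT_WINDOW, WindowConfig, to_uint8, window

__all__ = ["RunConfig", "run_workflow"]

log = logging.getLogger("deepclahe.workflow")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults are desk-scale."""

    out_dir: str = "runs/workflow"
    seed: int = 0
    n_per_stage: int = 10
    image_size: int = 64
    stages: tuple = STAGES
    epochs: int = 5
    batch_size: int = 8
    learning_rate: float = 1e-3
    surrogate_resolution: int = 5
    k_folds: int = 5
    window: WindowConfig = field(default_factory=lambda: DEFAULT_WINDOW)
    weights: LossWeights = field(default_factory=LossWeights)
    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    classifier_ids: tuple = ("LR", "SVM")
    interpret_epochs: int = 12
    resume: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["window"] = self.window.__dict__
        d["weights"] = self.weights.__dict__
        d["clahe"] = {"tiles": self.clahe.tiles, "clip_limit": self.clahe.clip_limit,
                      "n_bins": self.clahe.n_bins}
        d["stages"] = list(self.stages)
        d["classifier_ids"] = list(self.classifier_ids)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_done(paths: list[Path]) -> bool:
    return bool(paths) and all(p.exists() for p in paths)


def run_workflow(cfg: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "artifacts": {}}
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8)
    manifest["seeds"] = {name: int(s) for name, s in zip(
        ("data", "train", "classify", "compare", "interpret", "backbone",
         "aug", "spare"), seeds)}

    def record(stage: str, paths: dict[str, Path]):
        manifest["stages"][stage] = {"wall_s": round(time.time() - t_stage, 3)}
        for key, p in paths.items():
            manifest["artifacts"][f"{stage}/{key}"] = _sha256(Path(p))

    # -- generate ----------------------------------------------------------
    t_stage = time.time()
    data_dir = out / "phantoms"
    samples = make_dataset(cfg.n_per_stage, stages=cfg.stages,
                           base_seed=manifest["seeds"]["data"],
                           image_size=cfg.image_size)
    gen_paths = {}
    if not (cfg.resume and _stage_done([data_dir / "index.json"])):
        data_dir.mkdir(parents=True, exist_ok=True)
        index = []
        for i, s in enumerate(samples):
            name = f"{s.stage}_{i:04d}"
            save_sample(s, data_dir, name)
            index.append(name)
        (data_dir / "index.json").write_text(json.dumps(index, indent=2))
        log.info("generate: wrote %d phantoms", len(samples))
    gen_paths["index"] = data_dir / "index.json"
    record("generate", gen_paths)

    # -- train one parameter net per lesion stage --------------------------
    t_stage = time.time()
    model_dir = out / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    train_stages = [s for s in cfg.stages if s in LESION_STAGES]
    nets: dict[str, ParamNet] = {}
    train_paths = {}
    for si, stage in enumerate(train_stages):
        ckpt = model_dir / f"paramnet_{stage}.npz"
        hist_path = model_dir / f"history_{stage}.json"
        if cfg.resume and _stage_done([ckpt, hist_path]):
            nets[stage] = load_checkpoint(ckpt)
        else:
            seed = int(manifest["seeds"]["train"]) + si
            net = ParamNet(desk_scale_config(seed=seed,
                                             input_size=cfg.image_size))
            tcfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                               learning_rate=cfg.learning_rate,
                               weights=cfg.weights, stage_filter=stage,
                               seed=seed,
                               surrogate_resolution=cfg.surrogate_resolution,
                               window=cfg.window, clahe=cfg.clahe)
            net, hist = train_param_net(samples, net, tcfg)
            save_checkpoint(net, ckpt, extra={"stage": stage})
            hist_path.write_text(hist.to_json())
            nets[stage] = net
            log.info("train[%s]: final val loss %.4f", stage, hist.val_loss[-1])
        train_paths[f"ckpt_{stage}"] = ckpt
        train_paths[f"history_{stage}"] = hist_path
    # stage-parameter summary table
    summary_path = model_dir / "stage_params.csv"
    datasets = {st: [s for s in samples if s.stage == st] for st in train_stages}
    summarize_stage_params(nets, datasets).to_csv(summary_path, index=False,
                                                  float_format="%.6f")
    train_paths["stage_params"] = summary_path
    record("train", train_paths)

    # -- enhance a representative image per stage --------------------------
    t_stage = time.time()
    enh_dir = out / "enhanced"
    enh_dir.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    from .optimize import predict_params
    enh_paths = {}
    for stage in train_stages:
        s = datasets[stage][0]
        params = predict_params(nets[stage], s.image)
        result = enhance_pipeline(s.image, params, cfg.window, cfg.clahe)
        p = enh_dir / f"{stage}.png"
        Image.fromarray(result.enhanced8).save(p)
        (enh_dir / f"{stage}_params.json").write_text(json.dumps(
            {"alpha": params.alpha, "beta": params.beta,
             "gamma_clip": params.gamma_clip}, indent=2, sort_keys=True))
        enh_paths[f"png_{stage}"] = p
        enh_paths[f"params_{stage}"] = enh_dir / f"{stage}_params.json"
    record("enhance", enh_paths)

    # -- classify ----------------------------------------------------------
    t_stage = time.time()
    backbone = make_backbone(seed=manifest["seeds"]["backbone"])
    table = enhancement_ablation(
        samples, param_sources=("static", "network"),
        classifiers=cfg.classifier_ids, k=cfg.k_folds,
        seed=manifest["seeds"]["classify"], nets_by_stage=nets,
        backbone=backbone, window_cfg=cfg.window, clahe_cfg=cfg.clahe)
    cls_path = out / "classification.csv"
    table.to_csv(cls_path, index=False, float_format="%.6f")
    record("classify", {"table": cls_path})

    # -- compare -----------------------------------------------------------
    t_stage = time.time()
    cmp_table = enhancement_comparison(
        samples, static_lt=(STATIC_PARAMS.alpha, STATIC_PARAMS.beta),
        window_cfg=cfg.window)
    cmp_path = out / "comparison.csv"
    cmp_table.to_csv(cmp_path, index=False, float_format="%.6f")
    record("compare", {"table": cmp_path})

    # -- interpret ---------------------------------------------------------
    t_stage = time.time()
    itp_dir = out / "interpret"
    itp_dir.mkdir(parents=True, exist_ok=True)
    chronic = [s for s in samples if s.stage == "chronic"]
    normals = [s for s in samples if s.stage == "normal"]
    itp_paths = {}
    if chronic and normals:
        task = chronic + normals
        imgs8 = [to_uint8(window(s.image, cfg.window), cfg.window.lo,
                          cfg.window.hi) for s in task]
        labels = [1 if s.stage == "chronic" else 0 for s in task]
        clf = train_conv_classifier(imgs8, labels, n_classes=2,
                                    epochs=cfg.interpret_epochs,
                                    seed=manifest["seeds"]["interpret"],
                                    input_size=cfg.image_size)
        scores = []
        for s, im in zip(task, imgs8):
            if s.stage != "chronic":
                continue
            amap = gradcam(clf, im, target_class=1)
            scores.append(localization_score(amap, s.lesion_mask))
        amap = gradcam(clf, imgs8[0], target_class=1)
        overlay = itp_dir / "chronic_gradcam.png"
        save_overlay(imgs8[0], amap, overlay)
        loc_path = itp_dir / "localization.json"
        loc_path.write_text(json.dumps(
            {"mean_localization": float(np.mean(scores)),
             "n": len(scores)}, indent=2, sort_keys=True))
        itp_paths = {"overlay": overlay, "localization": loc_path}
    record("interpret", itp_paths)

    manifest["wall_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
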