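"""Stage classification from enhanced images.

Features come from the package's own conv encoder (pooled activations of
the parameter network); an optional pretrained DenseNet121 backbone can
be requested but requires an external deep-learning stack and downloaded
weights, so the encoder is the desk-scale default.  Classifiers are
logistic regression, an RBF SVM, and a random forest, evaluated with
seeded stratified k-fold cross-validation (k=25 by default, matching
the evaluation design) and reported as mean +/- SD of accuracy, PPV
(precision), recall, and F1.

Per-stage tasks are binary stage-vs-normal by default; a 5-way
multiclass mode is available by passing all labels at once.  Features
are standardized per fold with the scaler fit on the training split
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .enhance import STATIC_PARAMS, ClaheConfig, EnhancementParams, enhance_pipeline
from .optimize import ParamNet, desk_scale_config, grid_search_params, predict_params
from .phantom import StagedSample
from .preprocess import DEFAULT_WINDOW, WindowConfig

__all__ = [
    "make_backbone",
    "extract_features",
    "confusion_metrics",
    "ClassificationReport",
    "crossval_classify",
    "enhancement_ablation",
    "MODEL_IDS",
]

MODEL_IDS = ("LR", "SVM", "RF")


class EncoderBackbone:
    """Feature extractor built on a parameter network's conv encoder."""

    def __init__(self, net: ParamNet):
        self.net = net
        self.extractor_id = f"encoder[{net.cfg.conv_channels}-p{net.cfg.pooled_size}]"
        self.dim = net.feature_dim

    def extract(self, img8: np.ndarray) -> np.ndarray:
        x = self.net.prepare(img8)
        return self.net.forward_encoder(x)[0]


def make_backbone(kind: str = "encoder", net: ParamNet | None = None,
                  seed: int = 0) -> EncoderBackbone:
    if kind == "encoder":
        if net is None:
            net = ParamNet(desk_scale_config(seed=seed))
        return EncoderBackbone(net)
    if kind == "densenet121":
        raise RuntimeError(
            "the DenseNet121 backbone needs an external deep-learning stack "
            "and pretrained weights; use the 'encoder' backbone instead")
    raise ValueError(f"unknown backbone {kind!r}")


def extract_features(img8: np.ndarray, backbone: EncoderBackbone) -> np.ndarray:
    """Fixed-length finite feature vector for one 8-bit image."""
    vec = backbone.extract(img8)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite features")
    return vec


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Binary accuracy/precision/recall/F1 from confusion counts."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / (tp + fp + fn + tn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"accuracy": acc, "precision": precision, "recall": recall, "f1": f1}


@dataclass
class ClassificationReport:
    model_id: str
    k: int
    label_set: tuple
    acc_mean: float
    acc_sd: float
    ppv_mean: float
    ppv_sd: float
    recall_mean: float
    recall_sd: float
    f1_mean: float
    f1_sd: float
    per_fold: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        for m in (self.acc_mean, self.ppv_mean, self.recall_mean, self.f1_mean):
            if not 0.0 <= m <= 1.0:
                raise ValueError("metric means must lie in [0, 1]")


def _make_model(model_id: str, seed: int):
    if model_id == "LR":
        return LogisticRegression(C=1.0, max_iter=2000,  # L2 (default)
                                  random_state=seed)
    if model_id == "SVM":
        return SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    if model_id == "RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed,
                                      n_jobs=1)
    raise ValueError(f"unknown model {model_id!r}")


def crossval_classify(features: np.ndarray, labels, model_id: str, k: int = 25,
                      seed: int = 0, strict: bool = False) -> ClassificationReport:
    """Seeded stratified k-fold cross-validation of one classifier."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    min_count = int(counts.min())
    if min_count < k:
        if strict:
            raise ValueError(
                f"smallest class has {min_count} samples; cannot run {k} folds")
        warnings.warn(f"reducing folds from {k} to {min_count}", stacklevel=2)
        k = min_count
    if k < 2:
        raise ValueError("need at least 2 folds")

    binary = len(classes) == 2
    if binary:
        non_normal = [c for c in classes if c != "normal"]
        pos_label = non_normal[0] if len(non_normal) == 1 else classes[1]
        avg = dict(average="binary", pos_label=pos_label)
    else:
        avg = dict(average="macro")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(features, labels)):
        scaler = StandardScaler().fit(features[tr])
        model = _make_model(model_id, seed)
        model.fit(scaler.transform(features[tr]), labels[tr])
        pred = model.predict(scaler.transform(features[te]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # undefined-metric folds score 0
            rows.append({
                "fold": fold,
                "accuracy": accuracy_score(labels[te], pred),
                "ppv": precision_score(labels[te], pred, zero_division=0, **avg),
                "recall": recall_score(labels[te], pred, zero_division=0, **avg),
                "f1": f1_score(labels[te], pred, zero_division=0, **avg),
            })
    per_fold = pd.DataFrame(rows)
    return ClassificationReport(
        model_id=model_id, k=k, label_set=tuple(classes),
        acc_mean=per_fold["accuracy"].mean(), acc_sd=per_fold["accuracy"].std(ddof=1),
        ppv_mean=per_fold["ppv"].mean(), ppv_sd=per_fold["ppv"].std(ddof=1),
        recall_mean=per_fold["recall"].mean(), recall_sd=per_fold["recall"].std(ddof=1),
        f1_mean=per_fold["f1"].mean(), f1_sd=per_fold["f1"].std(ddof=1),
        per_fold=per_fold)


def _params_for(source: str, sample: StagedSample,
                nets_by_stage: dict[str, ParamNet] | None,
                task_stage: str, oracle_resolution: int,
                window_cfg: WindowConfig) -> EnhancementParams:
    if source == "static":
        return STATIC_PARAMS
    if source == "oracle":
        params, _ = grid_search_params(sample.image, oracle_resolution,
                                       window_cfg=window_cfg)
        return params
    if source == "network":
        if not nets_by_stage:
            raise ValueError("network source requires trained stage nets")
        net = nets_by_stage.get(task_stage) or next(iter(nets_by_stage.values()))
        return predict_params(net, sample.image)
    raise ValueError(f"unknown parameter source {source!r}")


def enhancement_ablation(samples: list[StagedSample],
                         param_sources=("static", "network"),
                         classifiers=MODEL_IDS, k: int = 5, seed: int = 0,
                         nets_by_stage: dict[str, ParamNet] | None = None,
                         backbone: EncoderBackbone | None = None,
                         oracle_resolution: int = 5,
                         window_cfg: WindowConfig = DEFAULT_WINDOW,
                         clahe_cfg: ClaheConfig = ClaheConfig()) -> pd.DataFrame:
    """Stage-vs-normal classification for each enhancement source.

    For every lesion stage present, builds the binary task (that stage's
    samples vs the normal controls), enhances each image with parameters
    from the given source, extracts encoder features, and cross-validates
    every classifier.  Returns one row per (stage, source, classifier).
    """
    if backbone is None:
        backbone = make_backbone(seed=seed)
    normals = [s for s in samples if s.stage == "normal"]
    lesion_stages = [st for st in ("hyperacute", "acute", "subacute", "chronic")
                     if any(s.stage == st for s in samples)]
    if not normals or not lesion_stages:
        raise ValueError("need both normal controls and lesion-stage samples")

    rows = []
    for stage in lesion_stages:
        task = [s for s in samples if s.stage == stage] + normals
        labels = np.array([s.stage for s in task])
        for source in param_sources:
            feats = []
            for s in task:
                params = _params_for(source, s, nets_by_stage, stage,
                                     oracle_resolution, window_cfg)
                result = enhance_pipeline(s.image, params, window_cfg, clahe_cfg)
                feats.append(extract_features(result.enhanced8, backbone))
            feats = np.array(feats)
            for model_id in classifiers:
                rep = crossval_classify(feats, labels, model_id, k=k, seed=seed)
                rows.append({
                    "stage": stage, "source": source, "classifier": model_id,
                    "acc_mean": rep.acc_mean, "acc_sd": rep.acc_sd,
                    "ppv_mean": rep.ppv_mean, "ppv_sd": rep.ppv_sd,
                    "recall_mean": rep.recall_mean, "recall_sd": rep.recall_sd,
                    "f1_mean": rep.f1_mean, "f1_sd": rep.f1_sd,
                })
    return pd.DataFrame(rows)
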