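"""Learned per-image enhancement parameters and their brute-force oracle.

A small CNN maps a windowed CT slice to three raw outputs that a scaled
logistic squashes into the allowed (alpha, beta, gamma) ranges, so any
network output is a valid parameter triple by construction.  The network
is trained to minimize the composite EME/PSNR/regularization loss of the
enhanced image.

The enhancement pipeline itself (windowing, 8-bit quantization, CLAHE)
is not differentiable, so training minimizes a per-image surrogate: the
true pipeline loss is evaluated once on a uniform grid over the
parameter box (the same machinery as the grid-search oracle) and
trilinearly interpolated in between.  The surrogate is exact at grid
nodes and piecewise-smooth elsewhere; the grid-search oracle then serves
as the independent correctness check for whatever the network learned.

Stage-specific models are independently trained copies, one per
temporal stage, summarized by per-stage 95% confidence intervals of the
predicted parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize

from . import nn
from .enhance import (PARAM_RANGES, ClaheConfig, EnhancementParams, clahe,
                      enhance_pipeline, linear_transform)
from .metrics import LossWeights, combined_loss
from .phantom import StagedSample
from .preprocess import DEFAULT_WINDOW, HUImage, WindowConfig, resample_to, to_uint8, window

__all__ = [
    "ParamNetConfig",
    "desk_scale_config",
    "ParamNet",
    "build_param_net",
    "constrain",
    "constrain_grad",
    "param_grid",
    "loss_surface",
    "grid_search_params",
    "TrainConfig",
    "TrainHistory",
    "train_param_net",
    "predict_params",
    "summarize_stage_params",
    "save_checkpoint",
    "load_checkpoint",
]

_RANGE_ARRAY = np.array([PARAM_RANGES["alpha"], PARAM_RANGES["beta"],
                         PARAM_RANGES["gamma_clip"]])


# ---------------------------------------------------------------------------
# parameter squashing

def _sigmoid(x):
    out = np.empty_like(np.asarray(x, dtype=float))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def constrain(raw) -> EnhancementParams:
    """Map three raw network outputs into the allowed parameter box.

    ``value = lo + (hi - lo) * logistic(raw)``: finite inputs land
    strictly inside the open intervals; raw zeros land on the midpoints.
    """
    raw = np.asarray(raw, dtype=float).reshape(3)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw parameter outputs must be finite")
    lo, hi = _RANGE_ARRAY[:, 0], _RANGE_ARRAY[:, 1]
    vals = lo + (hi - lo) * _sigmoid(raw)
    return EnhancementParams(*vals)


def constrain_grad(raw) -> np.ndarray:
    """Elementwise derivative d(constrained)/d(raw) of :func:`constrain`."""
    raw = np.asarray(raw, dtype=float)
    s = _sigmoid(raw)
    return (_RANGE_ARRAY[:, 1] - _RANGE_ARRAY[:, 0]) * s * (1.0 - s)


# ---------------------------------------------------------------------------
# network

@dataclass(frozen=True)
class ParamNetConfig:
    """Architecture knobs; the default mirrors the described topology."""

    conv_channels: tuple[int, ...] = (16, 32, 64, 128, 128)
    fc_widths: tuple[int, ...] = (512, 128, 32, 3)
    dropout_rate: float = 0.3
    pooled_size: int = 8
    input_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_channels) != 5:
            raise ValueError("exactly five convolutional widths required")
        if len(self.fc_widths) != 4 or self.fc_widths[-1] != 3:
            raise ValueError("exactly four fc widths ending in 3 required")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.pooled_size < 1 or self.input_size < 16:
            raise ValueError("invalid pooled/input size")


def desk_scale_config(seed: int = 0, input_size: int = 64) -> ParamNetConfig:
    """Compact architecture sized for pure-numpy training on one CPU core."""
    return ParamNetConfig(conv_channels=(8, 16, 32, 32, 32),
                          fc_widths=(64, 32, 16, 3), dropout_rate=0.1,
                          pooled_size=2, input_size=input_size, seed=seed)


class ParamNet:
    """Five conv/BN/ReLU/maxpool blocks -> adaptive pool -> four FC layers."""

    def __init__(self, cfg: ParamNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        c_prev = 1
        for c in cfg.conv_channels:
            layers += [nn.Conv2d(c_prev, c, rng), nn.BatchNorm2d(c),
                       nn.ReLU(), nn.MaxPool2()]
            c_prev = c
        self.gradcam_layer_index = len(layers) - 2  # ReLU of the last conv block
        layers.append(nn.AdaptiveAvgPool2d(cfg.pooled_size))
        self.encoder_end = len(layers)  # features = output of this prefix
        layers.append(nn.Flatten())
        n_in = cfg.conv_channels[-1] * cfg.pooled_size ** 2
        for w in cfg.fc_widths[:-1]:
            layers += [nn.Linear(n_in, w, rng), nn.ReLU(),
                       nn.Dropout(cfg.dropout_rate, np.random.default_rng(
                           rng.integers(0, 2 ** 31 - 1)))]
            n_in = w
        head_out = nn.Linear(n_in, cfg.fc_widths[-1], rng)
        # near-zero output init: predictions start at the range midpoints,
        # inside the basin the squashed-parameter gradients descend from
        head_out.W *= 0.01
        layers.append(head_out)
        self.net = nn.Sequential(layers)

    # -- plumbing -----------------------------------------------------------
    def forward_raw(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Raw (unconstrained) parameter triples for a (N,1,S,S) batch."""
        return self.net.forward(x, train=train)

    def backward(self, graw: np.ndarray) -> np.ndarray:
        return self.net.backward(graw)

    def forward_encoder(self, x: np.ndarray) -> np.ndarray:
        """Pooled conv-encoder activations, flattened (feature extractor)."""
        out = x
        for layer in self.net.layers[: self.encoder_end]:
            out = layer.forward(out, train=False)
        return out.reshape(out.shape[0], -1)

    @property
    def feature_dim(self) -> int:
        return self.cfg.conv_channels[-1] * self.cfg.pooled_size ** 2

    def param_count(self) -> int:
        return sum(p.size for p, _ in self.net.param_pairs())

    def prepare(self, img) -> np.ndarray:
        """Bring an HU image or 8-bit array to a (1,1,S,S) [0,1] tensor."""
        s = self.cfg.input_size
        if isinstance(img, HUImage):
            if img.shape != (s, s):
                img = resample_to(img, s)
            arr = to_uint8(window(img), DEFAULT_WINDOW.lo, DEFAULT_WINDOW.hi) / 255.0
        else:
            arr = np.asarray(img, dtype=float)
            if arr.max() > 1.0:
                arr = arr / 255.0
            if arr.shape != (s, s):
                arr = resize(arr, (s, s), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
        return arr[None, None, :, :]


def build_param_net(cfg: ParamNetConfig) -> ParamNet:
    return ParamNet(cfg)


# ---------------------------------------------------------------------------
# grid-search oracle and loss surface

def param_grid(resolution: int = 9) -> list[np.ndarray]:
    """Uniform per-axis grids over the three constrained ranges."""
    if resolution < 3:
        raise ValueError("grid resolution must be at least 3 per axis")
    return [np.linspace(lo, hi, resolution) for lo, hi in _RANGE_ARRAY]


def loss_surface(img: HUImage, resolution: int = 9,
                 weights: LossWeights = LossWeights(),
                 window_cfg: WindowConfig = DEFAULT_WINDOW,
                 clahe_cfg: ClaheConfig = ClaheConfig(),
                 block_size: int = 8):
    """True pipeline loss on the full parameter grid.

    Returns ``(axes, cube)`` where ``cube[i, j, k]`` is the composite
    loss at ``(alpha_i, beta_j, gamma_k)``.
    """
    axes = param_grid(resolution)
    alphas, betas, gammas = axes
    orig8 = to_uint8(window(img, window_cfg), window_cfg.lo, window_cfg.hi)
    cube = np.empty((len(alphas), len(betas), len(gammas)))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            lt8 = to_uint8(window(linear_transform(img, a, b), window_cfg),
                           window_cfg.lo, window_cfg.hi)
            for k, g in enumerate(gammas):
                enhanced = clahe(lt8, clahe_cfg.with_clip(g))
                rep = combined_loss(orig8, enhanced, EnhancementParams(a, b, g),
                                    weights, block_size=block_size)
                cube[i, j, k] = rep.loss
    return axes, cube


def grid_search_params(img: HUImage, grid_resolution: int = 9,
                       weights: LossWeights = LossWeights(),
                       window_cfg: WindowConfig = DEFAULT_WINDOW,
                       clahe_cfg: ClaheConfig = ClaheConfig(),
                       block_size: int = 8) -> tuple[EnhancementParams, float]:
    """Exhaustive argmin over the grid; ties break toward smaller values."""
    axes, cube = loss_surface(img, grid_resolution, weights, window_cfg,
                              clahe_cfg, block_size)
    flat = int(np.argmin(cube))  # first occurrence = lexicographic tie-break
    i, j, k = np.unravel_index(flat, cube.shape)
    params = EnhancementParams(axes[0][i], axes[1][j], axes[2][k])
    return params, float(cube[i, j, k])


def _trilinear(axes, cube, p):
    """Interpolated value and gradient of the loss cube at point ``p``."""
    idx, frac = [], []
    for ax, (lo, hi), v in zip(axes, _RANGE_ARRAY, p):
        n = len(ax)
        t = (v - lo) / (hi - lo) * (n - 1)
        i = int(np.clip(np.floor(t), 0, n - 2))
        idx.append(i)
        frac.append(float(np.clip(t - i, 0.0, 1.0)))
    (i, j, k), (fx, fy, fz) = idx, frac
    c = cube[i:i + 2, j:j + 2, k:k + 2]
    wx = np.array([1 - fx, fx])
    wy = np.array([1 - fy, fy])
    wz = np.array([1 - fz, fz])
    value = np.einsum("i,j,k,ijk->", wx, wy, wz, c)
    steps = [(hi - lo) / (len(ax) - 1)
             for ax, (lo, hi) in zip(axes, _RANGE_ARRAY)]
    gx = np.einsum("j,k,jk->", wy, wz, c[1] - c[0]) / steps[0]
    gy = np.einsum("i,k,ik->", wx, wz, c[:, 1] - c[:, 0]) / steps[1]
    gz = np.einsum("i,j,ij->", wx, wy, c[:, :, 1] - c[:, :, 0]) / steps[2]
    return float(value), np.array([gx, gy, gz])


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    epochs: int = 250
    batch_size: int = 16
    learning_rate: float = 1e-3
    weights: LossWeights = field(default_factory=LossWeights)
    stage_filter: str | None = None
    seed: int = 0
    surrogate_resolution: int = 7
    val_fraction: float = 0.2
    window: WindowConfig = field(default_factory=lambda: DEFAULT_WINDOW)
    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    block_size: int = 8

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be at least 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    mean_eme: list[float] = field(default_factory=list)
    mean_psnr: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _stratified_split(samples, val_fraction, rng):
    by_stage: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_stage.setdefault(s.stage, []).append(i)
    train_idx, val_idx = [], []
    for stage in sorted(by_stage):
        idx = np.array(by_stage[stage])
        rng.shuffle(idx)
        n_val = int(round(val_fraction * len(idx)))
        if len(idx) > 1:
            n_val = max(n_val, 1)
        n_val = min(n_val, len(idx) - 1) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return sorted(train_idx), sorted(val_idx)


def train_param_net(dataset: list[StagedSample], net: ParamNet,
                    tcfg: TrainConfig) -> tuple[ParamNet, TrainHistory]:
    """Minimize the composite loss via the interpolated-surface surrogate."""
    if tcfg.stage_filter is not None:
        dataset = [s for s in dataset if s.stage == tcfg.stage_filter]
    if not dataset:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(tcfg.seed)
    train_idx, val_idx = _stratified_split(dataset, tcfg.val_fraction, rng)
    if not val_idx:  # degenerate single-sample datasets
        val_idx = list(train_idx)

    # precompute network inputs and per-image loss surfaces
    xs = {i: net.prepare(dataset[i].image) for i in set(train_idx) | set(val_idx)}
    surfaces = {}
    for i in train_idx:
        surfaces[i] = loss_surface(dataset[i].image, tcfg.surrogate_resolution,
                                   tcfg.weights, tcfg.window, tcfg.clahe,
                                   tcfg.block_size)
    val_orig8 = {
        i: to_uint8(window(dataset[i].image, tcfg.window),
                    tcfg.window.lo, tcfg.window.hi)
        for i in val_idx
    }

    # warm-start the output bias at the argmin of the mean training surface:
    # the surrogate is multi-modal (an identity-transform basin competes with
    # the enhancement basin), and descending from the best constant triple
    # keeps refinement inside the globally best basin
    mean_cube = np.mean([surfaces[i][1] for i in train_idx], axis=0)
    i0, j0, k0 = np.unravel_index(int(np.argmin(mean_cube)), mean_cube.shape)
    axes0 = surfaces[train_idx[0]][0]
    start = np.array([axes0[0][i0], axes0[1][j0], axes0[2][k0]])
    lo, hi = _RANGE_ARRAY[:, 0], _RANGE_ARRAY[:, 1]
    frac = np.clip((start - lo) / (hi - lo), 1e-3, 1 - 1e-3)
    out_layer = net.net.layers[-1]
    out_layer.b[...] = np.clip(np.log(frac / (1 - frac)), -4.0, 4.0)

    opt = nn.Adam(net.net.param_pairs(), lr=tcfg.learning_rate)
    history = TrainHistory()
    order = np.array(train_idx)
    for epoch in range(tcfg.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = order[start:start + tcfg.batch_size]
            x = np.concatenate([xs[i] for i in batch], axis=0)
            raw = net.forward_raw(x, train=True)
            graw = np.zeros_like(raw)
            batch_loss = 0.0
            for bi, i in enumerate(batch):
                params = constrain(raw[bi])
                value, gparams = _trilinear(*surfaces[i], params.as_tuple())
                batch_loss += value
                graw[bi] = gparams * constrain_grad(raw[bi])
            batch_loss /= len(batch)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss")
            net.backward(graw / len(batch))
            opt.step()
            epoch_losses.append(batch_loss)
        history.train_loss.append(float(np.mean(epoch_losses)))

        # validation on the true (non-surrogate) pipeline
        v_loss, v_eme, v_psnr = [], [], []
        for i in val_idx:
            raw = net.forward_raw(xs[i], train=False)
            params = constrain(raw[0])
            result = enhance_pipeline(dataset[i].image, params, tcfg.window,
                                      tcfg.clahe)
            rep = combined_loss(val_orig8[i], result.enhanced8, params,
                                tcfg.weights, block_size=tcfg.block_size)
            v_loss.append(rep.loss)
            v_eme.append(rep.eme)
            v_psnr.append(rep.psnr)
        history.val_loss.append(float(np.mean(v_loss)))
        history.mean_eme.append(float(np.mean(v_eme)))
        history.mean_psnr.append(float(np.mean(v_psnr)))
    return net, history


def predict_params(net: ParamNet, img: HUImage | np.ndarray) -> EnhancementParams:
    """Deterministic per-image parameter prediction (dropout disabled)."""
    if isinstance(img, HUImage) and img.shape != (net.cfg.input_size,) * 2:
        warnings.warn(
            f"input {img.shape} resampled to {net.cfg.input_size} for prediction",
            stacklevel=2)
    x = net.prepare(img)
    raw = net.forward_raw(x, train=False)
    return constrain(raw[0])


# ---------------------------------------------------------------------------
# stage-level reporting

def summarize_stage_params(nets_by_stage: dict[str, ParamNet],
                           datasets_by_stage: dict[str, list[StagedSample]],
                           confidence: float = 0.95) -> pd.DataFrame:
    """Per-stage mean and t-based CI of each predicted parameter.

    Output rows mirror the stage-by-parameter bounds table layout:
    columns ``{slope, intercept, clip} x {mean, lb, ub}``.
    """
    rows = []
    for stage, net in nets_by_stage.items():
        samples = datasets_by_stage[stage]
        if len(samples) < 2:
            raise ValueError(f"stage {stage!r} needs at least 2 samples")
        preds = np.array([predict_params(net, s.image).as_tuple()
                          for s in samples])
        n = len(preds)
        tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        row = {"stage": stage, "n": n}
        for col, name, key in ((0, "slope", "alpha"), (1, "intercept", "beta"),
                               (2, "clip", "gamma_clip")):
            lo, hi = PARAM_RANGES[key]
            mean = preds[:, col].mean()
            half = tq * preds[:, col].std(ddof=1) / np.sqrt(n)
            row[f"{name}_mean"] = mean
            row[f"{name}_lb"] = float(np.clip(mean - half, lo, hi))
            row[f"{name}_ub"] = float(np.clip(mean + half, lo, hi))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(net: ParamNet, path, extra: dict | None = None) -> None:
    """Single-file archive: config JSON + all weights and BN statistics."""
    arrays = {f"arr_{i}": a for i, a in enumerate(net.net.state_arrays())}
    meta = {"config": net.cfg.__dict__, "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ParamNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        cfg_dict["fc_widths"] = tuple(cfg_dict["fc_widths"])
        net = ParamNet(ParamNetConfig(**cfg_dict))
        for i, target in enumerate(net.net.state_arrays()):
            target[...] = data[f"arr_{i}"]
    return net
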