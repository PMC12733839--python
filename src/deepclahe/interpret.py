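"""Grad-CAM attention maps over the package's conv networks.

Grad-CAM weighs the activations of a designated convolutional layer by
the spatially averaged gradient of a scalar target score with respect to
those activations, passes the weighted sum through a ReLU, upsamples to
the input size, and max-normalizes to [0, 1].  The target layer defaults
to the last conv block's ReLU output (the standard choice).  Combined
with a phantom's ground-truth lesion mask, the fraction of attention
mass inside the mask quantifies whether a trained classifier actually
attends to lesions.

Also hosts a compact CNN stage classifier (three conv/BN/ReLU/pool
blocks, global average pooling, one linear layer) used to produce the
trained networks those attention analyses need; the feature-based
classifiers of :mod:`deepclahe.classify` have no gradient path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn

__all__ = [
    "AttentionMap",
    "gradcam",
    "localization_score",
    "save_overlay",
    "ConvClassifier",
    "train_conv_classifier",
]


@dataclass
class AttentionMap:
    heat: np.ndarray          # relevance in [0, 1], input-shaped
    target: int               # index of the explained score
    layer_id: int             # layer index inside the network Sequential
    all_zero: bool = False    # flagged when gradients vanish everywhere


class ConvClassifier:
    """Small CNN classifier with a Grad-CAM-ready conv feature map."""

    def __init__(self, n_classes: int, input_size: int = 64,
                 channels=(8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        c_prev = 1
        for c in channels:
            layers += [nn.Conv2d(c_prev, c, rng), nn.BatchNorm2d(c),
                       nn.ReLU(), nn.MaxPool2()]
            c_prev = c
        self.gradcam_layer_index = len(layers) - 2  # last block's ReLU
        layers += [nn.AdaptiveAvgPool2d(1), nn.Flatten(),
                   nn.Linear(channels[-1], n_classes, rng)]
        self.net = nn.Sequential(layers)
        self.input_size = input_size
        self.n_classes = n_classes

    def prepare(self, img8: np.ndarray) -> np.ndarray:
        arr = np.asarray(img8, dtype=float)
        if arr.max() > 1.0:
            arr = arr / 255.0
        s = self.input_size
        if arr.shape != (s, s):
            arr = resize(arr, (s, s), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        return arr[None, None, :, :]

    def forward_raw(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    def predict(self, img8: np.ndarray) -> int:
        logits = self.forward_raw(self.prepare(img8), train=False)
        return int(np.argmax(logits[0]))


def train_conv_classifier(images8: list[np.ndarray], labels: list[int],
                          n_classes: int, epochs: int = 50,
                          batch_size: int = 8, lr: float = 1e-2,
                          seed: int = 0, input_size: int = 64) -> ConvClassifier:
    """Softmax cross-entropy training of the small CNN classifier."""
    clf = ConvClassifier(n_classes, input_size=input_size, seed=seed)
    xs = np.concatenate([clf.prepare(im) for im in images8], axis=0)
    ys = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(clf.net.param_pairs(), lr=lr)
    order = np.arange(len(ys))
    for _ in range(epochs):
        rng.shuffle(order)
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            logits = clf.forward_raw(xs[idx], train=True)
            loss, grad = nn.cross_entropy_grad(logits, ys[idx])
            if not np.isfinite(loss):
                raise RuntimeError("classifier training diverged")
            clf.backward(grad)
            opt.step()
    return clf


def gradcam(net, img8: np.ndarray, target_class: int = 0,
            layer: int | None = None) -> AttentionMap:
    """Grad-CAM heat map of ``net``'s target score over one 8-bit image.

    ``net`` must expose ``prepare``, ``forward_raw``, ``backward``, a
    ``net`` Sequential with cached activations, and a default
    ``gradcam_layer_index`` (both the parameter network and the conv
    classifier do).
    """
    layer = net.gradcam_layer_index if layer is None else layer
    img8 = np.asarray(img8)
    x = net.prepare(img8)
    out = net.forward_raw(x, train=False)
    gout = np.zeros_like(out)
    gout[0, target_class] = 1.0
    net.backward(gout)

    acts = net.net.activations[layer]          # (1, C, h, w)
    grads = net.net.output_grads[layer]
    weights = grads.mean(axis=(2, 3))          # (1, C)
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1)[0], 0.0)
    heat = resize(cam, img8.shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    heat = np.maximum(heat, 0.0)
    peak = heat.max()
    if peak == 0.0:
        return AttentionMap(heat=heat, target=target_class, layer_id=layer,
                            all_zero=True)
    return AttentionMap(heat=heat / peak, target=target_class, layer_id=layer)


def localization_score(attention: AttentionMap, mask: np.ndarray) -> float:
    """Fraction of total attention mass falling inside the lesion mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != attention.heat.shape:
        raise ValueError("mask and attention map shapes differ")
    if not mask.any():
        raise ValueError("empty lesion mask")
    total = attention.heat.sum()
    if total == 0:
        return 0.0
    return float(attention.heat[mask].sum() / total)


def save_overlay(img8: np.ndarray, attention: AttentionMap, path,
                 alpha: float = 0.45) -> None:
    """Write a PNG of the grayscale image blended with a jet heat map."""
    from matplotlib import cm
    from PIL import Image

    gray = np.asarray(img8, dtype=float)
    gray = gray / max(gray.max(), 1.0)
    base = np.stack([gray] * 3, axis=-1)
    heat_rgb = cm.jet(attention.heat)[..., :3]
    blended = (1 - alpha) * base + alpha * heat_rgb
    Image.fromarray((255 * np.clip(blended, 0, 1)).astype(np.uint8)).save(path)
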