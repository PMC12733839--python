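"""Image-quality metrics and the composite optimization loss.

``loss = w1 * EMEloss + w2 * PSNRloss + lambda * Regloss`` with default
weights w1=0.8, w2=0.2, lambda=0.01.  The EME term rewards contrast
enhancement, the PSNR term anchors the output to the original image, and
the regularizer penalizes parameter triples that drift toward the edges
of their allowed ranges.  Lower loss is better.

Conventions pinned here (published EME/PSNR definitions vary):

* EME is the Agaian-style block measure: the image is partitioned into
  non-overlapping ``block_size``-square blocks (trailing partial blocks
  dropped) and ``20*log10((max+1)/(min+1))`` is averaged over blocks;
  the +1 offsets make empty/zero blocks well defined.
* PSNR is ``10*log10(255^2/MSE)`` against the windowed 8-bit original
  (the pre-transform image), capped at 100 dB for identical inputs.
* EMEloss = -EME/eme_scale and PSNRloss = -PSNR/psnr_scale with scales
  50 and 40, which bring both components to order one for typical brain
  CT so the 0.8/0.2 weighting is meaningful.
* Regloss is the sum of squared normalized deviations of (alpha, beta,
  gamma) from their range midpoints; a parameter sitting at a range
  endpoint contributes exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enhance import PARAM_RANGES, EnhancementParams

__all__ = ["LossWeights", "MetricReport", "eme", "psnr", "reg_loss", "combined_loss"]

PSNR_CAP_DB = 100.0


@dataclass(frozen=True)
class LossWeights:
    w1: float = 0.8
    w2: float = 0.2
    lam: float = 0.01
    eme_scale: float = 50.0
    psnr_scale: float = 40.0

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0 or self.lam < 0:
            raise ValueError("weights must be nonnegative")
        if self.eme_scale <= 0 or self.psnr_scale <= 0:
            raise ValueError("normalization scales must be positive")


@dataclass(frozen=True)
class MetricReport:
    eme: float
    psnr: float
    loss: float
    eme_loss: float
    psnr_loss: float
    reg_loss: float


def eme(img8: np.ndarray, block_size: int = 8) -> float:
    """Mean blockwise ``20*log10((max+1)/(min+1))`` contrast measure."""
    img8 = np.asarray(img8, dtype=float)
    if block_size < 2:
        raise ValueError("block size must be at least 2")
    h, w = img8.shape
    nb_r, nb_c = h // block_size, w // block_size
    if nb_r == 0 or nb_c == 0:
        raise ValueError("image smaller than one block")
    crop = img8[: nb_r * block_size, : nb_c * block_size]
    blocks = crop.reshape(nb_r, block_size, nb_c, block_size)
    bmax = blocks.max(axis=(1, 3))
    bmin = blocks.min(axis=(1, 3))
    return float(np.mean(20.0 * np.log10((bmax + 1.0) / (bmin + 1.0))))


def psnr(ref8: np.ndarray, test8: np.ndarray) -> float:
    """``10*log10(255^2/MSE)``; identical images return the 100 dB cap."""
    ref8 = np.asarray(ref8, dtype=float)
    test8 = np.asarray(test8, dtype=float)
    if ref8.shape != test8.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((ref8 - test8) ** 2))
    if mse == 0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(255.0 ** 2 / mse))


def reg_loss(params: EnhancementParams) -> float:
    """Sum of squared normalized deviations from the range midpoints."""
    total = 0.0
    for name, value in zip(("alpha", "beta", "gamma_clip"), params.as_tuple()):
        lo, hi = PARAM_RANGES[name]
        mid = 0.5 * (lo + hi)
        halfwidth = 0.5 * (hi - lo)
        total += ((value - mid) / halfwidth) ** 2
    return total


def combined_loss(orig8: np.ndarray, enhanced8: np.ndarray,
                  params: EnhancementParams,
                  w: LossWeights = LossWeights(),
                  block_size: int = 8) -> MetricReport:
    """Evaluate the composite loss for an enhanced image."""
    if np.asarray(orig8).shape != np.asarray(enhanced8).shape:
        raise ValueError("original and enhanced images must share a shape")
    eme_val = eme(enhanced8, block_size=block_size)
    psnr_val = psnr(orig8, enhanced8)
    eme_l = -eme_val / w.eme_scale
    psnr_l = -psnr_val / w.psnr_scale
    reg_l = reg_loss(params)
    loss = w.w1 * eme_l + w.w2 * psnr_l + w.lam * reg_l
    return MetricReport(eme=eme_val, psnr=psnr_val, loss=loss,
                        eme_loss=eme_l, psnr_loss=psnr_l, reg_loss=reg_l)
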