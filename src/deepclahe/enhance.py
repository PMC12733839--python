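"""Constrained linear HU transform, CLAHE, and classical enhancers.

The core operation is ``HU' = CLAHE(alpha * HU + beta; gamma)``: a slope/
intercept transform applied in HU space, followed by windowing, 8-bit
quantization, and contrast-limited adaptive histogram equalization whose
clip limit gamma is the third optimized parameter.  Parameter ranges are
hard method constraints: alpha in [0.5, 2.0], beta in [-5, 5] HU, gamma
in [0.1, 2.0].

CLAHE dialect (dialects differ across libraries, so this one is pinned):

* tile grid 8x8 by default, 256 histogram bins;
* the clip limit is *relative* — the per-bin ceiling is
  ``clip_limit * tile_pixels / n_bins`` (a multiple of the mean bin
  count), which keeps the gamma range meaningful across tile sizes;
* clipped excess is redistributed uniformly over all bins in a single
  pass (no iterative re-clipping);
* the image is padded by reflection so the tile grid divides evenly;
* per-tile mappings are ``255 * CDF`` and are combined by bilinear
  interpolation between tile centers (clamped at the borders), with
  round-half-up quantization at the very end.

With a single tile and an unbounded clip limit this reduces bit-exactly
to global histogram equalization, which is how the implementation is
cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DEFAULT_WINDOW, HUImage, WindowConfig, to_uint8, window

__all__ = [
    "PARAM_RANGES",
    "EnhancementParams",
    "ClaheConfig",
    "linear_transform",
    "clahe",
    "he",
    "ahe",
    "gamma_correct",
    "power_law",
    "log_transform",
    "enhance_pipeline",
    "PipelineResult",
    "CLASSIC_ENHANCERS",
]

#: hard constraint ranges for (alpha, beta, gamma_clip)
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.5, 2.0),
    "beta": (-5.0, 5.0),
    "gamma_clip": (0.1, 2.0),
}


@dataclass(frozen=True)
class EnhancementParams:
    """The optimized triple: slope alpha, intercept beta (HU), CLAHE clip gamma."""

    alpha: float
    beta: float
    gamma_clip: float

    def __post_init__(self):
        for name, value in (("alpha", self.alpha), ("beta", self.beta),
                            ("gamma_clip", self.gamma_clip)):
            lo, hi = PARAM_RANGES[name]
            if not np.isfinite(value) or not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside allowed range [{lo}, {hi}]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma_clip)


#: static baseline used throughout comparisons (range midpoint slope, no
#: shift, unit relative clip)
STATIC_PARAMS = EnhancementParams(1.25, 0.0, 1.0)


@dataclass(frozen=True)
class ClaheConfig:
    tiles: tuple[int, int] = (8, 8)
    clip_limit: float = 1.0
    n_bins: int = 256

    def __post_init__(self):
        if self.tiles[0] < 1 or self.tiles[1] < 1:
            raise ValueError("tile grid must be at least 1x1")
        if self.clip_limit <= 0:
            raise ValueError("clip limit must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 histogram bins")

    def with_clip(self, clip: float) -> "ClaheConfig":
        return ClaheConfig(self.tiles, clip, self.n_bins)


def linear_transform(img: HUImage, alpha: float, beta: float) -> HUImage:
    """``out = alpha * HU + beta`` with hard range validation."""
    for name, value in (("alpha", alpha), ("beta", beta)):
        lo, hi = PARAM_RANGES[name]
        if not np.isfinite(value) or not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside allowed range [{lo}, {hi}]")
    return img.with_pixels(alpha * img.pixels + beta,
                           note=f"lt alpha={alpha} beta={beta}")


def _check_uint8(img8: np.ndarray) -> np.ndarray:
    img8 = np.asarray(img8)
    if img8.dtype != np.uint8:
        if np.issubdtype(img8.dtype, np.integer) and img8.min() >= 0 and img8.max() <= 255:
            img8 = img8.astype(np.uint8)
        else:
            raise ValueError("expected an integer image with values in [0, 255]")
    return img8


def _tile_luts(img8: np.ndarray, cfg: ClaheConfig) -> tuple[np.ndarray, int, int]:
    """Per-tile float mapping tables (255*CDF after clipping), plus tile size."""
    h, w = img8.shape
    tr, tc = cfg.tiles
    th = -(-h // tr)  # ceil
    tw = -(-w // tc)
    pad_r, pad_c = tr * th - h, tc * tw - w
    padded = np.pad(img8, ((0, pad_r), (0, pad_c)), mode="reflect") \
        if (pad_r or pad_c) else img8
    bins = (padded.astype(np.int64) * cfg.n_bins) >> 8  # value -> bin index
    tiles = bins.reshape(tr, th, tc, tw).transpose(0, 2, 1, 3).reshape(tr * tc, th * tw)
    offsets = np.arange(tr * tc)[:, None] * cfg.n_bins
    hist = np.bincount((tiles + offsets).ravel(),
                       minlength=tr * tc * cfg.n_bins).reshape(tr * tc, cfg.n_bins)
    hist = hist.astype(float)
    ceiling = cfg.clip_limit * (th * tw) / cfg.n_bins
    excess = np.clip(hist - ceiling, 0, None).sum(axis=1, keepdims=True)
    hist = np.minimum(hist, ceiling) + excess / cfg.n_bins
    cdf = np.cumsum(hist, axis=1) / (th * tw)
    luts = 255.0 * cdf  # (tiles, n_bins), float
    return luts.reshape(tr, tc, cfg.n_bins), th, tw


def clahe(img8: np.ndarray, cfg: ClaheConfig = ClaheConfig()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (dialect above)."""
    img8 = _check_uint8(img8)
    h, w = img8.shape
    tr, tc = cfg.tiles
    if h // tr < 2 or w // tc < 2:
        raise ValueError("tiles smaller than 2x2 pixels")
    luts, th, tw = _tile_luts(img8, cfg)

    bins = (img8.astype(np.int64) * cfg.n_bins) >> 8
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    ty = np.clip((rows + 0.5) / th - 0.5, 0, tr - 1)
    tx = np.clip((cols + 0.5) / tw - 0.5, 0, tc - 1)
    i0 = np.minimum(ty.astype(int), tr - 1)
    j0 = np.minimum(tx.astype(int), tc - 1)
    i1 = np.minimum(i0 + 1, tr - 1)
    j1 = np.minimum(j0 + 1, tc - 1)
    fy = ty - i0
    fx = tx - j0
    i0b = np.broadcast_to(i0, (h, w))
    i1b = np.broadcast_to(i1, (h, w))
    j0b = np.broadcast_to(j0, (h, w))
    j1b = np.broadcast_to(j1, (h, w))
    v00 = luts[i0b, j0b, bins]
    v01 = luts[i0b, j1b, bins]
    v10 = luts[i1b, j0b, bins]
    v11 = luts[i1b, j1b, bins]
    top = v00 * (1 - fx) + v01 * fx
    bot = v10 * (1 - fx) + v11 * fx
    out = top * (1 - fy) + bot * fy
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def he(img8: np.ndarray) -> np.ndarray:
    """Global histogram equalization via the standard 255*CDF mapping."""
    img8 = _check_uint8(img8)
    hist = np.bincount(img8.ravel(), minlength=256).astype(float)
    cdf = np.cumsum(hist) / img8.size
    lut = np.floor(255.0 * cdf + 0.5)
    return lut[img8].astype(np.uint8)


def ahe(img8: np.ndarray, tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Adaptive histogram equalization = CLAHE with an unbounded clip."""
    return clahe(img8, ClaheConfig(tiles=tiles, clip_limit=1e12))


def gamma_correct(img8: np.ndarray, g: float) -> np.ndarray:
    """``255 * (in/255)**g``; the c=1 member of the power-law family."""
    return power_law(img8, 1.0, g)


def power_law(img8: np.ndarray, c: float, g: float) -> np.ndarray:
    img8 = _check_uint8(img8)
    if g <= 0 or c <= 0:
        raise ValueError("power-law parameters must be positive")
    out = 255.0 * c * (img8.astype(float) / 255.0) ** g
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def log_transform(img8: np.ndarray, c: float = 1.0) -> np.ndarray:
    img8 = _check_uint8(img8)
    if c <= 0:
        raise ValueError("log-transform scale must be positive")
    out = 255.0 * c * np.log1p(img8.astype(float)) / np.log(256.0)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


#: the six classical enhancers of the comparison harness, with the fixed
#: settings used when a single callable per method is needed
CLASSIC_ENHANCERS = {
    "Gamma": lambda im: gamma_correct(im, 0.9),
    "Power Law": lambda im: power_law(im, 1.0, 1.2),
    "Log": lambda im: log_transform(im, 1.0),
    "CLAHE": lambda im: clahe(im, ClaheConfig(clip_limit=1.0)),
    "HE": he,
    "AHE": lambda im: ahe(im),
}


@dataclass
class PipelineResult:
    """Final 8-bit image plus the intermediates metric code needs."""

    enhanced8: np.ndarray   # CLAHE output
    lt8: np.ndarray         # windowed, quantized image after the linear transform
    orig8: np.ndarray       # windowed, quantized image without the transform
    lt: HUImage             # linear-transformed HU image
    params: EnhancementParams


def enhance_pipeline(img: HUImage, params: EnhancementParams,
                     window_cfg: WindowConfig = DEFAULT_WINDOW,
                     clahe_cfg: ClaheConfig = ClaheConfig()) -> PipelineResult:
    """Linear transform -> window clamp -> 8-bit -> CLAHE(clip=gamma)."""
    lt = linear_transform(img, params.alpha, params.beta)
    lt8 = to_uint8(window(lt, window_cfg), window_cfg.lo, window_cfg.hi)
    orig8 = to_uint8(window(img, window_cfg), window_cfg.lo, window_cfg.hi)
    enhanced8 = clahe(lt8, clahe_cfg.with_clip(params.gamma_clip))
    return PipelineResult(enhanced8=enhanced8, lt8=lt8, orig8=orig8,
                          lt=lt, params=params)
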