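"""CT preprocessing: HU conversion, resampling, windowing, 8-bit scaling.

The pipeline mirrors standard non-contrast brain CT handling: raw DICOM
pixel data are mapped to Hounsfield Units through the scanner's rescale
slope/intercept, resampled to a square matrix, clamped to a brain window
(default center 35 HU, width 70 HU), and only then quantized to 8 bits.
Windowing and 8-bit scaling are deliberately separate operations so the
linear HU transform of :mod:`deepclahe.enhance` can run in HU space
before quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.transform import resize

__all__ = [
    "HUImage",
    "WindowConfig",
    "DEFAULT_WINDOW",
    "dicom_to_hu",
    "read_dicom",
    "window",
    "resample_to",
    "to_uint8",
]

#: clinically plausible CT attenuation bounds used for clamping phantoms
HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class HUImage:
    """A 2D attenuation grid in Hounsfield Units.

    Parameters
    ----------
    pixels : 2D float array of HU values (finite, at least 16x16).
    pixel_spacing : optional in-plane spacing in mm.
    provenance : free-form metadata (scanner id, rescale pair, transform
        history); carried along but never interpreted.
    """

    pixels: np.ndarray
    pixel_spacing: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("HUImage requires a 2D pixel grid")
        if min(self.pixels.shape) < 16:
            raise ValueError("HUImage must be at least 16x16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("HUImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, note: str | None = None) -> "HUImage":
        prov = dict(self.provenance)
        if note:
            prov.setdefault("history", [])
            prov["history"] = list(prov["history"]) + [note]
        return HUImage(pixels, pixel_spacing=self.pixel_spacing, provenance=prov)


@dataclass(frozen=True)
class WindowConfig:
    """Display window: values are clamped to ``center ± width/2``."""

    center: float = 35.0
    width: float = 70.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.center - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.center + self.width / 2.0


DEFAULT_WINDOW = WindowConfig(35.0, 70.0)
#: the acquisition-console window reported by the scanners (kept for reference)
ACQUISITION_WINDOW = WindowConfig(40.0, 80.0)


def dicom_to_hu(raw_pixels: np.ndarray, rescale_slope: float,
                rescale_intercept: float) -> HUImage:
    """Affine map ``HU = slope * raw + intercept``, recording the pair."""
    if rescale_slope is None or rescale_intercept is None:
        raise ValueError("rescale slope/intercept missing — cannot convert to HU")
    if rescale_slope == 0:
        raise ValueError("rescale slope must be nonzero")
    hu = float(rescale_slope) * np.asarray(raw_pixels, dtype=float) + float(rescale_intercept)
    return HUImage(hu, provenance={
        "rescale_slope": float(rescale_slope),
        "rescale_intercept": float(rescale_intercept),
    })


def read_dicom(path) -> HUImage:
    """Read a single-frame CT DICOM file into HU.

    Raises ``ValueError`` when the rescale tags are absent, mirroring the
    exclusion of scans with missing acquisition metadata.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        raise ValueError(f"{path}: RescaleSlope/RescaleIntercept missing")
    img = dicom_to_hu(ds.pixel_array.astype(float),
                      float(ds.RescaleSlope), float(ds.RescaleIntercept))
    spacing = None
    if "PixelSpacing" in ds:
        spacing = float(ds.PixelSpacing[0])
    img.pixel_spacing = spacing
    img.provenance["source"] = str(path)
    return img


def resample_to(img: HUImage, size: int) -> HUImage:
    """Bilinear resample to a ``size x size`` matrix (identity short-circuit)."""
    if size < 16:
        raise ValueError("target size must be at least 16")
    if img.shape == (size, size):
        return img
    out = resize(img.pixels, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    res = img.with_pixels(out, note=f"resample {img.shape}->{size}x{size}")
    return res


def window(img: HUImage, cfg: WindowConfig = DEFAULT_WINDOW) -> HUImage:
    """Clamp to the window band; in-band values pass through unchanged."""
    out = np.clip(img.pixels, cfg.lo, cfg.hi)
    return img.with_pixels(out, note=f"window c={cfg.center} w={cfg.width}")


def to_uint8(img: HUImage | np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Scale ``[lo, hi]`` to ``[0, 255]`` with round-half-up quantization.

    Round-half-up (not banker's rounding) is used so the 8-bit histograms
    feeding CLAHE are bit-exactly reproducible across platforms.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    x = img.pixels if isinstance(img, HUImage) else np.asarray(img, dtype=float)
    scaled = 255.0 * (np.clip(x, lo, hi) - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)
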