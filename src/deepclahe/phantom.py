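"""Stage-labeled synthetic brain-CT phantoms with ground-truth lesion masks.

Each phantom is a single axial slice: an elliptical skull ring enclosing
a gray-matter band and white-matter core, a central CSF ventricle, and —
for the four stroke stages — one hypodense elliptical lesion whose mean
attenuation deficit grows with temporal stage (hyperacute lesions sit
below the default noise floor; chronic lesions approach CSF density, the
volume-loss analog).  Gaussian scanner noise and an affine HU jitter
emulate inter-scanner variability.  Everything is seeded, so identical
spec + seed reproduces bit-identical samples.

Default tissue attenuations (GM 40 HU, WM 32 HU, CSF 8 HU, skull 700 HU)
and the per-stage lesion deltas (-3, -6, -12, -22 HU from hyperacute to
chronic) are documented package constants chosen so hyperacute detection
is genuinely hard and chronic detection easy; all are overridable.

Lesion boundary softness is realized as a Gaussian falloff *outside* the
lesion disk: every pixel inside the mask carries the full delta, so the
mean attenuation deficit over the mask equals ``lesion_delta_hu``
exactly in the noiseless limit, while the visible edge remains smooth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import rotate

from .preprocess import HU_MAX, HU_MIN, DEFAULT_WINDOW, HUImage, to_uint8, window

__all__ = [
    "STAGES",
    "LESION_STAGES",
    "PhantomSpec",
    "StagedSample",
    "default_stage_spec",
    "make_phantom",
    "make_dataset",
    "apply_scanner_variation",
    "save_sample",
    "write_dicom",
]

STAGES = ("hyperacute", "acute", "subacute", "chronic", "normal")
LESION_STAGES = ("hyperacute", "acute", "subacute", "chronic")

AIR_HU = -1000.0

#: per-stage defaults: (lesion_delta_hu, lesion_radius_frac, edge_softness_px)
_STAGE_LESION_DEFAULTS = {
    "hyperacute": (-3.0, 0.20, 3.0),
    "acute": (-6.0, 0.24, 2.5),
    "subacute": (-12.0, 0.30, 2.0),
    "chronic": (-22.0, 0.26, 1.0),
    "normal": (0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 256
    gm_hu: float = 40.0
    wm_hu: float = 32.0
    csf_hu: float = 8.0
    skull_hu: float = 700.0
    noise_sd: float = 2.0
    stage: str = "normal"
    lesion_delta_hu: float = 0.0
    lesion_radius_frac: float = 0.0
    edge_softness: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not (self.gm_hu > self.wm_hu > self.csf_hu >= 0):
            raise ValueError("need gm_hu > wm_hu > csf_hu >= 0")
        if not self.skull_hu > self.gm_hu:
            raise ValueError("skull_hu must exceed gm_hu")
        if self.lesion_delta_hu > 0:
            raise ValueError("lesion_delta_hu must be <= 0 (hypodense)")
        if self.stage == "normal" and self.lesion_delta_hu != 0:
            raise ValueError("normal stage requires lesion_delta_hu == 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.stage != "normal" and self.lesion_radius_frac >= 1.0:
            raise ValueError("lesion larger than the brain")


@dataclass
class StagedSample:
    image: HUImage
    stage: str
    lesion_mask: np.ndarray
    spec: PhantomSpec


def default_stage_spec(stage: str, seed: int = 0, image_size: int = 256,
                       noise_sd: float = 2.0) -> PhantomSpec:
    """Documented per-stage defaults; lesion severity increases with stage."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    delta, radius, softness = _STAGE_LESION_DEFAULTS[stage]
    return PhantomSpec(image_size=image_size, noise_sd=noise_sd, stage=stage,
                       lesion_delta_hu=delta, lesion_radius_frac=radius,
                       edge_softness=softness, seed=seed)


def _geometry(size: int):
    """Normalized elliptical radius grid and brain semi-axes (rows, cols)."""
    by, bx = 0.42 * size, 0.35 * size
    cy = cx = (size - 1) / 2.0
    r = np.arange(size)[:, None]
    c = np.arange(size)[None, :]
    rho = np.sqrt(((r - cy) / by) ** 2 + ((c - cx) / bx) ** 2)
    return rho, (cy, cx), (by, bx)


def make_phantom(spec: PhantomSpec) -> StagedSample:
    """Render one phantom slice with its ground-truth lesion mask."""
    size = spec.image_size
    if size < 16:
        raise ValueError("image_size must be at least 16 pixels")
    rho, (cy, cx), (by, bx) = _geometry(size)
    rng = np.random.default_rng(spec.seed)

    tissue = np.full((size, size), spec.wm_hu)
    tissue[rho >= 0.62] = spec.gm_hu          # cortical gray-matter band
    tissue[rho < 0.16] = spec.csf_hu          # central ventricle
    brain = rho < 1.0

    mask = np.zeros((size, size), dtype=bool)
    if spec.stage != "normal":
        lesion_r = spec.lesion_radius_frac * min(by, bx)
        if lesion_r < 1.0:
            raise ValueError("lesion radius below one pixel at this image size")
        side = rng.choice((-1.0, 1.0))
        lcy = cy + by * rng.uniform(-0.15, 0.15)
        lcx = cx + side * bx * rng.uniform(0.40, 0.52)
        rr = np.arange(size)[:, None]
        cc = np.arange(size)[None, :]
        dist = np.sqrt((rr - lcy) ** 2 + (cc - lcx) ** 2)
        mask = (dist <= lesion_r) & brain
        if not mask.any():
            raise ValueError("lesion fell outside the brain")
        # full delta inside the disk, smooth Gaussian falloff outside it
        if spec.edge_softness > 0:
            falloff = np.exp(-np.clip(dist - lesion_r, 0, None) ** 2
                             / (2.0 * spec.edge_softness ** 2))
        else:
            falloff = (dist <= lesion_r).astype(float)
        tissue = tissue + spec.lesion_delta_hu * falloff * brain

    img = np.full((size, size), AIR_HU)
    img[rho < 1.12] = spec.skull_hu           # skull ring
    img[brain] = tissue[brain]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, HU_MIN, HU_MAX)

    hu = HUImage(img, provenance={"kind": "phantom", "stage": spec.stage,
                                  "seed": int(spec.seed)})
    return StagedSample(image=hu, stage=spec.stage, lesion_mask=mask, spec=spec)


def _jittered_spec(stage: str, seed: int, rng: np.random.Generator,
                   image_size: int, noise_sd: float) -> PhantomSpec:
    """Per-sample anatomical/severity jitter around the stage defaults."""
    base = default_stage_spec(stage, seed=seed, image_size=image_size,
                              noise_sd=noise_sd)
    gm = base.gm_hu + rng.uniform(-1.0, 1.0)
    wm = base.wm_hu + rng.uniform(-1.0, 1.0)
    kwargs = dict(gm_hu=gm, wm_hu=wm,
                  noise_sd=base.noise_sd * rng.uniform(0.8, 1.2))
    if stage != "normal":
        kwargs["lesion_delta_hu"] = base.lesion_delta_hu * rng.uniform(0.85, 1.15)
        kwargs["lesion_radius_frac"] = base.lesion_radius_frac * rng.uniform(0.9, 1.1)
    return replace(base, **kwargs)


def _augment(sample: StagedSample, angle: float) -> list[StagedSample]:
    """Horizontal flip plus one rotation within +/-7 degrees (3x the set)."""
    img = sample.image.pixels
    fill = float(img.min())
    flipped = img[:, ::-1].copy()
    rotated = rotate(img, angle, order=1, mode="constant", cval=fill,
                     preserve_range=True)
    out = []
    for name, pix, msk in (
        ("hflip", flipped, sample.lesion_mask[:, ::-1].copy()),
        (f"rot{angle:.2f}", rotated,
         rotate(sample.lesion_mask.astype(float), angle, order=0,
                mode="constant", cval=0, preserve_range=True) > 0.5),
    ):
        hu = sample.image.with_pixels(pix, note=f"augment {name}")
        out.append(StagedSample(image=hu, stage=sample.stage,
                                lesion_mask=msk, spec=sample.spec))
    return out


def make_dataset(n_per_stage: int, stages=STAGES, base_seed: int = 0,
                 augment: bool = False, image_size: int = 256,
                 noise_sd: float = 2.0) -> list[StagedSample]:
    """Seeded dataset with per-sample jitter; augmentation triples it."""
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be at least 1")
    stages = tuple(stages)
    if not stages:
        raise ValueError("stage list must be nonempty")
    master = np.random.default_rng(base_seed)
    samples: list[StagedSample] = []
    for stage in stages:
        for _ in range(n_per_stage):
            seed = int(master.integers(0, 2 ** 31 - 1))
            spec = _jittered_spec(stage, seed, master, image_size, noise_sd)
            sample = make_phantom(spec)
            samples.append(sample)
            if augment:
                angle = float(master.uniform(-7.0, 7.0))
                samples.extend(_augment(sample, angle))
    return samples


def apply_scanner_variation(img: HUImage, slope_jitter=0.0, intercept_jitter=0.0,
                            seed: int = 0) -> HUImage:
    """Random affine HU perturbation emulating inter-scanner variability.

    Scalar jitters ``j`` draw uniformly from ``[-j, j]`` (slope factor
    ``1 + draw``); a ``(lo, hi)`` tuple pins the draw interval, so e.g.
    ``intercept_jitter=(2, 2)`` shifts every pixel by exactly +2 HU.
    """
    def _interval(j):
        if np.ndim(j) == 0:
            j = float(j)
            if not np.isfinite(j):
                raise ValueError("jitter must be finite")
            return (-abs(j), abs(j))
        lo, hi = float(j[0]), float(j[1])
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
            raise ValueError("jitter interval must be finite with hi >= lo")
        return (lo, hi)

    rng = np.random.default_rng(seed)
    s_lo, s_hi = _interval(slope_jitter)
    i_lo, i_hi = _interval(intercept_jitter)
    ds = rng.uniform(s_lo, s_hi)
    di = rng.uniform(i_lo, i_hi)
    out = img.with_pixels(img.pixels * (1.0 + ds) + di,
                          note=f"scanner_jitter slope={1 + ds:.6f} shift={di:.4f}")
    out.provenance["scanner_jitter"] = {"slope": 1.0 + ds, "intercept": di}
    return out


def save_sample(sample: StagedSample, out_dir, name: str) -> dict:
    """Write HU grid (.npy), mask (.npy), 8-bit preview (.png), spec (.json)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{name}.npy",
        "mask": out_dir / f"{name}_mask.npy",
        "preview": out_dir / f"{name}.png",
        "spec": out_dir / f"{name}.json",
    }
    np.save(paths["image"], sample.image.pixels)
    np.save(paths["mask"], sample.lesion_mask)
    prev = to_uint8(window(sample.image), DEFAULT_WINDOW.lo, DEFAULT_WINDOW.hi)
    Image.fromarray(prev).save(paths["preview"])
    paths["spec"].write_text(json.dumps(
        {"stage": sample.stage, "spec": sample.spec.__dict__}, indent=2,
        sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def write_dicom(sample: StagedSample, path) -> None:
    """Minimal secondary-capture DICOM round-trippable by ``read_dicom``.

    Stores pixels as uint16 with RescaleSlope 1 / RescaleIntercept -1024.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid(
        entropy_srcs=[str(sample.spec)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = sample.image.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1
    ds.RescaleIntercept = -1024
    raw = np.clip(np.round(sample.image.pixels) + 1024, 0, 65535).astype(np.uint16)
    ds.PixelData = raw.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
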