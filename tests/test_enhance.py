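"""Linear transform, CLAHE dialect, classical enhancers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deepclahe.enhance import (ClaheConfig, EnhancementParams, ahe, clahe,
                               enhance_pipeline, gamma_correct, he,
                               linear_transform, log_transform, power_law)
from deepclahe.metrics import eme
from deepclahe.phantom import default_stage_spec, make_phantom
from deepclahe.preprocess import DEFAULT_WINDOW, HUImage, to_uint8, window


def clahe_reference(img8, tiles, clip_limit, n_bins=256):
    """Independent per-pixel CLAHE: explicit loops, no shared code paths."""
    h, w = img8.shape
    tr, tc = tiles
    th, tw = -(-h // tr), -(-w // tc)
    padded = np.pad(img8, ((0, tr * th - h), (0, tc * tw - w)), mode="reflect")
    luts = np.zeros((tr, tc, n_bins))
    for i in range(tr):
        for j in range(tc):
            tile = padded[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.zeros(n_bins)
            for v in tile.ravel():
                hist[(int(v) * n_bins) >> 8] += 1
            ceil = clip_limit * th * tw / n_bins
            excess = sum(max(c - ceil, 0.0) for c in hist)
            hist = np.minimum(hist, ceil) + excess / n_bins
            luts[i, j] = 255.0 * np.cumsum(hist) / (th * tw)
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            b = (int(img8[r, c]) * n_bins) >> 8
            ty = min(max((r + 0.5) / th - 0.5, 0.0), tr - 1)
            tx = min(max((c + 0.5) / tw - 0.5, 0.0), tc - 1)
            i0, j0 = int(ty), int(tx)
            i1, j1 = min(i0 + 1, tr - 1), min(j0 + 1, tc - 1)
            fy, fx = ty - i0, tx - j0
            val = ((1 - fy) * ((1 - fx) * luts[i0, j0, b] + fx * luts[i0, j1, b])
                   + fy * ((1 - fx) * luts[i1, j0, b] + fx * luts[i1, j1, b]))
            out[r, c] = np.floor(val + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def test_linear_transform_identity_and_values():
    img = HUImage(np.full((16, 16), 40.0))
    assert np.array_equal(linear_transform(img, 1.0, 0.0).pixels, img.pixels)
    out = linear_transform(img, 1.25, -0.05)
    assert np.allclose(out.pixels, 49.95)


@pytest.mark.parametrize("alpha,beta", [(3.0, 0.0), (0.4, 0.0), (1.0, 6.0),
                                        (1.0, -5.5)])
def test_linear_transform_rejects_out_of_range(alpha, beta):
    img = HUImage(np.zeros((16, 16)))
    with pytest.raises(ValueError):
        linear_transform(img, alpha, beta)


def test_enhancement_params_range_invariants():
    EnhancementParams(0.5, -5.0, 0.1)
    EnhancementParams(2.0, 5.0, 2.0)
    for bad in [(0.49, 0, 1), (2.01, 0, 1), (1, -5.1, 1), (1, 0, 0.09),
                (1, 0, 2.1), (np.nan, 0, 1)]:
        with pytest.raises(ValueError):
            EnhancementParams(*bad)


def test_clahe_constant_image_and_range_contract(rng):
    const = np.full((64, 64), 77, np.uint8)
    out = clahe(const, ClaheConfig())
    assert len(np.unique(out)) == 1
    noisy = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    for clip in (0.1, 1.0, 2.0):
        out = clahe(noisy, ClaheConfig(clip_limit=clip))
        assert out.dtype == np.uint8 and out.shape == noisy.shape


def test_clahe_single_tile_infinite_clip_equals_he(rng):
    for _ in range(10):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        assert np.array_equal(
            clahe(img, ClaheConfig(tiles=(1, 1), clip_limit=1e12)), he(img))


@pytest.mark.parametrize("tiles,clip", [((2, 2), 0.5), ((4, 4), 1.0),
                                        ((3, 5), 2.0), ((8, 8), 0.1)])
def test_clahe_matches_independent_reference(tiles, clip, rng):
    img = rng.integers(0, 256, (48, 40)).astype(np.uint8)
    assert np.array_equal(clahe(img, ClaheConfig(tiles=tiles, clip_limit=clip)),
                          clahe_reference(img, tiles, clip))


def test_clahe_rejects_tiny_tiles():
    with pytest.raises(ValueError):
        clahe(np.zeros((16, 16), np.uint8), ClaheConfig(tiles=(16, 16)))


def test_he_two_level_cdf_convention():
    img = np.zeros((16, 16), np.uint8)
    img[:8] = 10
    img[8:] = 20
    out = he(img)
    lo, hi = np.unique(out)
    assert abs(int(lo) - 127.5) <= 0.5  # 255 * 0.5, either rounding side
    assert hi == 255


def test_he_flattens_histograms(rng):
    img = rng.normal(128, 20, (64, 64)).clip(0, 255).astype(np.uint8)
    assert len(np.unique(img)) >= 16

    def hist_var(im):
        h, _ = np.histogram(im, bins=16, range=(0, 256))
        return np.var(h / im.size)

    assert hist_var(he(img)) <= hist_var(img)


def test_gamma_identity_log_zero_and_parameter_checks():
    img = np.arange(256, dtype=np.uint8).reshape(16, 16)
    assert np.array_equal(gamma_correct(img, 1.0), img)
    assert np.array_equal(power_law(img, 1.0, 1.0), img)
    zero = np.zeros((16, 16), np.uint8)
    assert np.array_equal(log_transform(zero, 1.0), zero)
    with pytest.raises(ValueError):
        gamma_correct(img, -1.0)
    with pytest.raises(ValueError):
        power_law(img, 0.0, 1.0)
    with pytest.raises(ValueError):
        log_transform(img, 0.0)


@given(st.integers(0, 2 ** 32 - 1))
def test_enhancers_preserve_range_and_shape(seed):
    img = np.random.default_rng(seed).integers(0, 256, (32, 32)).astype(np.uint8)
    for out in (he(img), ahe(img, (4, 4)), gamma_correct(img, 0.7),
                power_law(img, 1.2, 1.5), log_transform(img, 0.9),
                clahe(img, ClaheConfig(tiles=(4, 4)))):
        assert out.shape == img.shape
        assert out.dtype == np.uint8


def test_pipeline_identity_lt_matches_direct_clahe():
    img = make_phantom(default_stage_spec("acute", seed=1, image_size=64)).image
    params = EnhancementParams(1.0, 0.0, 0.8)
    result = enhance_pipeline(img, params)
    direct = clahe(to_uint8(window(img), DEFAULT_WINDOW.lo, DEFAULT_WINDOW.hi),
                   ClaheConfig(clip_limit=0.8))
    assert np.array_equal(result.enhanced8, direct)
    assert np.array_equal(result.lt8, result.orig8)


def test_pipeline_deterministic_and_raises_eme_on_two_tone_image():
    """On a GM/WM-like two-tone grid, enhancement raises blockwise contrast."""
    tones = np.where(np.add.outer(np.arange(64), np.arange(64)) % 2 == 0,
                     40.0, 32.0)
    img = HUImage(tones)
    params = EnhancementParams(1.25, 0.0, 1.0)
    r1 = enhance_pipeline(img, params)
    r2 = enhance_pipeline(img, params)
    assert np.array_equal(r1.enhanced8, r2.enhanced8)
    assert eme(r1.enhanced8) >= eme(r1.orig8)
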