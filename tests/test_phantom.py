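"""Phantom generator: geometry, stage severity, determinism, augmentation."""

from dataclasses import replace

import numpy as np
import pytest

from deepclahe.phantom import (LESION_STAGES, STAGES, PhantomSpec,
                               apply_scanner_variation, default_stage_spec,
                               make_dataset, make_phantom)
from deepclahe.preprocess import HU_MAX, HU_MIN


def test_identical_spec_and_seed_give_bit_identical_samples():
    spec = default_stage_spec("acute", seed=7, image_size=64)
    a, b = make_phantom(spec), make_phantom(spec)
    assert np.array_equal(a.image.pixels, b.image.pixels)
    assert np.array_equal(a.lesion_mask, b.lesion_mask)


def test_normal_stage_has_empty_mask_and_lesion_stages_do_not():
    for stage in STAGES:
        sample = make_phantom(default_stage_spec(stage, seed=1, image_size=64))
        assert sample.stage == stage
        assert sample.lesion_mask.any() == (stage != "normal")


def test_mask_lies_entirely_inside_the_brain():
    sample = make_phantom(default_stage_spec("subacute", seed=3, image_size=64))
    # brain pixels are far from both the air value and the skull value
    brainish = (sample.image.pixels > -200) & (sample.image.pixels < 200)
    assert np.all(brainish[sample.lesion_mask])


def test_noiseless_lesion_mean_matches_requested_delta():
    """With no noise, mean HU over the mask drops by exactly |delta|."""
    spec = replace(default_stage_spec("chronic", seed=3, image_size=64),
                   noise_sd=0.0, lesion_delta_hu=-20.0)
    lesioned = make_phantom(spec)
    baseline = make_phantom(replace(spec, stage="normal", lesion_delta_hu=0.0,
                                    lesion_radius_frac=0.0, edge_softness=0.0))
    diff = (lesioned.image.pixels - baseline.image.pixels)[lesioned.lesion_mask]
    assert abs(diff.mean() + 20.0) < 0.5
    assert np.allclose(diff, -20.0)  # plateau profile: exact inside the mask


def test_stage_defaults_order_lesion_severity():
    deltas = [abs(default_stage_spec(s, 0, 64).lesion_delta_hu)
              for s in LESION_STAGES]
    assert deltas == sorted(deltas)
    assert all(d > 0 for d in deltas)
    specs = [default_stage_spec(s, 0, 64) for s in STAGES]
    assert len({(sp.stage, sp.lesion_delta_hu) for sp in specs}) == 5
    assert default_stage_spec("normal", 0, 64).lesion_delta_hu == 0.0


def test_stage_contrast_monotone_without_noise():
    """Lesion-vs-contralateral HU deficit grows from hyperacute to chronic."""
    deficits = []
    for stage in LESION_STAGES:
        spec = replace(default_stage_spec(stage, seed=9, image_size=64),
                       noise_sd=0.0)
        s = make_phantom(spec)
        mirror = s.lesion_mask[:, ::-1]
        deficit = (s.image.pixels[mirror].mean()
                   - s.image.pixels[s.lesion_mask].mean())
        deficits.append(deficit)
    assert all(b > a for a, b in zip(deficits, deficits[1:]))


def test_spec_invariants_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(gm_hu=30.0, wm_hu=35.0)          # GM must exceed WM
    with pytest.raises(ValueError):
        PhantomSpec(stage="acute", lesion_delta_hu=2.0)   # hyperdense lesion
    with pytest.raises(ValueError):
        PhantomSpec(stage="normal", lesion_delta_hu=-5.0)
    with pytest.raises(ValueError):
        PhantomSpec(image_size=0)
    with pytest.raises(ValueError):
        PhantomSpec(stage="acute", lesion_radius_frac=1.5,
                    lesion_delta_hu=-5.0)            # lesion exceeds brain
    with pytest.raises(ValueError):
        default_stage_spec("fulminant")


def test_hu_values_stay_within_ct_bounds():
    spec = replace(default_stage_spec("chronic", seed=2, image_size=64),
                   noise_sd=400.0)
    img = make_phantom(spec).image.pixels
    assert img.min() >= HU_MIN and img.max() <= HU_MAX


def test_dataset_counts_and_augmentation_factor():
    plain = make_dataset(4, base_seed=0, image_size=64)
    assert len(plain) == 4 * 5
    augmented = make_dataset(4, base_seed=0, image_size=64, augment=True)
    assert len(augmented) == 60  # 3x: original + flip + rotation
    with pytest.raises(ValueError):
        make_dataset(0)
    with pytest.raises(ValueError):
        make_dataset(2, stages=())


def test_dataset_reproducible_across_calls():
    a = make_dataset(3, base_seed=42, image_size=64, augment=True)
    b = make_dataset(3, base_seed=42, image_size=64, augment=True)
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert sa.stage == sb.stage
        assert np.array_equal(sa.image.pixels, sb.image.pixels)
        assert np.array_equal(sa.lesion_mask, sb.lesion_mask)


def test_scanner_variation_affine_behaviour():
    img = make_phantom(default_stage_spec("normal", seed=0, image_size=64)).image
    same = apply_scanner_variation(img, 0.0, 0.0, seed=1)
    assert np.array_equal(same.pixels, img.pixels)
    shifted = apply_scanner_variation(img, 0.0, (2.0, 2.0), seed=1)
    assert np.allclose(shifted.pixels - img.pixels, 2.0)
    a = apply_scanner_variation(img, 0.05, 3.0, seed=9)
    b = apply_scanner_variation(img, 0.05, 3.0, seed=9)
    assert np.array_equal(a.pixels, b.pixels)
    assert "scanner_jitter" in a.provenance
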