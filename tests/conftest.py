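"""Shared fixtures; the expensive trained-model fixtures are session-scoped
so the convergence, ordering, and attention analyses reuse one training run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deepclahe import make_dataset, to_uint8, window
from deepclahe.experiments import oracle_comparison, stage_clip_ordering
from deepclahe.interpret import train_conv_classifier
from deepclahe.preprocess import DEFAULT_WINDOW

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def oracle_result():
    """Full training run + oracle comparison on held-out phantoms."""
    return oracle_comparison(seed=0)


@pytest.fixture(scope="session")
def ordering_result():
    """Per-stage networks on the two-regime stage-noise design."""
    return stage_clip_ordering(seed=0)


@pytest.fixture(scope="session")
def chronic_classifier():
    """Small CNN trained to separate chronic phantoms from normals.

    Returns (classifier, samples, windowed-8-bit images, labels).
    """
    samples = make_dataset(12, stages=("chronic", "normal"), base_seed=5,
                           image_size=64)
    imgs8 = [to_uint8(window(s.image), DEFAULT_WINDOW.lo, DEFAULT_WINDOW.hi)
             for s in samples]
    labels = [1 if s.stage == "chronic" else 0 for s in samples]
    clf = train_conv_classifier(imgs8, labels, n_classes=2, epochs=50,
                                seed=3, input_size=64)
    return clf, samples, imgs8, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
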