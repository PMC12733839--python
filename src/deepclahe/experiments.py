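"""Reproducible study harnesses built from the package's own pieces.

Each function runs a complete seeded experiment at desk scale (64x64
phantoms, the compact network configuration) and returns plain
dictionaries of measured quantities.  The same harnesses back the test
suite and the acceptance script, so every reported number is recomputed
from scratch.

The stage-noise design used for the clip-ordering experiment places the
early stages in the low-noise regime, where the grid-search-optimal
CLAHE clip limit is high (more equalization pays off), and the late
stages in the high-noise regime, where the optimum collapses to the
minimum clip (equalizing amplifies noise and the fidelity term wins).
On these phantoms the composite loss's clip response is two-regime
rather than continuously graded — the enhancement-vs-fidelity balance
flips at a noise threshold — so the recoverable stage signal is the
direction of that flip, and the experiment tests exactly that: every
stage pair whose grid-search mean clips genuinely differ must be
ordered the same way by the trained networks.
"""

from __future__ import annotations

import numpy as np

from .enhance import STATIC_PARAMS, enhance_pipeline
from .metrics import LossWeights, combined_loss
from .optimize import (ParamNet, TrainConfig, desk_scale_config,
                       grid_search_params, predict_params, train_param_net)
from .phantom import LESION_STAGES, make_dataset
from .preprocess import DEFAULT_WINDOW, to_uint8, window

__all__ = [
    "STAGE_NOISE_DESIGN",
    "evaluate_loss",
    "oracle_comparison",
    "stage_clip_ordering",
]

#: per-stage additive noise SD (HU) for the clip-ordering design; early
#: stages sit safely below the regime flip, late stages safely above it
STAGE_NOISE_DESIGN = {
    "hyperacute": 0.3,
    "acute": 0.45,
    "subacute": 1.3,
    "chronic": 2.4,
}

IMAGE_SIZE = 64  # desk-scale phantom matrix used by all experiments


def evaluate_loss(img, params, weights: LossWeights = LossWeights()):
    """Composite loss of the true pipeline at the given parameters."""
    result = enhance_pipeline(img, params)
    orig8 = to_uint8(window(img), DEFAULT_WINDOW.lo, DEFAULT_WINDOW.hi)
    return combined_loss(orig8, result.enhanced8, params, weights).loss


def oracle_comparison(seed: int = 0, n_train_per_stage: int = 25,
                      n_held_per_stage: int = 5, epochs: int = 50,
                      tolerance: float = 0.05,
                      oracle_resolution: int = 9) -> dict:
    """Train one network on all lesion stages; compare to the oracle.

    Returns the fraction of held-out images whose predicted-parameter
    loss is within ``tolerance`` of the grid-search optimum, plus the
    mean losses of the prediction, the oracle, and the static baseline.
    """
    train = make_dataset(n_train_per_stage, stages=LESION_STAGES,
                         base_seed=seed + 11, image_size=IMAGE_SIZE)
    held = make_dataset(n_held_per_stage, stages=LESION_STAGES,
                        base_seed=seed + 99, image_size=IMAGE_SIZE)
    net = ParamNet(desk_scale_config(seed=seed))
    tcfg = TrainConfig(epochs=epochs, batch_size=16, learning_rate=0.01,
                       seed=seed, surrogate_resolution=7)
    net, history = train_param_net(train, net, tcfg)

    pred_losses, oracle_losses, static_losses, within = [], [], [], 0
    for s in held:
        params = predict_params(net, s.image)
        lp = evaluate_loss(s.image, params)
        _, lo = grid_search_params(s.image, oracle_resolution)
        ls = evaluate_loss(s.image, STATIC_PARAMS)
        pred_losses.append(lp)
        oracle_losses.append(lo)
        static_losses.append(ls)
        if lp <= lo + tolerance:
            within += 1
    return {
        "n_held": len(held),
        "fraction_within_tolerance": within / len(held),
        "mean_predicted_loss": float(np.mean(pred_losses)),
        "mean_oracle_loss": float(np.mean(oracle_losses)),
        "mean_static_loss": float(np.mean(static_losses)),
        "history": history,
        "net": net,
    }


def stage_clip_ordering(seed: int = 0, n_train_per_stage: int = 20,
                        n_held_per_stage: int = 8, epochs: int = 30,
                        oracle_resolution: int = 9) -> dict:
    """Per-stage networks vs grid search on the stage-noise design.

    For each lesion stage a network is trained on phantoms drawn at that
    stage's design noise; grid-search mean optimal clips on held-out
    images define the reference ordering.  ``pairs_checked`` counts the
    stage pairs whose grid-search means differ by at least half a grid
    step (the resolvable separation); ``pairs_agreeing`` counts how many
    of those the network means order identically.
    """
    gs_means: dict[str, float] = {}
    net_means: dict[str, float] = {}
    for si, (stage, noise) in enumerate(STAGE_NOISE_DESIGN.items()):
        train = make_dataset(n_train_per_stage, stages=(stage,),
                             base_seed=seed + 100 + si, image_size=IMAGE_SIZE,
                             noise_sd=noise)
        held = make_dataset(n_held_per_stage, stages=(stage,),
                            base_seed=seed + 200 + si, image_size=IMAGE_SIZE,
                            noise_sd=noise)
        gs_means[stage] = float(np.mean(
            [grid_search_params(s.image, oracle_resolution)[0].gamma_clip
             for s in held]))
        net = ParamNet(desk_scale_config(seed=seed + si))
        tcfg = TrainConfig(epochs=epochs, batch_size=16, learning_rate=0.01,
                           seed=seed + si, surrogate_resolution=9)
        net, _ = train_param_net(train, net, tcfg)
        net_means[stage] = float(np.mean(
            [predict_params(net, s.image).gamma_clip for s in held]))

    # half of one gamma grid step: separations below this are grid noise
    step = (2.0 - 0.1) / (oracle_resolution - 1)
    resolvable = step / 2.0
    stages = list(STAGE_NOISE_DESIGN)
    checked = agreeing = 0
    for a in range(len(stages)):
        for b in range(a + 1, len(stages)):
            diff = gs_means[stages[a]] - gs_means[stages[b]]
            if abs(diff) < resolvable:
                continue
            checked += 1
            net_diff = net_means[stages[a]] - net_means[stages[b]]
            if np.sign(net_diff) == np.sign(diff):
                agreeing += 1
    return {
        "gs_mean_clip": gs_means,
        "net_mean_clip": net_means,
        "pairs_checked": checked,
        "pairs_agreeing": agreeing,
        "resolvable_separation": resolvable,
    }
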