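"""Parameter constraint, grid-search oracle, training loop, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deepclahe.enhance import PARAM_RANGES, EnhancementParams
from deepclahe.metrics import LossWeights
from deepclahe.optimize import (ParamNet, ParamNetConfig, TrainConfig,
                                build_param_net, constrain, constrain_grad,
                                desk_scale_config, grid_search_params,
                                load_checkpoint, loss_surface, param_grid,
                                predict_params, save_checkpoint,
                                summarize_stage_params, train_param_net)
from deepclahe.phantom import default_stage_spec, make_dataset, make_phantom
from deepclahe.preprocess import HUImage


def test_constrain_midpoints_and_saturation():
    mid = constrain(np.zeros(3))
    assert mid.as_tuple() == pytest.approx((1.25, 0.0, 1.05))
    high = constrain(np.array([40.0, 40.0, 40.0]))
    assert high.as_tuple() == pytest.approx((2.0, 5.0, 2.0), abs=1e-9)
    low = constrain(np.array([-40.0, -40.0, -40.0]))
    assert low.as_tuple() == pytest.approx((0.5, -5.0, 0.1), abs=1e-9)
    with pytest.raises(ValueError):
        constrain(np.array([np.inf, 0.0, 0.0]))


@given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
def test_constrain_always_lands_inside_ranges(raw):
    params = constrain(np.array(raw))
    for name, value in zip(("alpha", "beta", "gamma_clip"), params.as_tuple()):
        lo, hi = PARAM_RANGES[name]
        assert lo <= value <= hi


def test_constrain_grad_matches_finite_differences():
    raw = np.array([0.3, -1.2, 2.0])
    g = constrain_grad(raw)
    for d in range(3):
        up, down = raw.copy(), raw.copy()
        up[d] += 1e-6
        down[d] -= 1e-6
        num = (np.array(constrain(up).as_tuple())[d]
               - np.array(constrain(down).as_tuple())[d]) / 2e-6
        assert g[d] == pytest.approx(num, rel=1e-6)


def test_param_net_config_validation():
    with pytest.raises(ValueError):
        ParamNetConfig(conv_channels=(8, 16))
    with pytest.raises(ValueError):
        ParamNetConfig(fc_widths=(64, 32, 16, 2))
    with pytest.raises(ValueError):
        ParamNetConfig(dropout_rate=1.0)


def test_param_net_seeded_init_and_deterministic_inference():
    cfg = desk_scale_config(seed=5)
    a, b = build_param_net(cfg), build_param_net(cfg)
    for (pa, _), (pb, _) in zip(a.net.param_pairs(), b.net.param_pairs()):
        assert np.array_equal(pa, pb)
    img = make_phantom(default_stage_spec("acute", seed=1, image_size=64)).image
    p1, p2 = predict_params(a, img), predict_params(a, img)
    assert p1 == p2
    assert a.param_count() > 0


def test_predict_resamples_mismatched_input_with_warning():
    net = ParamNet(desk_scale_config(seed=0))
    img = make_phantom(default_stage_spec("normal", seed=0, image_size=96)).image
    with pytest.warns(UserWarning):
        params = predict_params(net, img)
    assert isinstance(params, EnhancementParams)


def test_grid_is_uniform_over_ranges():
    axes = param_grid(5)
    assert axes[0][0] == 0.5 and axes[0][-1] == 2.0
    assert axes[1][0] == -5.0 and axes[1][-1] == 5.0
    assert axes[2][0] == 0.1 and axes[2][-1] == 2.0
    with pytest.raises(ValueError):
        param_grid(2)


def test_grid_search_is_true_argmin_and_refinement_helps():
    img = make_phantom(default_stage_spec("acute", seed=8, image_size=64)).image
    axes, cube = loss_surface(img, 3)
    params, loss = grid_search_params(img, 3)
    assert loss == cube.min()
    # independent re-evaluation of every grid point
    from deepclahe.experiments import evaluate_loss
    for i, a in enumerate(axes[0]):
        for j, b in enumerate(axes[1]):
            for k, g in enumerate(axes[2]):
                assert loss <= cube[i, j, k] + 1e-12
                assert cube[i, j, k] == pytest.approx(
                    evaluate_loss(img, EnhancementParams(a, b, g)), abs=1e-12)
    _, loss9 = grid_search_params(img, 9)
    assert loss9 <= loss
    # any grid containing the midpoint triple cannot beat the argmin
    mid = EnhancementParams(1.25, 0.0, 1.05)
    assert loss9 <= evaluate_loss(img, mid)


def test_grid_search_constant_image_prefers_midpoints():
    """With EME 0 and capped PSNR everywhere, only the regularizer varies."""
    img = HUImage(np.full((32, 32), 1000.0))  # windows to a constant
    params, _ = grid_search_params(img, 5)
    assert params.as_tuple() == pytest.approx((1.25, 0.0, 1.05))


def test_training_smoke_history_and_errors():
    data = make_dataset(2, stages=("acute", "normal"), base_seed=0,
                        image_size=64)
    net = ParamNet(desk_scale_config(seed=0))
    tcfg = TrainConfig(epochs=1, batch_size=4, seed=0,
                       surrogate_resolution=3)
    net, hist = train_param_net(data, net, tcfg)
    assert len(hist.train_loss) == len(hist.val_loss) == 1
    assert len(hist.mean_eme) == len(hist.mean_psnr) == 1
    with pytest.raises(ValueError):
        train_param_net([], net, tcfg)
    with pytest.raises(ValueError):
        train_param_net(data, net, TrainConfig(epochs=1, stage_filter="chronic",
                                               surrogate_resolution=3))
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)


def test_training_is_seeded_end_to_end():
    data = make_dataset(3, stages=("acute",), base_seed=1, image_size=64)
    results = []
    for _ in range(2):
        net = ParamNet(desk_scale_config(seed=2))
        _, hist = train_param_net(data, net, TrainConfig(
            epochs=2, batch_size=4, learning_rate=0.01, seed=2,
            surrogate_resolution=3))
        results.append((hist.train_loss, hist.val_loss))
    assert results[0] == results[1]


def test_long_training_run_converges(oracle_result):
    """Validation loss at the end of training beats the start."""
    hist = oracle_result["history"]
    assert len(hist.val_loss) == 50
    assert np.mean(hist.val_loss[-5:]) < np.mean(hist.val_loss[:5])
    assert all(np.isfinite(v) for v in hist.train_loss)


def test_checkpoint_round_trip(tmp_path):
    net = ParamNet(desk_scale_config(seed=9))
    img = make_phantom(default_stage_spec("acute", seed=3, image_size=64)).image
    before = predict_params(net, img)
    path = tmp_path / "net.npz"
    save_checkpoint(net, path, extra={"stage": "acute"})
    restored = load_checkpoint(path)
    assert predict_params(restored, img) == before


def test_stage_summary_ci_properties():
    stages = ("acute", "chronic")
    nets = {s: ParamNet(desk_scale_config(seed=i)) for i, s in enumerate(stages)}
    small = {s: make_dataset(5, stages=(s,), base_seed=3, image_size=64)
             for s in stages}
    table = summarize_stage_params(nets, small)
    assert isinstance(table, pd.DataFrame) and len(table) == 2
    for _, row in table.iterrows():
        for p, (lo, hi) in (("slope", PARAM_RANGES["alpha"]),
                            ("intercept", PARAM_RANGES["beta"]),
                            ("clip", PARAM_RANGES["gamma_clip"])):
            assert lo <= row[f"{p}_lb"] <= row[f"{p}_ub"] <= hi
    # CI width shrinks roughly like 1/sqrt(n)
    big = {s: make_dataset(45, stages=(s,), base_seed=3, image_size=64)
           for s in stages}
    table_big = summarize_stage_params(nets, big)
    w_small = (table.set_index("stage")["slope_ub"]
               - table.set_index("stage")["slope_lb"])
    w_big = (table_big.set_index("stage")["slope_ub"]
             - table_big.set_index("stage")["slope_lb"])
    assert (w_big <= w_small + 1e-12).all()
    with pytest.raises(ValueError):
        summarize_stage_params(nets, {s: small[s][:1] for s in stages})


def test_identical_predictions_give_zero_width_ci():
    net = ParamNet(desk_scale_config(seed=0))
    img = make_phantom(default_stage_spec("acute", seed=0, image_size=64))
    table = summarize_stage_params({"acute": net}, {"acute": [img, img]})
    row = table.iloc[0]
    assert row["slope_lb"] == pytest.approx(row["slope_ub"])
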