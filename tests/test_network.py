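"""Autodiff engine, uncertainty-weighted loss, architecture and training."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from measurenet import autodiff as ad
from measurenet.network import (MeasureNet, NetConfig, Prediction,
                                dead_unit_fraction, ensemble_whr,
                                multitask_loss, predict, train_model)

from conftest import eq1_scalar


# ---- autodiff engine -------------------------------------------------------

def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def test_gradients_match_finite_differences():
    """Composite graph covering conv, SE-style gating, attention and CE."""
    rng = np.random.default_rng(0)
    x = ad.Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
    w = ad.Tensor(rng.normal(size=(4, 3, 3, 3)) * 0.4, requires_grad=True)
    t = np.abs(rng.normal(size=(2, 4)))
    t /= t.sum(axis=1, keepdims=True)

    def graph(xd, wd):
        xt = ad.Tensor(xd, requires_grad=True)
        wt = ad.Tensor(wd, requires_grad=True)
        h = ad.conv2d(xt, wt, stride=2, pad=1)
        h = ad.swish(h)
        pooled = ad.global_avg_pool(h)                   # (2, 4)
        gate = ad.sigmoid(pooled)
        h = ad.mul(h, ad.reshape(gate, (2, 4, 1, 1)))
        z = ad.global_avg_pool(h)
        loss = ad.add(ad.cross_entropy(z, t),
                      ad.mul(ad.reduce_sum(ad.softplus(z)), 0.1))
        return loss, xt, wt

    loss, xt, wt = graph(x.data, w.data)
    loss.backward()
    for name, tensor in (("x", xt), ("w", wt)):
        ng = _num_grad(lambda: float(graph(xt.data, wt.data)[0].data),
                       tensor.data)
        rel = np.abs(ng - tensor.grad).max() / (np.abs(ng).max() + 1e-12)
        assert rel < 1e-6, name


# ---- uncertainty-weighted loss (Eq.-style total) ---------------------------

def test_multitask_loss_single_task_value():
    theta = {"a": ad.Tensor(np.array([np.log(np.e - 1.0)]),
                            requires_grad=True)}  # softplus -> w = 1
    total, breakdown = multitask_loss({"a": ad.Tensor(np.array(1.0))}, theta)
    assert float(total.data) == pytest.approx(1.0 + np.log(2.0), abs=1e-9)
    assert breakdown["a"] == pytest.approx(1.0)


def test_multitask_loss_matches_scalar_oracle_on_random_tuples():
    rng = np.random.default_rng(1)
    for _ in range(50):
        k = rng.integers(1, 6)
        ls = rng.uniform(0.0, 5.0, size=k)
        ws = rng.uniform(0.05, 5.0, size=k)
        theta = {f"t{i}": ad.Tensor(np.array([np.log(np.expm1(ws[i]))]),
                                    requires_grad=True)
                 for i in range(k)}
        losses = {f"t{i}": ad.Tensor(np.array(ls[i])) for i in range(k)}
        total, _ = multitask_loss(losses, theta)
        assert float(total.data) == pytest.approx(eq1_scalar(ls, ws),
                                                  rel=1e-9, abs=1e-9)


def test_weight_minimizer_drives_contribution_to_zero():
    def contribution(loss_value):
        res = minimize_scalar(lambda w: loss_value / w + np.log1p(w),
                              bounds=(1e-12, 100.0), method="bounded")
        return res.fun

    vals = [contribution(x) for x in (1.0, 1e-2, 1e-4, 1e-8)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-3


def test_multitask_loss_additive_for_equal_tasks():
    theta = {n: ad.Tensor(np.array([0.3]), requires_grad=True)
             for n in ("a", "b")}
    one, _ = multitask_loss({"a": ad.Tensor(np.array(2.0))},
                            {"a": theta["a"]})
    two, _ = multitask_loss({"a": ad.Tensor(np.array(2.0)),
                             "b": ad.Tensor(np.array(2.0))}, theta)
    assert float(two.data) == pytest.approx(2 * float(one.data), rel=1e-12)


def test_multitask_loss_rejects_nonfinite():
    theta = {"a": ad.Tensor(np.array([0.0]), requires_grad=True)}
    with pytest.raises(FloatingPointError, match="a"):
        multitask_loss({"a": ad.Tensor(np.array(np.nan))}, theta)


def test_loss_gradient_flows_to_weights():
    theta = {"a": ad.Tensor(np.array([0.5]), requires_grad=True)}
    li = ad.Tensor(np.array(2.0), requires_grad=True)
    total, _ = multitask_loss({"a": li}, theta)
    total.backward()
    assert theta["a"].grad is not None and abs(theta["a"].grad[0]) > 0
    assert li.grad is not None and li.grad > 0


# ---- WHR ensemble ----------------------------------------------------------

def _mk_pred(whr_reg, probs, waist, hip):
    return Prediction(dense=np.zeros(112), named={"waist": waist, "hip": hip},
                      whr_regression=whr_reg,
                      whr_class_probabilities=np.asarray(probs),
                      shape_estimate=np.zeros(9))


def test_ensemble_whr_averages_members():
    cfg = NetConfig()
    centers = cfg.bin_centers()
    probs = np.zeros(60)
    probs[np.argmin(np.abs(centers - 0.85))] = 1.0
    c = centers[np.argmin(np.abs(centers - 0.85))]
    p = _mk_pred(c, probs, waist=c * 1000, hip=1000.0)
    assert ensemble_whr(p, centers) == pytest.approx(c, abs=1e-12)
    p2 = _mk_pred(0.80, probs * 0 + 1.0 / 60, waist=1000.0, hip=1000.0)
    expected = np.mean([0.80, centers.mean(), 1.0])
    assert ensemble_whr(p2, centers) == pytest.approx(expected, abs=1e-12)


def test_ensemble_whr_drops_ratio_member_on_bad_hip():
    cfg = NetConfig()
    centers = cfg.bin_centers()
    probs = np.full(60, 1.0 / 60)
    p = _mk_pred(0.9, probs, waist=900.0, hip=-5.0)
    with pytest.warns(UserWarning, match="hip"):
        v = ensemble_whr(p, centers)
    assert v == pytest.approx(np.mean([0.9, centers.mean()]), abs=1e-12)


def test_class_head_expectation_stays_in_bin_range():
    cfg = NetConfig()
    centers = cfg.bin_centers()
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = rng.dirichlet(np.ones(60))
        e = float(p @ centers)
        assert centers[0] <= e <= centers[-1]


# ---- architecture and training --------------------------------------------

@pytest.fixture(scope="module")
def tiny_model_and_data(small_cohort):
    cfg = NetConfig(views=3, epochs=2, batch_size=8, seed=3)
    model, history = train_model(small_cohort[:24], cfg)
    return model, history, small_cohort


def test_forward_on_blank_images_is_finite_and_normalized():
    cfg = NetConfig(views=3)
    model = MeasureNet(cfg)
    views = {v: np.zeros((64, 64), dtype=np.uint8)
             for v in ("front", "side", "back")}
    out = model.forward(views, np.zeros((1, 3), dtype=np.float32))
    assert out["dense"].shape == (1, 112)
    for k, t in out.items():
        assert np.all(np.isfinite(t.data)), k
    z = out["whr_cls"].data[0]
    p = np.exp(z - z.max())
    p /= p.sum()
    assert p.sum() == pytest.approx(1.0, abs=1e-6) and np.all(p >= 0)


def test_view_count_mismatch_raises():
    model = MeasureNet(NetConfig(views=3, epochs=1))
    with pytest.raises(ValueError, match="front|side|back"):
        model.forward({"front": np.zeros((64, 64), dtype=np.uint8)},
                      np.zeros((1, 3)))


def test_resolution_mismatch_raises():
    model = MeasureNet(NetConfig(views=1))
    with pytest.raises(ValueError, match="resolution"):
        model.forward({"front": np.zeros((32, 32), dtype=np.uint8)},
                      np.zeros((1, 3)))


def test_swish_has_no_dead_units_relu_has_many(small_cohort):
    ex = small_cohort[0]
    swish_model = MeasureNet(NetConfig(views=1, seed=0))
    relu_model = MeasureNet(NetConfig(views=1, seed=0, activation="relu"))
    assert dead_unit_fraction(swish_model, ex) == 0.0
    assert dead_unit_fraction(relu_model, ex) > 0.2


def test_training_reduces_loss_and_is_seeded(tiny_model_and_data):
    model, history, cohort = tiny_model_and_data
    assert history["total"].iloc[-1] < history["total"].iloc[0]
    assert set(history.columns) >= {"epoch", "total", "dense", "named",
                                    "whr_reg", "whr_cls", "w_dense"}
    # re-training with the same seed reproduces the loss trajectory
    cfg = NetConfig(views=3, epochs=2, batch_size=8, seed=3)
    _, h2 = train_model(cohort[:24], cfg)
    assert np.allclose(history["total"].to_numpy(), h2["total"].to_numpy(),
                       rtol=1e-6)


def test_prediction_units_and_view_keying(tiny_model_and_data):
    model, _, cohort = tiny_model_and_data
    ex = cohort[25]
    ms, pred = predict(model, ex)
    assert 400 < ms.named["hip"] < 1800
    assert 0.3 < ms.whr < 1.5
    assert pred.whr_final == ms.whr
    # views are keyed by name: supplying the dict in another order is identical
    reordered = dict(reversed(list(ex.images.items())))
    ex2_images = ex.images
    ex.images = reordered
    ms2, _ = predict(model, ex)
    ex.images = ex2_images
    assert ms2.named == ms.named


def test_shape_decode_mode_produces_physical_measurements(tiny_model_and_data):
    import copy

    model, _, cohort = tiny_model_and_data
    decoded = copy.copy(model)
    decoded.config = NetConfig(**{**model.config.__dict__, "mode":
                                  "shape-decode"})
    ms, _ = predict(decoded, cohort[26])
    assert all(v > 0 for v in ms.named.values())
    assert ms.whr > 0


def test_checkpoint_roundtrip(tiny_model_and_data, tmp_path):
    from measurenet.checkpoint import load_checkpoint, save_checkpoint

    model, history, cohort = tiny_model_and_data
    save_checkpoint(model, history, tmp_path / "ckpt")
    model2, h2 = load_checkpoint(tmp_path / "ckpt")
    ms1, _ = predict(model, cohort[27])
    ms2, _ = predict(model2, cohort[27])
    assert ms1.named == ms2.named and ms1.whr == ms2.whr
    assert len(h2) == len(history)
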