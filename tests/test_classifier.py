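"""Boosted voxel classifier: determinism, posteriors, importance."""

import numpy as np
import pytest

from vesselseg import BinaryMask, ContextSpec, FeatureLayout, threshold_map, train
from vesselseg.classifier import ProbabilityMap, load_model, predict_volume, save_model
from vesselseg.classifier import filter_importance
from vesselseg.filter_bank import FeatureStack


def _layout(d=2, h=0, mode="3d"):
    return FeatureLayout(
        spec=ContextSpec(h=h, mode=mode),
        channel_names=("origin",) + tuple(f"ch{i}" for i in range(1, d)),
    )


def _blobs(rng, n=200, d=2, sep=6.0):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n, d)),
        rng.normal(sep, 1.0, size=(n, d)),
    ]).astype(np.float32)
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y


def test_separable_blobs_trained_to_perfection(rng):
    X, y = _blobs(rng)
    model = train((X, y), _layout(), seed=3)
    pred = model.predict(X)
    assert (pred == y).mean() == 1.0


def test_duplicate_samples_do_not_change_predictions(rng):
    X, y = _blobs(rng, n=120)
    probe = rng.normal(2.0, 3.0, size=(50, 2)).astype(np.float32)
    m1 = train((X, y), _layout(), seed=3)
    m2 = train((np.vstack([X, X]), np.concatenate([y, y])), _layout(), seed=3)
    p1 = m1.predict_proba(probe)
    p2 = m2.predict_proba(probe)
    assert p1 == pytest.approx(p2, abs=0.12)
    assert np.array_equal(p1 >= 0.5, p2 >= 0.5)


def test_same_seed_reproduces_posteriors(rng):
    X, y = _blobs(rng)
    probe = rng.normal(3.0, 2.0, size=(20, 2)).astype(np.float32)
    p = [train((X, y), _layout(), seed=11).predict_proba(probe)
         for _ in range(2)]
    assert np.array_equal(p[0], p[1])


def test_single_class_input_rejected(rng):
    X = rng.normal(size=(50, 2)).astype(np.float32)
    with pytest.raises(ValueError):
        train((X, np.ones(50, dtype=int)), _layout())


def test_feature_width_checked(rng):
    X, y = _blobs(rng, d=3)
    with pytest.raises(ValueError):
        train((X, y), _layout(d=2))


def _toy_stack_and_model(rng, d=3):
    # channel 1 carries the label signal; channel 2 is pure noise
    shape = (6, 12, 12)
    label = (rng.random(shape) < 0.3).astype(float)
    data = np.stack([
        rng.normal(size=shape),
        label * 10.0 + rng.normal(0, 0.1, size=shape),
        rng.normal(size=shape),
    ], axis=-1).astype(np.float32)
    stack = FeatureStack(data=data, channel_names=("origin", "signal", "noise"))
    X = data.reshape(-1, 3)
    y = label.ravel().astype(int)
    layout = FeatureLayout(spec=ContextSpec(h=0, mode="3d"),
                           channel_names=("origin", "signal", "noise"))
    model = train((X, y), layout, seed=0)
    return stack, model, label


def test_probability_map_contract_and_empty_roi(rng):
    stack, model, label = _toy_stack_and_model(rng)
    empty = BinaryMask(np.zeros(stack.shape))
    pmap = predict_volume(model, stack, roi=empty)
    assert np.all(pmap.data == 0)
    full = predict_volume(model, stack)
    assert full.data.min() >= 0 and full.data.max() <= 1
    on = full.data[label.astype(bool)].mean()
    off = full.data[~label.astype(bool)].mean()
    assert on > 0.9 > 0.1 > off


def test_batching_is_invisible(rng):
    stack, model, _ = _toy_stack_and_model(rng)
    p1 = predict_volume(model, stack, batch=1 << 14)
    p2 = predict_volume(model, stack, batch=64)
    assert np.array_equal(p1.data, p2.data)


def test_layout_mismatch_rejected(rng):
    stack, model, _ = _toy_stack_and_model(rng)
    other = FeatureStack(data=stack.data, channel_names=("origin", "a", "b"))
    with pytest.raises(ValueError):
        predict_volume(model, other)


def test_threshold_map_cases(rng):
    pm = ProbabilityMap(np.array([[[0.4, 0.6]]]))
    assert threshold_map(pm, 0.5).data.tolist() == [[[0, 1]]]
    pm2 = ProbabilityMap(rng.uniform(0, 0.9, size=(4, 5, 5)))
    assert threshold_map(pm2, 0.999).data.sum() == 0
    t = 0.37
    brute = sum(
        1 for k in range(4) for i in range(5) for j in range(5)
        if pm2.data[k, i, j] >= t
    )
    assert int(threshold_map(pm2, t).data.sum()) == brute
    with pytest.raises(ValueError):
        threshold_map(pm2, 1.5)


def test_importance_finds_signal_channel(rng):
    stack, model, _ = _toy_stack_and_model(rng)
    imp = filter_importance(model)
    assert imp.loc["signal", "total"] > 10 * max(imp.loc["noise", "total"], 1e-12)
    assert bool(imp.loc["signal", "selected"])
    gains = model.booster.get_score(importance_type="total_gain")
    assert imp["total"].sum() == pytest.approx(sum(gains.values()), rel=1e-6)


def test_constant_channel_zero_importance(rng):
    shape = (4, 10, 10)
    label = (rng.random(shape) < 0.4).astype(float)
    data = np.stack([
        label * 5.0 + rng.normal(0, 0.1, size=shape),
        np.full(shape, 3.0),  # constant channel can never split
    ], axis=-1).astype(np.float32)
    layout = FeatureLayout(spec=ContextSpec(h=0, mode="3d"),
                           channel_names=("origin", "flat"))
    model = train((data.reshape(-1, 2), label.ravel().astype(int)), layout, seed=0)
    imp = filter_importance(model)
    assert imp.loc["flat", "total"] == 0.0
    assert not bool(imp.loc["flat", "selected"])


def test_model_roundtrip_preserves_predictions(tmp_path, rng):
    stack, model, _ = _toy_stack_and_model(rng)
    save_model(model, str(tmp_path / "model"))
    loaded = load_model(str(tmp_path / "model"))
    assert loaded.layout == model.layout
    p1 = predict_volume(model, stack)
    p2 = predict_volume(loaded, stack)
    assert np.array_equal(p1.data, p2.data)
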