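"""Network construction, gradients, training protocol, and presets."""

import numpy as np
import pytest

from capsleep import classifiers, nn
from capsleep.classifiers import (CnnSpec, EarlyStopper, FfnnSpec, LstmSpec,
                                  TrainConfig, build_model, class_weights,
                                  predict_labels, preset)
from capsleep.preprocess import WindowSpec


def _disable_dropout(model):
    for layer in model.layers:
        if isinstance(layer, nn.Dropout):
            layer.p = 0.0


def numeric_gradient_check(model, x, y, rng, n_checks_per_param=2):
    """Central-difference gradient vs backprop, worst relative error."""
    sw = np.ones(len(y))
    model.loss_and_grad(x, y, sw)
    grads = [g.copy() for g in model.grads()]
    worst = 0.0
    for p, g in zip(model.params(), grads):
        for _ in range(n_checks_per_param):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            old = p[idx]
            p[idx] = old + eps
            lp = model.loss_and_grad(x, y, sw)
            p[idx] = old - eps
            lm = model.loss_and_grad(x, y, sw)
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            denom = max(1e-8, abs(num) + abs(g[idx]))
            worst = max(worst, abs(num - g[idx]) / denom)
    return worst


def test_ffnn_forward_matches_manual_arithmetic():
    """Hand-rolled forward pass on a 2-unit toy network: tanh hidden layer,
    soft-max output, explicit matrix arithmetic."""
    model = build_model(FfnnSpec(n_inputs=3, hidden_units=2), seed=0)
    w1, b1 = model.layers[0].w, model.layers[0].b
    w2, b2 = model.layers[1].w, model.layers[1].b
    x = np.array([[0.5, -1.0, 2.0]])
    hidden = np.tanh(x @ w1 + b1)
    logits = hidden @ w2 + b2
    expected = np.exp(logits[0, 1]) / np.exp(logits[0]).sum()
    assert model.predict_proba(x)[0] == pytest.approx(expected, abs=1e-12)


def test_softmax_outputs_sum_to_one(rng):
    for spec in (FfnnSpec(5, 8),
                 CnnSpec(goflayers=(4,), dense_units=6, window=WindowSpec(0)),
                 LstmSpec(n_inputs=4, hidden_units=6, time_steps=3)):
        model = build_model(spec, seed=1)
        if isinstance(spec, FfnnSpec):
            x = rng.normal(size=(7, 5))
        elif isinstance(spec, CnnSpec):
            x = rng.normal(size=(7, 100))
        else:
            x = rng.normal(size=(7, 3, 4))
        logits = model.forward(x, training=False)
        probs = nn.softmax(logits)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_cnn_gradients(rng):
    model = build_model(CnnSpec(goflayers=(4, 8), dense_units=5,
                                window=WindowSpec(0)), seed=0)
    _disable_dropout(model)
    x = rng.normal(size=(6, 100))
    y = rng.integers(0, 2, 6)
    assert numeric_gradient_check(model, x, y, rng) < 1e-4


def test_lstm_gradients(rng):
    model = build_model(LstmSpec(n_inputs=5, hidden_units=6, time_steps=4,
                                 depth=2, bidirectional=True,
                                 dense_option="half"), seed=0)
    _disable_dropout(model)
    x = rng.normal(size=(6, 4, 5))
    y = rng.integers(0, 2, 6)
    assert numeric_gradient_check(model, x, y, rng) < 1e-4


def test_class_weights():
    labels = np.concatenate([np.zeros(90), np.ones(10)])
    w = class_weights(labels)
    assert w[0] == pytest.approx(100 / 180)
    assert w[1] == pytest.approx(5.0)
    assert 90 * w[0] == pytest.approx(10 * w[1])  # equalized total cost
    assert np.allclose(class_weights(np.array([0, 1, 0, 1])), [1.0, 1.0])
    with pytest.raises(ValueError):
        class_weights(np.zeros(10))


def test_train_separable_features_reaches_high_auc(rng):
    """A thresholdable informative feature alone already achieves AUC 1, so
    the FFNN must reach >= 0.95 validation AUC within 50 epochs."""
    n = 600
    y = rng.integers(0, 2, n)
    x = np.column_stack([y + rng.normal(0, 0.2, n), rng.normal(size=n)])
    model = build_model(FfnnSpec(2, 16), seed=0)
    history = classifiers.train(
        model, (x[:400], y[:400]), (x[400:], y[400:]),
        TrainConfig(batch_size=64, seed=0))
    assert max(history["val_auc"]) >= 0.95


def test_early_stopper_flat_trace_stops_by_six():
    stopper = EarlyStopper(delta=0.01, patience=5)
    decisions = [stopper.update(0.5) for _ in range(6)]
    assert decisions == [False] * 5 + [True]


def test_early_stopper_resets_on_improvement():
    stopper = EarlyStopper(delta=0.01, patience=5)
    for auc in (0.5, 0.52, 0.521, 0.54):
        assert not stopper.update(auc)
    assert stopper.stale == 0


def test_training_deterministic(rng):
    n = 300
    y = rng.integers(0, 2, n)
    x = np.column_stack([y + rng.normal(0, 0.5, n), rng.normal(size=n)])

    def run():
        model = build_model(FfnnSpec(2, 8), seed=3)
        h = classifiers.train(model, (x[:200], y[:200]), (x[200:], y[200:]),
                              TrainConfig(batch_size=64, max_epochs=8, seed=3))
        return h["val_auc"]

    assert run() == run()


def test_cost_sensitive_training_raises_sensitivity():
    """On a 9:1 imbalanced overlapping problem, inverse-frequency weighting
    lifts sensitivity above the unweighted run (paired seeds)."""
    rng = np.random.default_rng(7)
    n = 2000
    y = (rng.random(n) < 0.1).astype(int)
    x = np.column_stack([y * 1.5 + rng.normal(0, 1.0, n),
                         rng.normal(size=n)])
    split = 1400
    sens = {}
    for cost_sensitive in (True, False):
        model = build_model(FfnnSpec(2, 16), seed=5)
        classifiers.train(model, (x[:split], y[:split]), (x[split:], y[split:]),
                          TrainConfig(batch_size=128, seed=5),
                          cost_sensitive=cost_sensitive)
        pred = predict_labels(model.predict_proba(x[split:]))
        truth = y[split:].astype(bool)
        sens[cost_sensitive] = (pred & truth).sum() / truth.sum()
    assert sens[True] >= 0.6
    assert sens[True] > sens[False]


def test_predict_proba_deterministic_and_bounded(rng):
    model = build_model(LstmSpec(n_inputs=4, hidden_units=8, time_steps=3),
                        seed=2)
    x = rng.normal(size=(20, 3, 4))
    p1 = model.predict_proba(x)
    p2 = model.predict_proba(x)
    assert np.array_equal(p1, p2)
    assert np.all((p1 >= 0) & (p1 <= 1))


def test_predict_labels_threshold_and_monotonicity(rng):
    assert predict_labels([0.7])[0]
    assert predict_labels([0.5])[0]  # tie goes positive
    assert not predict_labels([0.49])[0]
    probs = rng.random(500)
    fractions = [(probs >= thr).mean() for thr in np.linspace(0, 1, 21)]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_reference_presets_build():
    cases = {
        "ffnn": (14,),
        "cnn-afc": (1900,),
        "cnn-nrem": (1900,),
        "lstm-afc": (25, 100),
        "lstm-features": (25, 12),
        "lstm-nrem": (25, 12),
    }
    rng = np.random.default_rng(0)
    for name, shape in cases.items():
        spec = preset(name)
        model = build_model(spec, seed=0)
        x = rng.normal(size=(2,) + shape)
        probs = nn.softmax(model.forward(x, training=False))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert preset("cnn-afc").goflayers == (64, 128)
    assert preset("cnn-afc").window.window_w == 19
    assert preset("lstm-afc").dense_units == 50
    assert preset("lstm-nrem").dense_units == 150
    assert preset("ffnn").hidden_units == 400


def test_checkpoint_round_trip(tmp_path, rng):
    spec = FfnnSpec(4, 6)
    model = build_model(spec, seed=9)
    x = rng.normal(size=(10, 4))
    path = tmp_path / "model.npz"
    classifiers.save_checkpoint(path, model, spec, TrainConfig())
    loaded, loaded_spec = classifiers.load_checkpoint(path, seed=1)
    assert loaded_spec == spec
    assert np.allclose(loaded.predict_proba(x), model.predict_proba(x))
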