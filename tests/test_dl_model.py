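"""Sequence model: resampling, augmentation, layer gradients, structure.

Full smoke training of the real-size network lives in the acceptance
suite; here the layers are validated at small sizes against
finite-difference gradients, and the public surface is exercised.
"""

import numpy as np
import pytest

from bovigait.dl_model import (
    AugmentParams,
    BiLSTM,
    Conv1DRelu,
    DenseSoftmax,
    DLModel,
    NetConfig,
    SequenceSample,
    _build_network,
    _Network,
    _softmax,
    augment,
    build_sequence,
    load_dl_model,
    predict_proba,
    save_dl_model,
)
from bovigait.gait_events import StepEvent
from bovigait.indicators import CHANNELS, IndicatorConfig, IndicatorSeries


def _series(n=60, values=None):
    vals = {name: np.linspace(0.0, 1.0, n) for name in CHANNELS}
    if values:
        vals.update(values)
    valid = {name: np.isfinite(vals[name]) for name in CHANNELS}
    return IndicatorSeries(
        frame_index=np.arange(n), values=vals, valid=valid,
        steps={"FR": [StepEvent("FR", 10, (10, 20))]}, config=IndicatorConfig(),
    )


class TestBuildSequence:
    def test_identity_resample(self):
        s = _series(n=30)
        sample = build_sequence(s, T=30)
        np.testing.assert_allclose(sample.matrix[:, 0], np.linspace(0, 1, 30), atol=1e-9)

    def test_constant_channel(self):
        s = _series(values={"head_norm": np.full(60, 0.8)})
        sample = build_sequence(s, T=25)
        np.testing.assert_allclose(sample.matrix[:, CHANNELS.index("head_norm")], 0.8)

    def test_linear_ramp_downsampled(self):
        sample = build_sequence(_series(n=60), T=30)
        np.testing.assert_allclose(sample.matrix[:, 0], np.linspace(0, 1, 30), atol=1e-9)

    def test_invalid_frames_interpolated(self):
        vals = np.linspace(0.0, 1.0, 60)
        vals[20:25] = np.nan
        s = _series(values={"spine_angle_ratio": vals})
        sample = build_sequence(s, T=60)
        np.testing.assert_allclose(sample.matrix[:, 0], np.linspace(0, 1, 60), atol=1e-9)
        assert np.isfinite(sample.matrix).all()

    def test_empty_channel_zero_filled(self):
        s = _series(values={"leg_dist_FL_BL": np.full(60, np.nan)})
        sample = build_sequence(s, T=40)
        np.testing.assert_array_equal(sample.matrix[:, CHANNELS.index("leg_dist_FL_BL")], 0.0)


class TestAugment:
    def _sample(self, T=300):
        rng = np.random.default_rng(0)
        return SequenceSample(matrix=rng.normal(size=(T, 5)), label=3)

    def test_identity_when_disabled(self):
        s = self._sample()
        out = augment(s, AugmentParams(noise_sigma=0.0, smooth_window=0, dropout_frac=0.0), 1)
        np.testing.assert_array_equal(out.matrix, s.matrix)
        assert out.label == s.label

    def test_deterministic_given_seed(self):
        s = self._sample()
        p = AugmentParams(noise_sigma=0.05, smooth_window=3, dropout_frac=0.2)
        np.testing.assert_array_equal(augment(s, p, 9).matrix, augment(s, p, 9).matrix)
        assert not np.array_equal(augment(s, p, 9).matrix, augment(s, p, 10).matrix)

    def test_jitter_std_matches_sigma(self):
        s = self._sample(T=400)  # 2000 entries
        out = augment(s, AugmentParams(noise_sigma=0.01, dropout_frac=0.0), 5)
        dev = (out.matrix - s.matrix).ravel()
        assert 0.008 <= dev.std() <= 0.012

    def test_dropout_fraction_bounds(self):
        with pytest.raises(ValueError):
            AugmentParams(dropout_frac=1.0)


def test_layer_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    layers = [
        Conv1DRelu(3, 4, 3, rng, np.float64),
        BiLSTM(4, 5, True, rng, np.float64),
        BiLSTM(10, 6, False, rng, np.float64),
        DenseSoftmax(12, 7, rng, np.float64),
    ]
    net = _Network(layers)
    X = rng.normal(size=(3, 8, 3))
    Y = np.zeros((3, 7))
    Y[np.arange(3), [0, 3, 6]] = 1.0
    _, grads = net.loss_and_grads(X, Y)
    flat = net.flat_grads(grads)
    params = net.parameters()
    eps = 1e-6
    check_rng = np.random.default_rng(1)
    for p, g in zip(params, flat):
        for _ in range(4):
            idx = tuple(check_rng.integers(0, s) for s in p.shape)
            old = p[idx]
            p[idx] = old + eps
            lp, _ = net.loss_and_grads(X, Y)
            p[idx] = old - eps
            lm, _ = net.loss_and_grads(X, Y)
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-8)


def test_architecture_structure():
    """Two recurrent layers (256 sequence-returning, then 512 summarizing),
    all conv kernels size 3, softmax head of width 7."""
    rng = np.random.default_rng(0)
    net = _build_network(NetConfig(), n_channels=5, rng=rng)
    desc = [layer.describe() for layer in net.layers]
    convs = [d for d in desc if d["type"] == "conv1d"]
    lstms = [d for d in desc if d["type"] == "bilstm"]
    assert all(d["kernel_size"] == 3 for d in convs)
    assert [d["filters"] for d in convs] == [128, 192, 320]
    assert len(lstms) == 2
    assert lstms[0] == {"type": "bilstm", "units": 256, "return_sequences": True}
    assert lstms[1] == {"type": "bilstm", "units": 512, "return_sequences": False}
    assert desc[-1] == {"type": "dense", "units": 7, "activation": "softmax"}


def test_net_config_invariants():
    with pytest.raises(ValueError, match="kernel"):
        NetConfig(kernel_size=5)
    with pytest.raises(ValueError, match="conv_filters"):
        NetConfig(conv_filters=(64, 128))
    with pytest.raises(ValueError, match="conv_filters"):
        NetConfig(conv_filters=(320, 128))
    with pytest.raises(ValueError, match="7"):
        NetConfig(n_classes=5)


def test_forward_deterministic_and_probabilities_normalized():
    rng = np.random.default_rng(3)
    net = _build_network(NetConfig(dropout=0.0), n_channels=5, rng=rng)
    model = DLModel(config=NetConfig(dropout=0.0), network=net)
    sample = SequenceSample(matrix=np.random.default_rng(4).normal(size=(40, 5)))
    p1 = predict_proba(model, sample)
    p2 = predict_proba(model, sample)
    np.testing.assert_array_equal(p1, p2)
    assert p1.shape == (7,)
    assert p1.sum() == pytest.approx(1.0, abs=1e-6)
    assert (p1 >= 0).all()


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    cfg = NetConfig(dropout=0.0)
    net = _build_network(cfg, n_channels=5, rng=rng)
    model = DLModel(config=cfg, network=net, loss_trace=[1.0, 0.5],
                    train_accuracy=[0.3, 0.6],
                    channel_mean=np.arange(5.0), channel_std=np.ones(5))
    path = tmp_path / "model.npz"
    save_dl_model(model, path)
    back = load_dl_model(path)
    sample = SequenceSample(matrix=np.random.default_rng(6).normal(size=(32, 5)))
    np.testing.assert_allclose(predict_proba(back, sample), predict_proba(model, sample),
                               atol=1e-7)
    assert back.loss_trace == [1.0, 0.5]


def test_softmax_rows_sum_to_one(rng):
    logits = rng.normal(scale=20, size=(10, 7))
    P = _softmax(logits)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
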