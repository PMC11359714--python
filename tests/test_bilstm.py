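"""Recurrent interpolator: cell math, bidirectional passes, training.

The independent oracle is a pure-Python scalar-loop evaluation of the gate
equations (sigmoid/tanh per component, explicit dot products), against which
the vectorized implementation is checked on random instances.
"""

import math

import numpy as np
import pytest

from eegdense.bilstm import (
    LSTMCellParams,
    LSTMState,
    TrainConfig,
    bilstm_layer,
    ci_half_width,
    forward,
    init_network,
    lstm_cell_step,
    load_network,
    make_windows,
    predict_series,
    save_network,
    train,
)
from eegdense.montage import ChannelSplit
from eegdense.preprocess import ArtifactMask, Recording


# ----------------------------------------------------------------- oracle

def scalar_sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def scalar_cell_step(params, h_prev, c_prev, x_t):
    """Scalar-loop LSTM step: explicit per-component gate equations."""
    H = params.hidden
    concat = list(h_prev) + list(x_t)
    h_new, c_new = [], []
    for j in range(H):
        zf = sum(params.W_f[j][k] * concat[k] for k in range(len(concat))) + params.b_f[j]
        zi = sum(params.W_i[j][k] * concat[k] for k in range(len(concat))) + params.b_i[j]
        zo = sum(params.W_o[j][k] * concat[k] for k in range(len(concat))) + params.b_o[j]
        zc = sum(params.W_c[j][k] * concat[k] for k in range(len(concat))) + params.b_c[j]
        f = scalar_sigmoid(zf)
        i = scalar_sigmoid(zi)
        o = scalar_sigmoid(zo)
        g = math.tanh(zc)
        c = f * c_prev[j] + i * g
        c_new.append(c)
        h_new.append(o * math.tanh(c))
    return h_new, c_new


def scalar_bilstm_layer(p_fwd, p_bwd, seq):
    T = len(seq)
    H = p_fwd.hidden
    hf = [0.0] * H
    cf = [0.0] * H
    fwd = []
    for t in range(T):
        hf, cf = scalar_cell_step(p_fwd, hf, cf, seq[t])
        fwd.append(hf)
    hb = [0.0] * H
    cb = [0.0] * H
    bwd = [None] * T
    for t in range(T - 1, -1, -1):
        hb, cb = scalar_cell_step(p_bwd, hb, cb, seq[t])
        bwd[t] = hb
    return [fwd[t] + bwd[t] for t in range(T)]


def random_params(rng, hidden, input_dim, scale=0.8):
    return LSTMCellParams(
        W=rng.uniform(-scale, scale, size=(4 * hidden, hidden + input_dim)),
        b=rng.uniform(-scale, scale, size=4 * hidden),
    )


# ------------------------------------------------------------- cell tests

class TestCellStep:
    def test_matches_scalar_loop_on_random_instances(self, rng):
        for _ in range(100):
            H = int(rng.integers(1, 5))
            D = int(rng.integers(1, 5))
            p = random_params(rng, H, D)
            h0 = rng.uniform(-0.9, 0.9, size=H)
            c0 = rng.uniform(-2, 2, size=H)
            x = rng.uniform(-2, 2, size=D)
            state = lstm_cell_step(p, LSTMState(h=h0, C=c0), x)
            h_ref, c_ref = scalar_cell_step(p, h0, c0, x)
            assert np.all(np.abs(state.h - np.array(h_ref)) < 1e-10)
            assert np.all(np.abs(state.C - np.array(c_ref)) < 1e-10)

    def test_zero_parameters_halve_the_cell_state(self):
        # sigma(0) = 1/2 and tanh(0) = 0, so f = i = o = 1/2, c~ = 0,
        # C_t = C_{t-1}/2 and h_t = tanh(C_t)/2
        H = 3
        p = LSTMCellParams(W=np.zeros((4 * H, H + 2)), b=np.zeros(4 * H))
        c = np.array([0.4, -1.2, 2.0])
        state = lstm_cell_step(p, LSTMState(h=np.zeros(H), C=c), np.ones(2))
        assert np.allclose(state.C, 0.5 * c, atol=1e-15)
        assert np.allclose(state.h, 0.5 * np.tanh(0.5 * c), atol=1e-15)
        zero = lstm_cell_step(p, LSTMState(h=np.zeros(H), C=np.zeros(H)), np.ones(2))
        assert np.allclose(zero.h, 0.0) and np.allclose(zero.C, 0.0)

    def test_saturated_gates_preserve_memory_over_100_steps(self, rng):
        # open forget gate, closed input and output gates: C persists, h ~ 0
        H = 4
        b = np.concatenate([
            np.full(H, 50.0), np.full(H, -50.0), np.full(H, -50.0), np.zeros(H)
        ])
        p = LSTMCellParams(W=np.zeros((4 * H, H + 3)), b=b)
        c0 = rng.uniform(-1, 1, size=H)
        state = LSTMState(h=np.zeros(H), C=c0.copy())
        for _ in range(100):
            state = lstm_cell_step(p, state, rng.uniform(-1, 1, size=3))
        assert np.all(np.abs(state.C - c0) < 1e-6)
        assert np.all(np.abs(state.h) < 1e-6)

    def test_gate_ranges(self, rng):
        # hidden activations stay inside (-1, 1) by construction
        p = random_params(rng, 6, 3, scale=2.0)
        state = LSTMState(h=np.zeros(6), C=np.zeros(6))
        for _ in range(50):
            state = lstm_cell_step(p, state, rng.uniform(-5, 5, size=3))
            assert np.all(np.abs(state.h) < 1.0)

    def test_dimension_mismatch_rejected(self, rng):
        p = random_params(rng, 3, 2)
        with pytest.raises(ValueError):
            lstm_cell_step(p, LSTMState(h=np.zeros(3), C=np.zeros(3)), np.zeros(5))


class TestBiLSTMLayer:
    def test_matches_scalar_loop(self, rng):
        for _ in range(25):
            H = int(rng.integers(1, 5))
            D = int(rng.integers(1, 4))
            T = int(rng.integers(1, 7))
            pf = random_params(rng, H, D)
            pb = random_params(rng, H, D)
            seq = rng.uniform(-2, 2, size=(T, D))
            out = bilstm_layer(pf, pb, seq)
            ref = np.array(scalar_bilstm_layer(pf, pb, [list(r) for r in seq]))
            assert np.all(np.abs(out - ref) < 1e-10)

    def test_single_step_sees_same_input_in_both_directions(self, rng):
        pf = random_params(rng, 3, 2)
        pb = random_params(rng, 3, 2)
        x = rng.uniform(-1, 1, size=(1, 2))
        out = bilstm_layer(pf, pb, x)
        sf = lstm_cell_step(pf, LSTMState(h=np.zeros(3), C=np.zeros(3)), x[0])
        sb = lstm_cell_step(pb, LSTMState(h=np.zeros(3), C=np.zeros(3)), x[0])
        assert np.allclose(out[0], np.concatenate([sf.h, sb.h]), atol=1e-14)

    def test_palindrome_with_tied_directions_is_time_symmetric(self, rng):
        p = random_params(rng, 4, 2)
        half = rng.uniform(-1, 1, size=(3, 2))
        seq = np.concatenate([half, half[::-1]])  # palindrome, T = 6
        out = bilstm_layer(p, p, seq)
        H = 4
        # reversing time swaps the forward and backward blocks
        swapped = np.concatenate([out[::-1, H:], out[::-1, :H]], axis=1)
        assert np.allclose(out, swapped, atol=1e-12)

    def test_zero_parameters_zero_output(self):
        p = LSTMCellParams(W=np.zeros((8, 5)), b=np.zeros(8))
        out = bilstm_layer(p, p, np.ones((4, 3)))
        assert np.allclose(out, 0.0)

    def test_empty_sequence_rejected(self, rng):
        p = random_params(rng, 2, 2)
        with pytest.raises(ValueError):
            bilstm_layer(p, p, np.empty((0, 2)))


# -------------------------------------------------------------- net tests

def tiny_cfg(**kw):
    defaults = dict(batch_size=4, seq_len=10, hidden1=3, hidden2=4, seed=0,
                    max_epochs=2, allow_out_of_range=True)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestNetworkForward:
    def test_default_architecture_dimensions(self):
        net = init_network(18, 42, TrainConfig(seed=0))
        assert net.layer1_fwd.hidden == 120
        assert net.layer2_fwd.input_dim == 240  # 2 x 120 bidirectional features
        assert net.readout_W.shape == (42, 256)  # 2 x 128

    def test_zero_weights_output_is_readout_bias(self, rng):
        cfg = tiny_cfg()
        net = init_network(2, 3, cfg, rng)
        for p in net._params():
            p[...] = 0.0
        net.readout_b[...] = np.array([1.0, -2.0, 0.5])
        net.target_mean = np.array([10.0, 0.0, 0.0])
        net.target_sd = np.array([2.0, 1.0, 1.0])
        out = forward(net, rng.standard_normal((10, 2)))
        assert np.allclose(out, [12.0, -2.0, 0.5])

    def test_output_shape_contract(self, rng):
        net = init_network(5, 7, tiny_cfg(), rng)
        out = forward(net, rng.standard_normal((13, 5)))
        assert out.shape == (13, 7)

    def test_forward_deterministic(self, rng):
        net = init_network(4, 2, tiny_cfg(), rng)
        w = rng.standard_normal((10, 4))
        assert np.array_equal(forward(net, w), forward(net, w))


class TestMakeWindows:
    @pytest.fixture
    def rec(self, rng):
        return Recording(
            data=rng.standard_normal((5, 1500)), fs=250.0,
            channel_labels=("a", "b", "c", "d", "e"),
        )

    @pytest.fixture
    def split(self):
        return ChannelSplit(observed=(1, 2, 3), targets=(4, 5))

    def test_nonoverlapping_window_count(self, rec, split):
        X, Y = make_windows(rec, split, seq_len=150)
        assert X.shape == (10, 150, 3)
        assert Y.shape == (10, 150, 2)

    def test_half_second_context_at_250hz(self, rec, split):
        X, _ = make_windows(rec, split, seq_len=125)
        assert X.shape[1] / rec.fs == pytest.approx(0.5)

    def test_stride_one_matches_slicing(self, rng, split):
        rec = Recording(data=rng.standard_normal((5, 10)), fs=250.0,
                        channel_labels=("a", "b", "c", "d", "e"))
        X, Y = make_windows(rec, split, seq_len=5, stride=1)
        assert len(X) == 6
        for w, s in zip(X, range(6)):
            assert np.array_equal(w, rec.data[:3, s:s + 5].T)

    def test_artifact_windows_dropped(self, rec, split):
        mask = np.zeros((5, 1500), dtype=bool)
        mask[0, 300] = True  # falls in the 3rd window of 150
        X, _ = make_windows(rec, split, 150, artifact_mask=ArtifactMask(mask))
        assert len(X) == 9

    def test_too_long_window_rejected(self, rec, split):
        with pytest.raises(ValueError):
            make_windows(rec, split, seq_len=2000)


def _mixture_recordings(rng, n_obs=3, n_tgt=2, n=3000, noise=0.0):
    labels = tuple(f"ch{i}" for i in range(n_obs + n_tgt))
    obs = rng.standard_normal((n_obs, n))
    w = rng.dirichlet(np.ones(n_obs), size=n_tgt)
    tgt = w @ obs + noise * rng.standard_normal((n_tgt, n))
    data = np.concatenate([obs, tgt])
    rec = Recording(data=data, fs=250.0, channel_labels=labels)
    split = ChannelSplit(
        observed=tuple(range(1, n_obs + 1)),
        targets=tuple(range(n_obs + 1, n_obs + n_tgt + 1)),
    )
    return rec, split


class _FakeMontage:
    def __init__(self, labels):
        self.names = labels


class TestTraining:
    def test_max_epochs_zero_returns_initialized_network(self, rng):
        rec, split = _mixture_recordings(rng)
        net = train(rec, rec, split, _FakeMontage(rec.channel_labels),
                    tiny_cfg(max_epochs=0))
        out = forward(net, rng.standard_normal((10, 3)))
        assert out.shape == (10, 2)

    def test_same_seed_bit_identical_training(self, rng):
        rec, split = _mixture_recordings(rng, n=1200)
        cfg = tiny_cfg(max_epochs=3, seed=5)
        mont = _FakeMontage(rec.channel_labels)
        n1 = train(rec, rec, split, mont, cfg)
        n2 = train(rec, rec, split, mont, cfg)
        for a, b in zip(n1._params(), n2._params()):
            assert np.array_equal(a, b)

    def test_training_reduces_loss_100x_on_noiseless_mixture(self, rng):
        rec, split = _mixture_recordings(rng, n=4000, noise=0.0)
        mont = _FakeMontage(rec.channel_labels)
        cfg = tiny_cfg(batch_size=16, seq_len=40, hidden1=12, hidden2=12,
                       max_epochs=80, patience=80, learning_rate=5e-3, seed=2)
        X, Y = make_windows(rec, split, cfg.seq_len)
        net0 = train(rec, rec, split, mont, tiny_cfg(max_epochs=0, seq_len=40,
                                                     hidden1=12, hidden2=12, seed=2))
        net = train(rec, rec, split, mont, cfg)

        def loss(model):
            errs = [
                np.mean((forward(model, x) - y) ** 2)
                for x, y in zip(X[:, :, :], Y)
            ]
            return float(np.mean(errs))

        assert loss(net) < loss(net0) / 100.0

    def test_zero_variance_channel_rejected(self, rng):
        rec, split = _mixture_recordings(rng)
        data = rec.data.copy()
        data[0] = 5.0
        flat = Recording(data=data, fs=250.0, channel_labels=rec.channel_labels)
        with pytest.raises(ValueError):
            train(flat, flat, split, _FakeMontage(rec.channel_labels), tiny_cfg())


class TestPredictionAndCI:
    def test_gaussian_half_width_and_coverage(self, rng):
        # sd-1 residuals: the 95 % half-width is the normal quantile 1.96
        resid = rng.standard_normal(5000)
        half = float(ci_half_width(resid, 0.95))
        assert half == pytest.approx(1.959964, rel=0.05)
        errors = rng.standard_normal(5000)
        coverage = np.mean(np.abs(errors) <= half)
        assert 0.93 <= coverage <= 0.97

    def test_zero_residuals_zero_width_full_coverage(self):
        assert float(ci_half_width(np.zeros(100), 0.95)) == 0.0

    def test_half_width_monotone_in_level(self, rng):
        resid = rng.standard_normal(1000)
        assert float(ci_half_width(resid, 0.5)) < float(ci_half_width(resid, 0.95))

    def test_invalid_level(self, rng):
        with pytest.raises(ValueError):
            ci_half_width(rng.standard_normal(10), 1.5)

    def test_predict_series_covers_whole_recording(self, rng):
        rec, split = _mixture_recordings(rng, n=1234)
        net = train(rec, rec, split, _FakeMontage(rec.channel_labels),
                    tiny_cfg(max_epochs=0, seq_len=100))
        pred = predict_series(net, rec, split)
        assert pred.shape == (2, 1234)
        assert np.all(np.isfinite(pred))


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        rec, split = _mixture_recordings(rng, n=1200)
        net = train(rec, rec, split, _FakeMontage(rec.channel_labels),
                    tiny_cfg(max_epochs=1, seed=3))
        path = tmp_path / "ckpt.npz"
        save_network(net, path)
        loaded = load_network(path)
        w = rng.standard_normal((10, 3))
        assert np.array_equal(forward(net, w), forward(loaded, w))
        assert loaded.config.seq_len == net.config.seq_len
        assert loaded.observed_labels == net.observed_labels
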