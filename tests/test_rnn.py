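"""Ring-integrator RNN: dynamics, trials, training, deactivation scoring."""

import numpy as np
import pytest

import headcode as hc
from headcode.rnn import (
    RNNConfig,
    RNNState,
    TrainedRNN,
    deactivate_and_score,
    forward,
    make_trial_batch,
    make_trial_inputs,
    nmse,
    step_dynamics,
    total_normalized_error,
)

TWO_PI = 2 * np.pi


def _zero_rnn(n=4, **cfg_kwargs):
    cfg = RNNConfig(n_units=n, trial_len=20, n_trials=4, epochs=1,
                    init_phase=5, **cfg_kwargs)
    return TrainedRNN(
        W_rec=np.zeros((n, n)), W_in=np.zeros((3, n)),
        W_out=np.zeros((n, 2)), b=np.zeros(n), config=cfg,
    )


class TestStepDynamics:
    def test_origin_is_fixed_point_of_zero_network(self):
        rnn = _zero_rnn()
        state = RNNState.zeros(4)
        out = step_dynamics(state, np.zeros(3), rnn)
        np.testing.assert_array_equal(out.s, 0.0)
        np.testing.assert_array_equal(out.r, 0.0)

    def test_euler_decay_arithmetic(self):
        # with zero drive, s' = (1 - dt/tau) * s = 0.9 for dt=25, tau=250
        rnn = _zero_rnn()
        state = RNNState(s=np.ones(4), r=np.zeros(4))
        out = step_dynamics(state, np.zeros(3), rnn)
        np.testing.assert_allclose(out.s, 0.9)

    def test_negative_synaptic_input_rectified_to_zero_rate(self):
        rnn = _zero_rnn()
        state = step_dynamics(
            RNNState(s=-10 * np.ones(4), r=np.zeros(4)), np.zeros(3), rnn
        )
        np.testing.assert_array_equal(state.r, 0.0)
        assert np.all(state.s < 0)

    def test_rates_bounded_below_one(self):
        rng = np.random.default_rng(0)
        rnn = _zero_rnn()
        state = RNNState(s=rng.normal(0, 50, 4), r=np.zeros(4))
        out = step_dynamics(state, rng.normal(size=3), rnn)
        # tanh saturates to 1.0 in floating point; the open bound is analytic
        assert np.all((out.r >= 0) & (out.r <= 1))

    def test_nonfinite_state_fails_fast(self):
        rnn = _zero_rnn()
        with pytest.raises(FloatingPointError):
            step_dynamics(
                RNNState(s=np.array([np.nan, 0, 0, 0]), r=np.zeros(4)),
                np.zeros(3), rnn,
            )


class TestTrialConstruction:
    def test_phase_one_carries_initial_heading(self):
        cfg = RNNConfig(n_units=8, trial_len=50, init_phase=10)
        inp, tgt = make_trial_inputs(cfg, theta0=0.0, seed=0)
        np.testing.assert_allclose(inp[:10, 0], 1.0)  # cos 0
        np.testing.assert_allclose(inp[:10, 1], 0.0)  # sin 0
        np.testing.assert_allclose(inp[:10, 2], 0.0)  # no AHV yet
        np.testing.assert_allclose(inp[10:, :2], 0.0)

    def test_target_reconstructs_integrated_heading(self):
        cfg = RNNConfig(n_units=8, trial_len=200, init_phase=10)
        inp, tgt = make_trial_inputs(cfg, theta0=1.2, seed=1)
        theta = 1.2 + np.cumsum(inp[:, 2])
        recon = np.arctan2(tgt[:, 1], tgt[:, 0])
        np.testing.assert_allclose(
            np.mod(recon, TWO_PI), np.mod(theta, TWO_PI), atol=1e-9
        )

    def test_all_zero_ahv_trial_has_constant_target(self):
        cfg = RNNConfig(n_units=8, trial_len=50, init_phase=10, sigma=0.0)
        _, tgt = make_trial_inputs(cfg, theta0=0.7, seed=2)
        np.testing.assert_allclose(tgt[:, 0], np.cos(0.7))
        np.testing.assert_allclose(tgt[:, 1], np.sin(0.7))

    def test_half_of_batch_contains_zero_ahv_segment(self):
        cfg = RNNConfig(n_units=8, trial_len=300, init_phase=10)
        inp, _ = make_trial_batch(cfg, 100, seed=3)
        ahv = inp[10:, :, 2]
        # a zero-velocity segment shows as a run of >= 5 exact zeros
        has_seg = []
        for b in range(100):
            z = ahv[:, b] == 0
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, z, 0])))[::2]
            has_seg.append(len(runs) > 0 and runs.max() >= 5)
        assert sum(has_seg) == pytest.approx(50, abs=10)

    def test_euler_halving_dt_converges(self, tiny_rnn):
        # halving dt while doubling steps changes trajectories by O(dt)
        from dataclasses import asdict

        rnn = tiny_rnn
        cfg = rnn.config
        T = 40
        inputs = np.zeros((T, 1, 3))
        inputs[:, 0, 0] = 0.6
        y_coarse = forward(rnn, inputs)
        cfg_fine = RNNConfig(**{**asdict(cfg), "dt": cfg.dt / 2})
        rnn_fine = TrainedRNN(
            W_rec=rnn.W_rec, W_in=rnn.W_in, W_out=rnn.W_out, b=rnn.b,
            config=cfg_fine,
        )
        y_fine = forward(rnn_fine, np.repeat(inputs, 2, axis=0))
        err = np.max(np.abs(y_fine[1::2] - y_coarse))
        assert err < 0.1 * max(np.max(np.abs(y_coarse)), 1e-9)


class TestNMSE:
    def test_mean_predictor_scores_200(self):
        rng = np.random.default_rng(4)
        tgt = rng.normal(size=(100, 7, 2))
        pred = np.broadcast_to(
            tgt.reshape(-1, 2).mean(axis=0), tgt.shape
        ).copy()
        assert total_normalized_error(pred, tgt) == pytest.approx(200.0)

    def test_perfect_prediction_scores_zero(self):
        rng = np.random.default_rng(5)
        tgt = rng.normal(size=(50, 3, 2))
        assert total_normalized_error(tgt, tgt) == 0.0

    def test_per_output_normalization(self):
        rng = np.random.default_rng(6)
        tgt = rng.normal(size=(200, 1, 2))
        pred = tgt.copy()
        pred[..., 0] += 1.0  # constant offset on first output only
        per = nmse(pred, tgt)
        assert per[1] == 0.0
        assert per[0] > 0


class TestTraining:
    def test_error_decreases_and_is_seed_reproducible(self, tiny_rnn):
        trace = tiny_rnn.nmse_trace
        assert trace[-1] < 0.5 * trace[0]
        cfg = tiny_rnn.config
        again = hc.train(cfg)
        np.testing.assert_allclose(again.W_rec, tiny_rnn.W_rec)
        np.testing.assert_allclose(again.nmse_trace, trace)

    def test_untrained_network_uncorrelated_with_target(self):
        cfg = RNNConfig(n_units=32, trial_len=150, seed=8)
        rng = np.random.default_rng(8)
        from headcode.rnn import _init_weights

        W_rec, W_in, W_out, b = _init_weights(cfg, rng)
        rnn = TrainedRNN(W_rec=W_rec, W_in=W_in, W_out=W_out, b=b, config=cfg)
        inp, tgt = make_trial_batch(cfg, 40, seed=9)
        y = forward(rnn, inp)
        r = np.corrcoef(y.ravel(), tgt.ravel())[0, 1]
        assert abs(r) < 0.2

    def test_checkpoint_roundtrip(self, tiny_rnn, tmp_path):
        tiny_rnn.save(tmp_path / "net")
        back = TrainedRNN.load(tmp_path / "net")
        np.testing.assert_array_equal(back.W_rec, tiny_rnn.W_rec)
        assert back.config == tiny_rnn.config
        np.testing.assert_allclose(back.nmse_trace, tiny_rnn.nmse_trace)


class TestSessionGeneration:
    def test_session_shapes_and_duration(self, tiny_rnn):
        sess = hc.generate_session(tiny_rnn, n_steps=4000, seed=0,
                                   trial_len=500)
        assert sess.n_samples == 4000
        assert sess.n_units == tiny_rnn.n_units
        assert sess.duration == pytest.approx(4000 * 0.025)
        assert sess.meta["trial_seams"][:2] == [0, 500]
        assert np.all((sess.rates >= 0) & (sess.rates < 1))

    def test_session_reproducible_by_seed(self, tiny_rnn):
        s1 = hc.generate_session(tiny_rnn, n_steps=1000, seed=5)
        s2 = hc.generate_session(tiny_rnn, n_steps=1000, seed=5)
        np.testing.assert_array_equal(s1.rates, s2.rates)

    def test_hd_is_exact_integral_of_stored_ahv(self, tiny_rnn):
        sess = hc.generate_session(tiny_rnn, n_steps=2000, seed=1,
                                   trial_len=1000)
        seam = 1000
        dtheta = np.diff(np.unwrap(sess.hd[:seam]))
        np.testing.assert_allclose(
            dtheta, (sess.ahv[1:seam] * sess.dt), atol=1e-9
        )


class TestDeactivation:
    def test_empty_set_scores_intact_network(self, tiny_rnn):
        cfg = tiny_rnn.config
        trials = make_trial_batch(cfg, 20, seed=10)
        base = deactivate_and_score(tiny_rnn, set(), trials)
        y = forward(tiny_rnn, trials[0])
        assert base == pytest.approx(total_normalized_error(y, trials[1]))

    def test_deactivating_all_units_defined_not_crashing(self, tiny_rnn):
        cfg = tiny_rnn.config
        trials = make_trial_batch(cfg, 10, seed=11)
        err = deactivate_and_score(
            tiny_rnn, set(range(tiny_rnn.n_units)), trials
        )
        assert np.isfinite(err)
        base = deactivate_and_score(tiny_rnn, set(), trials)
        assert err > base

    def test_out_of_range_unit_rejected(self, tiny_rnn):
        trials = make_trial_batch(tiny_rnn.config, 2, seed=12)
        with pytest.raises(ValueError):
            deactivate_and_score(tiny_rnn, {tiny_rnn.n_units + 3}, trials)
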