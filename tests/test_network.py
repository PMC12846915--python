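"""Linear-network mechanics: initialisation, forward pass, gradients, training."""

import numpy as np
import pytest

import continualtwin as ct
from continualtwin.network import _trial_gradients
from continualtwin.schedule import Trial


def make_trial(stimulus_id=3, season="winter", target=200.0, feedback=True):
    return Trial(
        index=0,
        phase="trainA",
        block=1,
        stimulus_id=stimulus_id,
        season=season,
        target_deg=target,
        feedback_given=feedback,
        feedback_deg=target if feedback else float("nan"),
    )


class TestInit:
    def test_zero_scale_gives_zero_embedding(self):
        state = ct.init_network(ct.TrainConfig(sigma_embed=0.0, seed=0))
        assert np.all(state.W_embed == 0.0)

    def test_same_seed_identical(self):
        a = ct.init_network(ct.TrainConfig(seed=4))
        b = ct.init_network(ct.TrainConfig(seed=4))
        assert np.array_equal(a.W_embed, b.W_embed)
        assert np.array_equal(a.W_readout, b.W_readout)

    def test_lazy_embedding_scale(self):
        # pooled over >= 10 nets the sample s.d. should match sigma = 2 within 5%
        samples = np.concatenate(
            [ct.init_network(ct.TrainConfig.lazy(seed=s)).W_embed.ravel() for s in range(10)]
        )
        assert abs(samples.std() - 2.0) / 2.0 < 0.05


class TestForward:
    def test_zero_weights_zero_outputs(self):
        state = ct.NetworkState(np.zeros((50, 12)), np.zeros((4, 50)))
        assert np.allclose(ct.forward(state, 5), 0.0)

    def test_linearity_in_readout(self, rng):
        state = ct.init_network(ct.TrainConfig.lazy(seed=11))
        doubled = ct.NetworkState(state.W_embed, 2.0 * state.W_readout)
        assert np.allclose(ct.forward(doubled, 7), 2.0 * ct.forward(state, 7))

    def test_matches_dense_matrix_oracle(self, rng):
        state = ct.init_network(ct.TrainConfig.lazy(seed=12))
        for sid in range(12):
            onehot = np.zeros(12)
            onehot[sid] = 1.0
            oracle = state.W_readout @ (state.W_embed @ onehot)
            assert np.allclose(ct.forward(state, sid), oracle)

    def test_rejects_out_of_range_stimulus(self):
        state = ct.init_network(ct.TrainConfig(seed=0))
        with pytest.raises(ValueError):
            ct.forward(state, 12)


class TestOutputToAngle:
    @pytest.mark.parametrize(
        "pair,season,expected",
        [((1.0, 0.0), "summer", 90.0), ((0.0, 1.0), "summer", 0.0), ((0.0, -1.0), "winter", 180.0)],
    )
    def test_cardinal_directions(self, pair, season, expected):
        outputs = np.zeros(4)
        p = 0 if season == "summer" else 2
        outputs[p : p + 2] = pair
        assert ct.output_to_angle(outputs, season) == pytest.approx(expected)

    def test_round_trip_identity(self, rng):
        angles = rng.uniform(0, 360, size=200)
        rad = np.deg2rad(angles)
        for a, s, c in zip(angles, np.sin(rad), np.cos(rad)):
            out = np.array([s, c, 0.0, 0.0])
            assert ct.output_to_angle(out, "summer") == pytest.approx(a, abs=1e-9)


class TestSgdStep:
    def test_exact_prediction_gives_zero_update(self):
        # engineer a state whose winter output equals the target exactly
        target = 60.0
        rad = np.deg2rad(target)
        W_embed = np.zeros((50, 12))
        W_embed[0, 3] = 1.0
        W_readout = np.zeros((4, 50))
        W_readout[2, 0] = np.sin(rad)
        W_readout[3, 0] = np.cos(rad)
        state = ct.NetworkState(W_embed, W_readout)
        new, resp = ct.sgd_step(state, make_trial(target=target))
        assert resp == pytest.approx(target)
        assert np.allclose(new.W_embed, state.W_embed)
        assert np.allclose(new.W_readout, state.W_readout)

    def test_no_feedback_leaves_state_bit_identical(self):
        state = ct.init_network(ct.TrainConfig.lazy(seed=3))
        before_e, before_r = state.W_embed.copy(), state.W_readout.copy()
        new, _ = ct.sgd_step(state, make_trial(feedback=False))
        assert np.array_equal(new.W_embed, before_e)
        assert np.array_equal(new.W_readout, before_r)

    def test_gradient_matches_finite_differences(self, rng):
        def loss(We, Wr, sid, pair, rad):
            out = (Wr @ We[:, sid])[pair : pair + 2]
            err = out - np.array([np.sin(rad), np.cos(rad)])
            return 0.5 * float(err @ err)

        for _ in range(5):
            state = ct.NetworkState(rng.normal(0, 1, (8, 12)), rng.normal(0, 1, (4, 8)))
            sid, pair, rad = 4, 2, rng.uniform(0, 2 * np.pi)
            _, g_embed, g_readout = _trial_gradients(state, sid, pair, rad)
            eps = 1e-6
            # embedding column
            for k in [0, 3, 7]:
                Wp, Wm = state.W_embed.copy(), state.W_embed.copy()
                Wp[k, sid] += eps
                Wm[k, sid] -= eps
                num = (loss(Wp, state.W_readout, sid, pair, rad) - loss(Wm, state.W_readout, sid, pair, rad)) / (2 * eps)
                assert num == pytest.approx(g_embed[k], rel=1e-6, abs=1e-8)
            # readout rows of the probed pair
            for r, k in [(pair, 1), (pair + 1, 5)]:
                Wp, Wm = state.W_readout.copy(), state.W_readout.copy()
                Wp[r, k] += eps
                Wm[r, k] -= eps
                num = (loss(state.W_embed, Wp, sid, pair, rad) - loss(state.W_embed, Wm, sid, pair, rad)) / (2 * eps)
                assert num == pytest.approx(g_readout[r - pair, k], rel=1e-6, abs=1e-8)

    def test_unprobed_outputs_not_penalised(self, rng):
        state = ct.NetworkState(rng.normal(0, 1, (8, 12)), rng.normal(0, 1, (4, 8)))
        new, _ = ct.sgd_step(state, make_trial(season="winter"))
        # summer readout rows untouched by a winter trial
        assert np.array_equal(new.W_readout[0:2], state.W_readout[0:2])

    def test_repeated_trial_drives_loss_to_zero(self):
        state = ct.init_network(ct.TrainConfig(seed=21))
        trial = make_trial(target=123.0)
        rad = np.deg2rad(123.0)
        for _ in range(10_000):
            state, _ = ct.sgd_step(state, trial)
        out = ct.forward(state, trial.stimulus_id)[2:4]
        err = out - np.array([np.sin(rad), np.cos(rad)])
        assert 0.5 * err @ err < 1e-6

    def test_per_trial_loss_nonincreasing(self):
        state = ct.init_network(ct.TrainConfig(seed=22))
        trial = make_trial(target=45.0, season="summer")
        rad = np.deg2rad(45.0)

        def cur_loss(s):
            err = ct.forward(s, trial.stimulus_id)[0:2] - np.array([np.sin(rad), np.cos(rad)])
            return 0.5 * err @ err

        prev = cur_loss(state)
        for _ in range(500):
            state, _ = ct.sgd_step(state, trial)
            cur = cur_loss(state)
            assert cur <= prev + 1e-12
            prev = cur


class TestTraining:
    def test_zero_repeats_no_op(self, near_schedule):
        cfg = ct.TrainConfig(repeats_per_phase=0, seed=1)
        init = ct.init_network(cfg)
        res = ct.TwinnedLinearNetwork(near_schedule, cfg).fit(start_state=init)
        assert res.responses.empty
        assert np.array_equal(res.state.W_embed, init.W_embed)

    def test_rich_net_reaches_near_zero_training_loss(self, trained_rich_near):
        assert trained_rich_near.end_of_phase_loss("trainA") < 1e-3
        assert trained_rich_near.end_of_phase_loss("trainB") < 1e-3

    def test_far_taskB_initial_loss_exceeds_same(self, far_schedule, same_schedule):
        reps = {}
        for name, sched in [("far", far_schedule), ("same", same_schedule)]:
            res = ct.TwinnedLinearNetwork(sched, ct.TrainConfig.rich(seed=55)).fit()
            tr = res.loss_trace
            reps[name] = float(
                tr[(tr.phase == "trainB") & (tr.repeat == 0)]["mean_loss"].iloc[0]
            )
        assert reps["far"] > reps["same"]

    def test_same_condition_end_state_retains_task_a_winter_map(self, trained_rich_same, same_schedule):
        # both tasks share one rule: continual training cannot conflict, so
        # task A winter predictions survive task B training with only the
        # few-degree distortion caused by readout retuning to task B's
        # summer placements
        spec = same_schedule.spec
        state = trained_rich_same.state
        errs = [
            ct.circular_error(ct.output_to_angle(ct.forward(state, sid), "winter"), spec.winter_location(sid))
            for sid in range(6)
        ]
        assert max(errs) < 5.0
        assert np.mean(errs) < 3.0

    def test_responses_logged_before_update(self, near_schedule):
        # the first response to any stimulus comes from the untrained net:
        # with rich init the output is ~1e-6, so the logged angle must be
        # the raw atan2 of that tiny vector, not a post-update prediction
        cfg = ct.TrainConfig(repeats_per_phase=1, seed=6)
        model = ct.TwinnedLinearNetwork(near_schedule, cfg)
        res = model.fit()
        first = res.responses.iloc[0]
        init = ct.init_network(cfg)
        expected = ct.output_to_angle(ct.forward(init, int(first.stimulus_id)), first.season)
        assert first.response_deg == pytest.approx(expected)

    def test_deterministic_given_seed(self, near_schedule):
        cfg = ct.TrainConfig(repeats_per_phase=2, seed=8)
        a = ct.TwinnedLinearNetwork(near_schedule, cfg).fit()
        b = ct.TwinnedLinearNetwork(near_schedule, cfg).fit()
        assert np.array_equal(a.state.W_embed, b.state.W_embed)
        assert a.responses.response_deg.equals(b.responses.response_deg)
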