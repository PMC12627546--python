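"""Follow-net: windowing, training, prediction contracts, causal rollout."""

import numpy as np
import pytest

from mirrorgame.follow_net import (
    FollowNetConfig,
    _renorm_output,
    make_windows,
    predict_next_pose,
    run_follower,
    train_follow,
)
from mirrorgame.quaternions import geodesic_distance
from mirrorgame.sequence import MotionSequence
from mirrorgame.synthetic import SynthesisConfig, derive_follower, generate_leader
from conftest import TOY_FOLLOW_CONFIG


def _toy_pair(T_frames: float, seed: int = 31):
    leader = generate_leader(SynthesisConfig(seed=seed), T_frames / 90.0)
    return leader, derive_follower(leader, 0, 0.0)


class TestConfig:
    def test_default_window_geometry(self):
        cfg = FollowNetConfig()
        assert cfg.history == 120 and cfg.stride == 4
        assert cfg.input_frames == 30
        assert cfg.features == 40

    def test_history_stride_divisibility(self):
        with pytest.raises(ValueError):
            FollowNetConfig(history=121, stride=4)


class TestMakeWindows:
    def test_boundary_no_target(self):
        cfg = FollowNetConfig(history=120, stride=4)
        leader, follower = _toy_pair(121)
        with pytest.raises(ValueError):
            make_windows(leader, follower, cfg)

    @pytest.mark.parametrize("T", [122, 160, 221])
    def test_count_formula(self, T):
        cfg = FollowNetConfig(history=120, stride=4)
        leader, follower = _toy_pair(T)
        X, Y = make_windows(leader, follower, cfg)
        assert X.shape == (T - cfg.history - 1, cfg.input_frames, cfg.features)
        assert Y.shape == (T - cfg.history - 1, cfg.features)

    def test_inputs_are_canonical_unit_quaternions(self):
        cfg = TOY_FOLLOW_CONFIG
        leader, follower = _toy_pair(200)
        X, _ = make_windows(leader, follower, cfg)
        q = X.reshape(X.shape[0], X.shape[1], -1, 4)
        np.testing.assert_allclose(np.linalg.norm(q, axis=-1), 1.0, atol=1e-3)
        assert np.all(q[..., 0] >= 0)

    def test_window_content_indexing(self):
        """Input block ends at frame t; target is the follower frame t+1."""
        cfg = FollowNetConfig(history=8, stride=2)
        leader, follower = _toy_pair(20)
        X, Y = make_windows(leader, follower, cfg)
        lead_flat = leader.quats.reshape(leader.n_frames, -1)
        fol_flat = follower.quats.reshape(follower.n_frames, -1)
        # first window: t = history = 8; inputs at frames 2,4,6,8
        np.testing.assert_array_equal(X[0], lead_flat[[2, 4, 6, 8]])
        np.testing.assert_array_equal(Y[0], fol_flat[9])


class TestTraining:
    def test_learns_identity_mapping(self, toy_follow):
        """Lag-0 zero-noise corpus: held-out mean per-joint geodesic error
        below 0.05 rad."""
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, Y = make_windows(held.leader, held.follower, cfg)
        pred = _renorm_output(toy_follow["model"].predict(X), cfg.joints)
        true = _renorm_output(Y, cfg.joints)
        err = geodesic_distance(pred, true).mean()
        assert err < 0.05

    def test_loss_decreases_over_epochs(self, toy_follow):
        losses = toy_follow["losses"]
        assert losses[-1] <= losses[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_follow([], TOY_FOLLOW_CONFIG)

    def test_training_determinism(self):
        """Two small runs with the same seed give identical loss curves."""
        from mirrorgame.synthetic import generate_dyad_corpus

        corpus = generate_dyad_corpus(
            SynthesisConfig(seed=3), 1, ("lead",), duration=3.0
        )
        cfg = FollowNetConfig(history=20, stride=2, hidden=8, dense_widths=(8,), epochs=2)
        _, l1 = train_follow(corpus, cfg, seed=1)
        _, l2 = train_follow(corpus, cfg, seed=1)
        assert l1 == l2


class TestPrediction:
    def test_output_contract(self, toy_follow):
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        pose = predict_next_pose(toy_follow["model"], X[0], cfg.joints)
        norms = np.linalg.norm(pose.quats, axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert np.all(pose.quats[:, 0] >= 0)

    def test_deterministic(self, toy_follow):
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        a = predict_next_pose(toy_follow["model"], X[5], cfg.joints)
        b = predict_next_pose(toy_follow["model"], X[5], cfg.joints)
        np.testing.assert_array_equal(a.quats, b.quats)

    def test_identity_model_tracks_last_input(self, toy_follow):
        """On the lag-0 toy fit, the prediction stays near the leader's
        current pose."""
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        pose = predict_next_pose(toy_follow["model"], X[10], cfg.joints)
        last_input = X[10, -1].reshape(-1, 4)
        assert geodesic_distance(pose.quats, last_input).mean() < 0.05

    def test_malformed_window_rejected(self, toy_follow):
        with pytest.raises(ValueError):
            predict_next_pose(toy_follow["model"], np.zeros((3, 7)))


class TestRollout:
    def test_output_length_and_rate(self, toy_follow):
        cfg = toy_follow["config"]
        leader = toy_follow["held"].leader
        out = run_follower(toy_follow["model"], leader, cfg)
        assert out.n_frames == leader.n_frames
        assert out.rate == leader.rate

    def test_causality(self, toy_follow):
        """Truncating the leader after frame t does not change outputs
        up to t+1."""
        cfg = toy_follow["config"]
        leader = toy_follow["held"].leader
        full = run_follower(toy_follow["model"], leader, cfg)
        t_cut = 200
        truncated = MotionSequence(
            leader.rate, leader.joints, leader.quats[: t_cut + 1]
        )
        part = run_follower(toy_follow["model"], truncated, cfg)
        # the truncated rollout covers frames 0..t_cut; all are unchanged
        np.testing.assert_allclose(part.quats, full.quats[: t_cut + 1], atol=1e-12)

    def test_output_continuity(self, toy_follow):
        """Consecutive predicted poses stay within 0.3 rad geodesic per
        joint on smooth leaders (no pose jumps)."""
        cfg = toy_follow["config"]
        leader = toy_follow["held"].leader
        out = run_follower(toy_follow["model"], leader, cfg)
        steps = geodesic_distance(out.quats[cfg.history :-1], out.quats[cfg.history + 1 :])
        assert steps.max() < 0.3

    def test_lag_recovery_from_rollout(self, lag20_follow):
        """Trained on 20-frame-lag dyads, the rollout follows a fresh leader
        with a positive lag within 25% of the generative value."""
        import mirrorgame as mg
        from mirrorgame.kinematics import filter_trajectory, speed_profile
        from mirrorgame.sequence import hand_track_from_sequence

        cfg = lag20_follow["config"]
        leader = lag20_follow["leader"]
        out = run_follower(lag20_follow["model"], leader, cfg)
        sp_out = speed_profile(
            filter_trajectory(hand_track_from_sequence(out), leader.rate)
        ).speed
        sp_lead = speed_profile(filter_trajectory(leader.hand_track, leader.rate)).speed
        res = mg.wtlcc(sp_out, sp_lead)
        assert np.all(res.lags > 0)  # the rollout follows
        assert mg.mean_abs_lag(res) == pytest.approx(20.0, rel=0.25)

    def test_short_leader_rejected(self, toy_follow):
        cfg = toy_follow["config"]
        leader = generate_leader(SynthesisConfig(seed=1), (cfg.history + 1) / 90.0)
        with pytest.raises(ValueError):
            run_follower(toy_follow["model"], leader, cfg)
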