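"""Turing-test confusion metrics and follow-net sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from mirrorgame.evaluation import (
    confusion_rates,
    perturbed_prediction_distance,
    sensitivity_matrix,
)
from mirrorgame.follow_net import FollowNetConfig, make_windows, train_follow
from mirrorgame.quaternions import from_axis_angle
from mirrorgame.sequence import MotionSequence
from mirrorgame.skeleton import FOCAL_ARM_JOINTS, MODEL_JOINTS
from mirrorgame.synthetic import (
    SynthesisConfig,
    derive_follower,
    generate_dyad_corpus,
    generate_turing_table,
)


def _independent_rates(df):
    """Plain counting, independent of the implementation."""
    fn = fp = n_art = n_hum = 0
    for _, row in df.iterrows():
        if row["s"] == 1:
            n_art += 1
            fn += int(row["s_tilde"] == 0)
        else:
            n_hum += 1
            fp += int(row["s_tilde"] == 1)
    return 100 * fn / n_art, 100 * fp / n_hum


class TestConfusionRates:
    def test_oracle_table(self):
        df = generate_turing_table(200, "oracle", seed=0)
        s = confusion_rates(df)["overall"]
        assert s.fnr == 0.0 and s.fpr == 0.0 and s.accuracy == 100.0

    def test_direct_count_example(self):
        """4 artificial trials, guesses [1,1,0,0] -> FNR 50%."""
        df = pd.DataFrame({"s": [1, 1, 1, 1], "s_tilde": [1, 1, 0, 0]})
        s = confusion_rates(df)["overall"]
        assert s.fnr == 50.0
        assert np.isnan(s.fpr)  # no human trials: undefined, not 0

    def test_matches_independent_count(self):
        df = generate_turing_table(500, "random", seed=1)
        s = confusion_rates(df)["overall"]
        fnr, fpr = _independent_rates(df)
        assert s.fnr == pytest.approx(fnr)
        assert s.fpr == pytest.approx(fpr)
        # accuracy identity from the class-weighted error rates
        expected_acc = 100 - (s.fnr * s.n_hri + s.fpr * s.n_hhi) / (s.n_hri + s.n_hhi)
        assert s.accuracy == pytest.approx(expected_acc)

    def test_random_guess_accuracy_near_chance(self):
        df = generate_turing_table(10_000, "random", seed=2)
        s = confusion_rates(df)["overall"]
        half_width = 100 * 2.576 * np.sqrt(0.25 / len(df))
        assert abs(s.accuracy - 50.0) < half_width

    def test_stratified_rates(self):
        df = generate_turing_table(600, "random", seed=3)
        by_cond = confusion_rates(df, by="condition")
        assert set(by_cond) == {"lead", "follow", "improvise"}
        assert sum(s.n_hri + s.n_hhi for s in by_cond.values()) == 600

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            confusion_rates(pd.DataFrame(columns=["s", "s_tilde"]))


class TestPerturbedDistance:
    def test_original_replacement_is_zero(self, toy_follow):
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        X = X[:20]
        # freeze the hand to the pose it already holds in every frame:
        # only exactly constant-joint windows give exactly zero, so perturb
        # with per-window current values and expect near-zero drift
        j = MODEL_JOINTS.index("left_hand")
        repl = X[:, -1, 4 * j : 4 * j + 4]
        X_const = X.copy()
        X_const[:, :, 4 * j : 4 * j + 4] = repl[:, None, :]
        d = perturbed_prediction_distance(
            toy_follow["model"], X_const, "left_hand", repl, "left_hand"
        )
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_perturbation_angle(self, toy_follow):
        """Larger frozen-pose rotations displace the output more."""
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        X = X[:30]
        axis = np.array([0.0, 0.0, 1.0])
        dists = []
        for angle in (0.1, 0.4, 0.8, 1.6):
            repl = from_axis_angle(axis, angle)
            dists.append(
                perturbed_prediction_distance(
                    toy_follow["model"], X, "left_hand", repl, "left_hand"
                )
            )
        assert all(b >= a for a, b in zip(dists, dists[1:]))

    def test_unknown_joint_rejected(self, toy_follow):
        with pytest.raises(ValueError):
            perturbed_prediction_distance(
                toy_follow["model"], np.zeros((1, 10, 40)), "pelvis",
                np.array([1.0, 0, 0, 0]), "left_hand",
            )


class TestSensitivityMatrix:
    def test_diagonal_dominance_on_identity_coupling(self, toy_follow):
        """The lag-0 toy model copies each leader joint to the matching
        follower joint, so every row peaks on the diagonal."""
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        sens = sensitivity_matrix(
            toy_follow["model"], X, n_sequences=50, n_replacements=3, seed=3,
            config=cfg,
        )
        assert sens.leader_joints == FOCAL_ARM_JOINTS
        for r in range(len(FOCAL_ARM_JOINTS)):
            assert sens.values[r].argmax() == r
            assert np.all(sens.values[r] >= 0)

    def test_reproducible_for_fixed_seed(self, toy_follow):
        cfg = toy_follow["config"]
        held = toy_follow["held"]
        X, _ = make_windows(held.leader, held.follower, cfg)
        a = sensitivity_matrix(
            toy_follow["model"], X, n_sequences=20, n_replacements=2, seed=9, config=cfg
        )
        b = sensitivity_matrix(
            toy_follow["model"], X, n_sequences=20, n_replacements=2, seed=9, config=cfg
        )
        np.testing.assert_array_equal(a.values, b.values)

    def test_insufficient_corpus_rejected(self, toy_follow):
        with pytest.raises(ValueError):
            sensitivity_matrix(toy_follow["model"], np.zeros((5, 10, 40)), n_sequences=10)

    def test_decoupled_joint_yields_near_zero_row(self):
        """A follower whose head ignores the leader entirely: perturbing the
        leader's head barely moves any output."""
        cfg = FollowNetConfig(history=20, stride=2, hidden=32, dense_widths=(32,), epochs=15)
        syn = SynthesisConfig(seed=31, rate=90.0, lag=0, follower_noise=0.0)
        corpus = generate_dyad_corpus(syn, 1, ("lead",), duration=30.0)
        trial = corpus[0]
        # freeze the follower's head so no leader joint drives it, and
        # scramble the leader's head so it carries no usable signal
        fol_q = trial.follower.quats.copy()
        head = MODEL_JOINTS.index("head")
        fol_q[:, head] = fol_q[0, head]
        follower = MotionSequence(90.0, MODEL_JOINTS, fol_q)
        from mirrorgame.synthetic import _geodesic_jitter

        lead_q = trial.leader.quats.copy()
        rng = np.random.default_rng(5)
        lead_q[:, head] = _geodesic_jitter(lead_q[:, head], 0.5, rng)
        leader = MotionSequence(90.0, MODEL_JOINTS, lead_q)
        from mirrorgame.follow_net import train_follow as tf
        from mirrorgame.synthetic import DyadTrial

        model, _ = tf(
            [DyadTrial(leader, follower, condition="lead")], cfg, seed=2
        )
        X, _ = make_windows(leader, follower, cfg)
        sens = sensitivity_matrix(
            model, X, n_sequences=40, n_replacements=3, seed=4,
            leader_joints=("head", "left_hand"),
            follower_joints=("head", "left_hand"),
            config=cfg,
        )
        head_row = sens.values[0]
        hand_row = sens.values[1]
        assert head_row.max() < 0.2 * hand_row.max()
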