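"""Agent controller: SLERP blending, role switching, full simulation."""

import numpy as np
import pytest

from mirrorgame.controller import (
    ControllerConfig,
    RoleState,
    blend_poses,
    run_agent,
    update_role,
)
from mirrorgame.quaternions import geodesic_distance, random_canonical
from mirrorgame.sequence import PoseFrame, constant_sequence, identity_pose
from mirrorgame.skeleton import FULL_SKELETON, MODEL_JOINTS
from mirrorgame.synthetic import SynthesisConfig, generate_leader


def _random_pose(seed):
    rng = np.random.default_rng(seed)
    return PoseFrame(MODEL_JOINTS, random_canonical(rng, len(MODEL_JOINTS)))


class TestBlendPoses:
    def test_endpoints(self):
        lead, follow = _random_pose(1), _random_pose(2)
        np.testing.assert_allclose(
            blend_poses(lead, follow, 0.0).quats, follow.quats, atol=1e-12
        )
        d = geodesic_distance(blend_poses(lead, follow, 1.0).quats, lead.quats)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_linear_angle_property(self):
        """w = 0.1 puts the blend at 10% of the geodesic from follow to lead."""
        lead, follow = _random_pose(3), _random_pose(4)
        blended = blend_poses(lead, follow, 0.1)
        full = geodesic_distance(follow.quats, lead.quats)
        part = geodesic_distance(follow.quats, blended.quats)
        np.testing.assert_allclose(part, 0.1 * full, atol=1e-9)

    def test_mismatched_joint_sets_rejected(self):
        torso = FULL_SKELETON.subset(("head", "sternum"))
        a = PoseFrame(torso, identity_pose(torso))
        with pytest.raises(ValueError):
            blend_poses(a, _random_pose(5), 0.5)


class TestUpdateRole:
    def test_distance_trigger_forces_follow_immediately(self):
        cfg = ControllerConfig()
        rng = np.random.default_rng(0)
        state = RoleState(coefficient=1, next_decision=100.0)
        out = update_role(state, 1.0, 0.31, rng, cfg)
        assert out.coefficient == 0
        assert out.triggered

    def test_below_threshold_between_epochs_no_change(self):
        cfg = ControllerConfig()
        rng = np.random.default_rng(0)
        state = RoleState(coefficient=1, next_decision=100.0)
        out = update_role(state, 1.0, 0.3, rng, cfg)  # exactly at threshold
        assert out.coefficient == 1
        assert not out.triggered

    def test_unbiased_switching_is_symmetric(self):
        """Long-run leading fraction within the 99% binomial CI of 50%."""
        cfg = ControllerConfig(balancing=False)
        rng = np.random.default_rng(42)
        state = RoleState(next_decision=cfg.decision_period_s)
        n = 100_000
        lead = 0
        t = 0.0
        for _ in range(n):
            t += cfg.decision_period_s
            state = update_role(state, t, 0.0, rng, cfg)
            lead += state.coefficient
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(lead / n - 0.5) < half_width

    def test_balancing_keeps_roles_near_parity(self):
        """With the +1% bias, leading fraction stays in [45%, 55%]."""
        cfg = ControllerConfig(balancing=True)
        rng = np.random.default_rng(7)
        state = RoleState(next_decision=cfg.decision_period_s)
        n = 10_000
        lead = 0
        t = 0.0
        for _ in range(n):
            t += cfg.decision_period_s
            state = update_role(state, t, 0.0, rng, cfg)
            lead += state.coefficient
        assert 0.45 <= lead / n <= 0.55

    def test_switch_probability_stays_in_band_and_resets(self):
        cfg = ControllerConfig(balancing=True)
        rng = np.random.default_rng(3)
        state = RoleState(next_decision=cfg.decision_period_s)
        t = 0.0
        saw_above_base = False
        for _ in range(2000):
            t += cfg.decision_period_s
            new = update_role(state, t, 0.0, rng, cfg)
            assert cfg.base_switch_prob <= new.switch_prob <= 1.0
            if new.switch_prob > cfg.base_switch_prob:
                saw_above_base = True
            if state.coefficient == 0 and new.coefficient == 1:
                # becoming leader resets the bias
                assert new.switch_prob == cfg.base_switch_prob
            state = new
        assert saw_above_base


@pytest.fixture(scope="module")
def sim_setup(request):
    """Partner sequence + trained toy follow model + constant lead sequence."""
    toy = request.getfixturevalue("toy_follow")
    cfg = toy["config"]
    partner = generate_leader(SynthesisConfig(seed=55), 15.0)
    lead_seq = generate_leader(SynthesisConfig(seed=66), 16.0)
    return {"partner": partner, "model": toy["model"], "lead": lead_seq, "fcfg": cfg}


class TestRunAgent:
    def test_follow_mode_output_length(self, sim_setup):
        agent, trace = run_agent(
            sim_setup["partner"], "follow", sim_setup["model"], sim_setup["lead"],
            seed=1, follow_config=sim_setup["fcfg"],
        )
        assert agent.n_frames == sim_setup["partner"].n_frames
        assert (trace["w"] == 0.1).all()
        assert (trace["coefficient"] == 0).all()

    def test_lead_mode_weight(self, sim_setup):
        _, trace = run_agent(
            sim_setup["partner"], "lead", sim_setup["model"], sim_setup["lead"],
            seed=1, follow_config=sim_setup["fcfg"],
        )
        assert (trace["w"] == 0.9).all()

    def test_missing_partner_rejected(self, sim_setup):
        with pytest.raises(ValueError):
            run_agent(None, "follow", sim_setup["model"], sim_setup["lead"])

    def test_improvise_trace_is_continuous(self, sim_setup):
        """Blend weight ramps: per-frame |dw| never exceeds the 1 s linear
        ramp step."""
        agent, trace = run_agent(
            sim_setup["partner"], "improvise", sim_setup["model"], sim_setup["lead"],
            seed=2, follow_config=sim_setup["fcfg"],
        )
        w = trace["w"].to_numpy()
        rate = sim_setup["partner"].rate
        ramp_step = (0.9 - 0.1) / rate  # 1 s ramp
        assert np.abs(np.diff(w)).max() <= ramp_step + 1e-12
        assert w.min() >= 0.1 - 1e-12 and w.max() <= 0.9 + 1e-12

    def test_improvise_decisions_on_4s_grid(self, sim_setup):
        """Role changes happen at 4 s epochs except distance-triggered
        switches."""
        _, trace = run_agent(
            sim_setup["partner"], "improvise", sim_setup["model"], sim_setup["lead"],
            seed=3, follow_config=sim_setup["fcfg"],
        )
        coef = trace["coefficient"].to_numpy()
        trig = trace["triggered"].to_numpy()
        times = trace["time_s"].to_numpy()
        changes = np.nonzero(np.diff(coef))[0] + 1
        for i in changes:
            if trig[i]:
                continue
            # decision epochs are multiples of 4 s; allow one frame of slack
            phase = times[i] % 4.0
            assert min(phase, 4.0 - phase) < 2.0 / sim_setup["partner"].rate

    def test_determinism(self, sim_setup):
        out = [
            run_agent(
                sim_setup["partner"], "improvise", sim_setup["model"],
                sim_setup["lead"], seed=4, follow_config=sim_setup["fcfg"],
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(out[0][0].quats, out[1][0].quats)
        assert out[0][1].equals(out[1][1])

    def test_output_continuity_across_role_switches(self, sim_setup):
        """No pose teleport: per-joint geodesic steps stay bounded during
        weight ramps."""
        agent, _ = run_agent(
            sim_setup["partner"], "improvise", sim_setup["model"], sim_setup["lead"],
            seed=5, follow_config=sim_setup["fcfg"],
        )
        h = sim_setup["fcfg"].history
        steps = geodesic_distance(agent.quats[h:-1], agent.quats[h + 1 :])
        assert steps.max() < 0.3
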