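"""Joint control of the artificial agent: SLERP blending of lead-net and
follow-net outputs, plus the improvisation role-switching process.

The agent's pose is a per-joint spherical interpolation between the
follow-net output and the (pre-generated) lead-net motion with lead-weight
``w``: ``w = 0.1`` while following (a subtle leading component keeps the
agent from freezing when the partner stands still) and ``w = 0.9`` while
leading (a subtle following component imitates a 'good' leader).  During
improvisation a binary role coefficient is redrawn every 4 s with a switch
probability starting at 50%; to keep roles balanced the probability of
becoming leader grows by 1% per decision while following dominates the
recent past, and resets to 50% upon becoming leader.  Whenever the
inter-hand distance exceeds 0.3 scene units the agent drops to following
immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinematics import filter_trajectory, hand_distance
from .nn import RecurrentRegressor
from .quaternions import slerp
from .sequence import (
    FKConfig,
    MotionSequence,
    PoseFrame,
    forward_kinematics_hand,
    with_fk_hand_track,
)
from .follow_net import FollowNetConfig, run_follower

__all__ = [
    "ControllerConfig",
    "RoleState",
    "blend_poses",
    "update_role",
    "run_agent",
]

MODES = ("lead", "follow", "improvise")


@dataclass(frozen=True)
class ControllerConfig:
    """Role-switching and blending parameters."""

    decision_period_s: float = 4.0
    base_switch_prob: float = 0.5
    bias_increment: float = 0.01  # per decision while following dominates
    balance_window_s: float = 20.0  # trailing window judging dominance
    distance_threshold: float = 0.3  # scene units; beyond this, follow
    follow_weight: float = 0.1
    lead_weight: float = 0.9
    ramp_s: float = 1.0  # linear blend-weight ramp at role changes
    balancing: bool = True

    @property
    def balance_epochs(self) -> int:
        return max(1, int(round(self.balance_window_s / self.decision_period_s)))


@dataclass(frozen=True)
class RoleState:
    """State of the role-switching process (functional updates)."""

    coefficient: int = 0  # 0 = following, 1 = leading
    switch_prob: float = 0.5  # probability of becoming leader at a decision
    next_decision: float = 4.0  # s
    epoch_history: tuple[int, ...] = ()  # trailing per-epoch coefficients
    triggered: bool = False  # last update forced follow via the distance rule

    def __post_init__(self) -> None:
        if self.coefficient not in (0, 1):
            raise ValueError("coefficient must be 0 or 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch probability outside [0, 1]")


def blend_poses(lead_pose: PoseFrame, follow_pose: PoseFrame, w: float) -> PoseFrame:
    """Per-joint SLERP between the two network outputs with lead-weight *w*.

    ``w = 0`` returns the follow pose exactly; ``w = 1`` the lead pose.
    """
    if lead_pose.joints.names != follow_pose.joints.names:
        raise ValueError("poses must share a joint set")
    quats = slerp(follow_pose.quats, lead_pose.quats, np.full(len(lead_pose.joints), w))
    return PoseFrame(lead_pose.joints, quats)


def update_role(
    state: RoleState,
    elapsed: float,
    hand_dist: float,
    rng: np.random.Generator,
    config: ControllerConfig | None = None,
) -> RoleState:
    """Advance the role process to time *elapsed* (seconds, monotone).

    The distance trigger acts at any step: ``hand_dist`` above the threshold
    forces the coefficient to 0 immediately (the 4 s decision clock keeps
    running).  At each decision epoch the coefficient flips with the current
    switch probability; while following dominated the trailing window the
    probability of becoming leader grows by the bias increment, and it
    resets to the base value upon becoming leader.
    """
    config = config or ControllerConfig()
    triggered = hand_dist > config.distance_threshold
    if triggered and state.coefficient == 1:
        state = replace(state, coefficient=0)
    next_decision = state.next_decision
    coefficient = state.coefficient
    switch_prob = state.switch_prob
    history = state.epoch_history
    while elapsed >= next_decision:
        history = (history + (coefficient,))[-config.balance_epochs :]
        p = switch_prob if coefficient == 0 else config.base_switch_prob
        if rng.random() < p:
            coefficient = 1 - coefficient
            if coefficient == 1:
                switch_prob = config.base_switch_prob
        if config.balancing and coefficient == 0 and history and np.mean(history) < 0.5:
            switch_prob = min(1.0, switch_prob + config.bias_increment)
        next_decision += config.decision_period_s
    return RoleState(
        coefficient=coefficient,
        switch_prob=switch_prob,
        next_decision=next_decision,
        epoch_history=history,
        triggered=triggered,
    )


def run_agent(
    partner: MotionSequence | None,
    mode: str,
    follow_model: RecurrentRegressor,
    lead_sequence: MotionSequence,
    seed: int = 0,
    config: ControllerConfig | None = None,
    follow_config: FollowNetConfig | None = None,
    fk_config: FKConfig | None = None,
) -> tuple[MotionSequence, pd.DataFrame]:
    """Simulate the agent in one trial; returns its motion and a role trace.

    * ``follow`` — fixed ``w = 0.1`` against the partner.
    * ``lead`` — fixed ``w = 0.9`` replaying the pre-generated lead
      sequence, with the subtle follow component reacting to the partner.
    * ``improvise`` — ``w`` driven by the role process, ramping linearly
      over 1 s between 0.1 and 0.9 at role changes.

    The distance trigger is evaluated per frame on the 4 Hz-filtered partner
    hand track against the agent's own (previous-frame) forward-kinematics
    hand position.  Deterministic given *seed*.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if partner is None:
        raise ValueError("a partner sequence is required (all modes are reactive)")
    config = config or ControllerConfig()
    follow_config = follow_config or FollowNetConfig()
    fk_config = fk_config or FKConfig()
    follow_seq = run_follower(follow_model, partner.select_joints(follow_config.joints), follow_config)
    T = follow_seq.n_frames
    if lead_sequence.n_frames < T:
        raise ValueError("lead sequence shorter than the trial")
    lead_q = lead_sequence.select_joints(follow_config.joints).quats[:T]
    follow_q = follow_seq.quats
    rate = partner.rate
    dt = 1.0 / rate

    partner_hand = partner.hand_track
    if partner_hand is not None:
        partner_hand = filter_trajectory(partner_hand, rate)

    rng = np.random.default_rng(seed)
    state = RoleState(next_decision=config.decision_period_s)
    w_for = {0: config.follow_weight, 1: config.lead_weight}
    if mode == "follow":
        w = config.follow_weight
    elif mode == "lead":
        w = config.lead_weight
    else:
        w = w_for[state.coefficient]
    ramp_step = (config.lead_weight - config.follow_weight) / max(1, int(round(config.ramp_s * rate)))

    quats = np.empty_like(follow_q)
    rows = []
    prev_dist = 0.0
    joints = follow_config.joints
    for t in range(T):
        if mode == "improvise":
            state = update_role(state, t * dt, prev_dist, rng, config)
            target = w_for[state.coefficient]
            if w < target:
                w = min(target, w + ramp_step)
            elif w > target:
                w = max(target, w - ramp_step)
        pose_q = slerp(follow_q[t], lead_q[t], np.full(len(joints), w))
        quats[t] = pose_q
        frame = PoseFrame(joints, pose_q)
        hand = forward_kinematics_hand(frame, "left", fk_config)
        if partner_hand is not None:
            prev_dist = float(
                hand_distance(hand[None, :], partner_hand[t][None, :])[0]
            )
        rows.append(
            {
                "frame": t,
                "time_s": t * dt,
                "coefficient": state.coefficient if mode == "improvise" else (1 if mode == "lead" else 0),
                "w": w,
                "switch_prob": state.switch_prob,
                "triggered": state.triggered if mode == "improvise" else False,
                "hand_distance": prev_dist,
            }
        )
    out = with_fk_hand_track(MotionSequence(rate, joints, quats), "left", fk_config)
    return out, pd.DataFrame(rows)
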