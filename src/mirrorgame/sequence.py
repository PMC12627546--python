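"""Pose and motion-sequence containers plus the standard pre-processing moves.

A :class:`MotionSequence` stores per-frame joint orientations as one
``(T, J, 4)`` array of canonical unit quaternions over a declared
:class:`~mirrorgame.skeleton.JointSet`, along with an optional 3-D hand-position
track in scene units.  Sequences are sampled at a constant frame rate; the
package-wide canonical rate is 90 fps (the real-time rendering loop), and
lower-rate captures are resampled on load.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .quaternions import canonicalize, check_unit, from_axis_angle, rotate_vector, slerp
from .skeleton import ARM_CHAIN, JointSet

__all__ = [
    "PoseFrame",
    "MotionSequence",
    "FKConfig",
    "mirror_sequence",
    "mirror_pose",
    "resample",
    "forward_kinematics_hand",
    "hand_track_from_sequence",
    "CANONICAL_RATE",
]

CANONICAL_RATE = 90.0


@dataclass(frozen=True)
class PoseFrame:
    """Joint orientations of a single frame (canonical unit quaternions)."""

    joints: JointSet
    quats: np.ndarray  # (J, 4)
    index: int = 0

    def __post_init__(self) -> None:
        q = np.asarray(self.quats, dtype=float)
        if q.shape != (len(self.joints), 4):
            raise ValueError(
                f"expected quats of shape ({len(self.joints)}, 4), got {q.shape}"
            )
        check_unit(q, tol=1e-3)
        object.__setattr__(self, "quats", q)

    def orientation(self, joint: str) -> np.ndarray:
        return self.quats[self.joints.index(joint)]


@dataclass(frozen=True)
class MotionSequence:
    """Fixed-rate sequence of poses with an optional hand-position track."""

    rate: float
    joints: JointSet
    quats: np.ndarray  # (T, J, 4)
    hand_track: np.ndarray | None = None  # (T, 3) scene units

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("frame rate must be positive")
        q = np.asarray(self.quats, dtype=float)
        if q.ndim != 3 or q.shape[1] != len(self.joints) or q.shape[2] != 4:
            raise ValueError(f"expected quats of shape (T, {len(self.joints)}, 4)")
        if q.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        object.__setattr__(self, "quats", q)
        if self.hand_track is not None:
            h = np.asarray(self.hand_track, dtype=float)
            if h.shape != (q.shape[0], 3):
                raise ValueError("hand track must have shape (T, 3)")
            object.__setattr__(self, "hand_track", h)

    @property
    def n_frames(self) -> int:
        return self.quats.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def frame(self, i: int) -> PoseFrame:
        return PoseFrame(self.joints, self.quats[i], index=i)

    def joint_track(self, joint: str) -> np.ndarray:
        """(T, 4) orientation track of one joint."""
        return self.quats[:, self.joints.index(joint), :]

    def select_joints(self, joints: JointSet) -> "MotionSequence":
        idx = [self.joints.index(n) for n in joints.names]
        return MotionSequence(self.rate, joints, self.quats[:, idx, :], self.hand_track)


@dataclass(frozen=True)
class FKConfig:
    """Segment geometry for hand forward kinematics.

    The avatar has no published dimensions; defaults are plausible scene
    units — 0.20 shoulder offset from the sternum root, 0.30 upper arm,
    0.30 forearm — and are configurable.
    """

    root: tuple[float, float, float] = (0.0, 1.4, 0.0)
    shoulder_offset: float = 0.20
    upper_arm: float = 0.30
    forearm: float = 0.30

    def segments(self, side: str) -> np.ndarray:
        """Rest-pose segment vectors (T-pose, arms along the lateral x-axis)."""
        sign = -1.0 if side == "left" else 1.0
        return np.array(
            [
                [sign * self.shoulder_offset, 0.0, 0.0],
                [sign * self.upper_arm, 0.0, 0.0],
                [sign * self.forearm, 0.0, 0.0],
            ]
        )


def mirror_pose(quats: np.ndarray, joints: JointSet) -> np.ndarray:
    """Mirror one or more ``(..., J, 4)`` pose arrays across the x-axis.

    Left/right joints swap and each quaternion maps
    ``(w, x, y, z) -> (w, x, -y, -z)`` (re-canonicalized).
    """
    perm = joints.mirror_permutation()
    q = np.asarray(quats, dtype=float)[..., perm, :]
    q = q * np.array([1.0, 1.0, -1.0, -1.0])
    return canonicalize(q)


def mirror_sequence(seq: MotionSequence) -> MotionSequence:
    """Swap left and right sides of a sequence (an involution).

    Joint orientations follow the sign rule of :func:`mirror_pose`; the hand
    track, if any, is reflected across the x = 0 plane.
    """
    quats = mirror_pose(seq.quats, seq.joints)
    hand = None
    if seq.hand_track is not None:
        hand = seq.hand_track * np.array([-1.0, 1.0, 1.0])
    return MotionSequence(seq.rate, seq.joints, quats, hand)


def resample(seq: MotionSequence, target_rate: float) -> MotionSequence:
    """Resample to *target_rate* via per-joint SLERP between adjacent frames.

    The hand track is linearly interpolated.  Duration is preserved within
    one frame period.  Raises for a single-frame sequence when the rate
    actually changes.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == seq.rate:
        return seq
    if seq.n_frames < 2:
        raise ValueError("cannot resample a sequence with fewer than 2 frames")
    t_old = np.arange(seq.n_frames) / seq.rate
    n_new = int(round(t_old[-1] * target_rate)) + 1
    t_new = np.arange(n_new) / target_rate
    t_new = np.minimum(t_new, t_old[-1])

    idx = np.clip(np.searchsorted(t_old, t_new, side="right") - 1, 0, seq.n_frames - 2)
    frac = np.clip((t_new - t_old[idx]) * seq.rate, 0.0, 1.0)

    q1 = seq.quats[idx]  # (T', J, 4)
    q2 = seq.quats[idx + 1]
    quats = canonicalize(slerp(q1, q2, frac[:, None] * np.ones((1, len(seq.joints)))))

    hand = None
    if seq.hand_track is not None:
        h1 = seq.hand_track[idx]
        h2 = seq.hand_track[idx + 1]
        hand = h1 + frac[:, None] * (h2 - h1)
    return MotionSequence(target_rate, seq.joints, quats, hand)


def forward_kinematics_hand(
    frame: PoseFrame, side: str = "left", config: FKConfig | None = None
) -> np.ndarray:
    """Hand position from chaining shoulder, upper-arm and forearm rotations.

    Each segment's rest vector is rotated by the absolute orientation of its
    joint and the results accumulate from a fixed root: with all-identity
    orientations the hand sits at ``root + sum(segment vectors)``.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    config = config or FKConfig()
    segments = config.segments(side)
    chain = [f"{side}_{name}" for name in ARM_CHAIN[:3]]  # shoulder, upper, forearm
    missing = [j for j in chain if j not in frame.joints]
    if missing:
        raise ValueError(f"arm-chain joints missing: {missing}")
    pos = np.array(config.root, dtype=float)
    for joint, seg in zip(chain, segments):
        pos = pos + rotate_vector(frame.orientation(joint), seg)
    return pos


def hand_track_from_sequence(
    seq: MotionSequence, side: str = "left", config: FKConfig | None = None
) -> np.ndarray:
    """(T, 3) hand positions computed by forward kinematics over all frames."""
    config = config or FKConfig()
    segments = config.segments(side)
    chain = [f"{side}_{name}" for name in ARM_CHAIN[:3]]
    missing = [j for j in chain if j not in seq.joints]
    if missing:
        raise ValueError(f"arm-chain joints missing: {missing}")
    pos = np.tile(np.array(config.root, dtype=float), (seq.n_frames, 1))
    for joint, seg in zip(chain, segments):
        pos = pos + rotate_vector(seq.joint_track(joint), seg)
    return pos


def with_fk_hand_track(
    seq: MotionSequence, side: str = "left", config: FKConfig | None = None
) -> MotionSequence:
    """Return the sequence with its hand track recomputed by FK."""
    return replace(seq, hand_track=hand_track_from_sequence(seq, side, config))


def constant_sequence(
    joints: JointSet, pose: np.ndarray, n_frames: int, rate: float = CANONICAL_RATE
) -> MotionSequence:
    """A sequence holding one pose for *n_frames* (rest-pose helper)."""
    quats = np.tile(canonicalize(pose)[None, :, :], (n_frames, 1, 1))
    return MotionSequence(rate, joints, quats)


def identity_pose(joints: JointSet) -> np.ndarray:
    """(J, 4) all-identity pose."""
    q = np.zeros((len(joints), 4))
    q[:, 0] = 1.0
    return q


def axis_angle_pose(
    joints: JointSet, axes: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    """(J, 4) pose from per-joint axes (J, 3) and angles (J,)."""
    return canonicalize(from_axis_angle(axes, angles))
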