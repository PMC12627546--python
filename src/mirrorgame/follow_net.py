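"""The follow-net: reactive next-frame pose prediction from the partner's
recent motion.

The network sees the partner's last 120 frames subsampled at every fourth
frame (30 input frames, about 1.3 s at 90 fps), each frame flattened to the
4 quaternion components of the 10 model joints (40 features), and predicts
the agent's own joint orientations at the next frame.  Training uses
RMSprop, learning rate 1e-3, mean squared error on the canonical quaternion
components, 15 epochs; the raw output is renormalized per joint to canonical
unit quaternions only at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import RecurrentRegressor, fit
from .quaternions import canonicalize
from .sequence import MotionSequence, PoseFrame, mirror_sequence
from .skeleton import MODEL_JOINTS, JointSet
from .synthetic import DyadTrial

__all__ = [
    "FollowNetConfig",
    "make_windows",
    "train_follow",
    "predict_next_pose",
    "run_follower",
]


@dataclass(frozen=True)
class FollowNetConfig:
    """Architecture and training hyper-parameters of the follow-net."""

    history: int = 120  # frames of partner motion per window
    stride: int = 4  # every fourth frame enters the network
    joints: JointSet = MODEL_JOINTS
    hidden: int = 128
    dense_widths: tuple[int, ...] = (128, 64)
    epochs: int = 15
    learning_rate: float = 1e-3
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.history % self.stride != 0:
            raise ValueError("history must be divisible by stride")

    @property
    def input_frames(self) -> int:
        return self.history // self.stride

    @property
    def features(self) -> int:
        return 4 * len(self.joints)


def _flatten(quats: np.ndarray) -> np.ndarray:
    """(T, J, 4) -> (T, 4J) canonical component features."""
    return quats.reshape(quats.shape[0], -1)


def _window_input_indices(t: int, config: FollowNetConfig) -> np.ndarray:
    """Strided input frame indices for a window ending at frame ``t``."""
    return t - config.history + config.stride * np.arange(1, config.input_frames + 1)


def make_windows(
    leader: MotionSequence, follower: MotionSequence, config: FollowNetConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Training windows: partner history in, own next frame out.

    For every frame ``t`` with a full history behind it and a ``t + 1``
    target ahead, the input block is the leader's strided frames ending at
    ``t`` and the target is the follower's frame ``t + 1``.  Returns
    ``X (N, input_frames, 4J)`` and ``Y (N, 4J)`` with
    ``N = T - history - 1``.
    """
    if leader.rate != follower.rate or leader.n_frames != follower.n_frames:
        raise ValueError("leader and follower must be aligned")
    T = leader.n_frames
    if T < config.history + 2:
        raise ValueError(
            f"sequence too short: need at least {config.history + 2} frames, got {T}"
        )
    lead_q = _flatten(leader.select_joints(config.joints).quats)
    fol_q = _flatten(follower.select_joints(config.joints).quats)
    ts = np.arange(config.history, T - 1)
    idx = np.stack([_window_input_indices(t, config) for t in ts])  # (N, 30)
    X = lead_q[idx]  # (N, 30, 4J)
    Y = fol_q[ts + 1]
    return X, Y


def _training_pairs(trial: DyadTrial) -> tuple[MotionSequence, MotionSequence] | None:
    """Leader/follower pair of a trial, mirrored to the left side if needed."""
    if trial.condition == "improvise":
        return None
    leader, follower = trial.leader, trial.follower
    if trial.active_side == "right":
        leader = mirror_sequence(leader)
        follower = mirror_sequence(follower)
    return leader, follower


def train_follow(
    corpus: list[DyadTrial], config: FollowNetConfig, seed: int = 0
) -> tuple[RecurrentRegressor, list[float]]:
    """Train the follow-net on all lead/follow trials of a corpus.

    Right-arm-active trials are mirrored to the left so a single left-arm
    network serves both sides.  Returns the trained model and per-epoch
    training losses.  Reproducible given *seed*.
    """
    if not corpus:
        raise ValueError("empty corpus")
    Xs, Ys = [], []
    for trial in corpus:
        pair = _training_pairs(trial)
        if pair is None:
            continue
        X, Y = make_windows(*pair, config)
        Xs.append(X)
        Ys.append(Y)
    if not Xs:
        raise ValueError("corpus contains no lead/follow trials")
    X = np.concatenate(Xs)
    Y = np.concatenate(Ys)
    model = RecurrentRegressor(
        d_in=config.features,
        hidden=config.hidden,
        dense_widths=config.dense_widths,
        d_out=config.features,
        return_sequences=False,
        seed=seed,
    )
    result = fit(
        model,
        X,
        Y,
        epochs=config.epochs,
        lr=config.learning_rate,
        batch_size=config.batch_size,
        seed=seed,
    )
    return model, result.losses


def _renorm_output(raw: np.ndarray, joints: JointSet) -> np.ndarray:
    """Raw (..., 4J) network output -> canonical (..., J, 4) quaternions."""
    q = raw.reshape(raw.shape[:-1] + (len(joints), 4))
    return canonicalize(q)


def predict_next_pose(
    model: RecurrentRegressor, window: np.ndarray, joints: JointSet = MODEL_JOINTS
) -> PoseFrame:
    """Predict the next-frame pose from one input window.

    The raw 4J-vector is renormalized per joint to canonical unit
    quaternions.  Deterministic.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 4 * len(joints):
        raise ValueError(
            f"expected window of shape (input_frames, {4 * len(joints)}), got {window.shape}"
        )
    raw = model.predict(window[None])[0]
    return PoseFrame(joints, _renorm_output(raw, joints))


def run_follower(
    model: RecurrentRegressor,
    leader: MotionSequence,
    config: FollowNetConfig | None = None,
) -> MotionSequence:
    """Causal rollout of the follow-net against a leader sequence.

    Output frame ``t + 1`` is predicted from leader frames up to ``t``; the
    first ``history + 1`` frames hold a rest pose (the mirrored first leader
    frame).  Output length and rate equal the leader's.  Predictions do not
    feed back, so the rollout is causal by construction.
    """
    config = config or FollowNetConfig()
    sub = leader.select_joints(config.joints)
    T = sub.n_frames
    if T < config.history + 2:
        raise ValueError("leader shorter than one history window")
    lead_q = _flatten(sub.quats)
    ts = np.arange(config.history, T - 1)
    idx = np.stack([_window_input_indices(t, config) for t in ts])
    preds = model.predict(lead_q[idx])  # (N, 4J)
    quats = np.empty((T, len(config.joints), 4))
    rest = mirror_sequence(sub).quats[0]
    quats[: config.history + 1] = rest
    quats[ts + 1] = _renorm_output(preds, config.joints)
    return MotionSequence(leader.rate, config.joints, quats)
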