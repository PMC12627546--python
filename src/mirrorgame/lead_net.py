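"""The lead-net: open-loop motion synthesis by recursive chunk prediction.

Motion generation is cast as sequence-to-sequence prediction: the network
maps a chunk of motion to the next chunk, and its output is fed back as
input to generate arbitrarily long sequences.  With the default 10 s chunks
and 15 recursions this yields 150 s of motion, of which the first 120 s are
used.  Gaussian noise perturbs the inputs during training as regularization.

The model operates at the stride-4 subsampled rate (22.5 Hz at the canonical
90 fps); generated chunks are SLERP-upsampled back to the full rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import RecurrentRegressor, fit
from .quaternions import canonicalize, slerp
from .sequence import MotionSequence, resample, with_fk_hand_track
from .skeleton import MODEL_JOINTS, JointSet

__all__ = [
    "LeadNetConfig",
    "train_lead",
    "generate_sequence",
    "sample_seed_chunk",
]


@dataclass(frozen=True)
class LeadNetConfig:
    """Architecture, training and generation settings of the lead-net."""

    rate: float = 90.0
    stride: int = 4
    chunk_seconds: float = 10.0
    joints: JointSet = MODEL_JOINTS
    hidden: int = 128
    dense_widths: tuple[int, ...] = (64,)
    epochs: int = 15
    learning_rate: float = 1e-3
    batch_size: int = 16
    noise_sd: float = 0.01  # component-space Gaussian input noise, training only
    recursions: int = 15
    used_seconds: float = 120.0

    @property
    def model_rate(self) -> float:
        return self.rate / self.stride

    @property
    def chunk_frames(self) -> int:
        return int(round(self.chunk_seconds * self.model_rate))

    @property
    def generated_seconds(self) -> float:
        """Total generated duration: recursions x chunk length."""
        return self.recursions * self.chunk_seconds

    @property
    def features(self) -> int:
        return 4 * len(self.joints)

    def __post_init__(self) -> None:
        if self.chunk_frames < 2:
            raise ValueError("chunk shorter than 2 model frames")
        if self.used_seconds > self.generated_seconds:
            raise ValueError("used length exceeds generated length")


def _subsample_features(seq: MotionSequence, config: LeadNetConfig) -> np.ndarray:
    """(N, 4J) canonical component features at the model's strided rate."""
    sub = seq.select_joints(config.joints)
    q = sub.quats[:: config.stride]
    return q.reshape(q.shape[0], -1)


def _chunk_pairs(feats: np.ndarray, config: LeadNetConfig) -> tuple[np.ndarray, np.ndarray]:
    """Teacher-forced pairs: per-step target is the frame one chunk ahead."""
    C = config.chunk_frames
    n = feats.shape[0]
    starts = np.arange(0, n - 2 * C + 1, max(1, C // 2))
    X = np.stack([feats[s : s + C] for s in starts])
    Y = np.stack([feats[s + C : s + 2 * C] for s in starts])
    return X, Y


def train_lead(
    corpus: list[MotionSequence], config: LeadNetConfig, seed: int = 0
) -> tuple[RecurrentRegressor, list[float]]:
    """Train the chunk-to-chunk generator on leader sequences.

    Only joint orientations enter training (hand tracks are ignored).
    Inputs are perturbed by ``N(0, noise_sd)`` during training only.
    Returns the model and per-epoch training losses; reproducible given
    *seed*.
    """
    if not corpus:
        raise ValueError("empty corpus")
    Xs, Ys = [], []
    for seq in corpus:
        feats = _subsample_features(seq, config)
        if feats.shape[0] < 2 * config.chunk_frames:
            raise ValueError("sequence shorter than two chunks")
        X, Y = _chunk_pairs(feats, config)
        Xs.append(X)
        Ys.append(Y)
    X = np.concatenate(Xs)
    Y = np.concatenate(Ys)
    model = RecurrentRegressor(
        d_in=config.features,
        hidden=config.hidden,
        dense_widths=config.dense_widths,
        d_out=config.features,
        return_sequences=True,
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
        input_noise_sd=config.noise_sd,
    )
    return model, result.losses


def _renorm_chunk(raw: np.ndarray, joints: JointSet) -> np.ndarray:
    """(C, 4J) raw output -> canonical unit quaternion features."""
    q = canonicalize(raw.reshape(raw.shape[0], len(joints), 4))
    return q.reshape(raw.shape[0], -1)


def sample_seed_chunk(
    corpus: list[MotionSequence], config: LeadNetConfig, seed: int = 0
) -> np.ndarray:
    """Randomly sampled starting chunk from the training data (seeded)."""
    rng = np.random.default_rng(seed)
    seq = corpus[rng.integers(len(corpus))]
    feats = _subsample_features(seq, config)
    C = config.chunk_frames
    if feats.shape[0] < C:
        raise ValueError("sequence shorter than one chunk")
    start = int(rng.integers(0, feats.shape[0] - C + 1))
    return feats[start : start + C]


def generate_sequence(
    model: RecurrentRegressor,
    seed_chunk: np.ndarray,
    config: LeadNetConfig,
) -> MotionSequence:
    """Open-loop generation: recursive chunk prediction.

    The seed chunk is mapped to the next chunk, which is fed back as input;
    after ``recursions`` passes the concatenated output spans
    ``generated_seconds``, of which the first ``used_seconds`` are returned,
    SLERP-upsampled to the full frame rate with the hand track recomputed by
    forward kinematics.  Outputs are renormalized to canonical unit
    quaternions after every pass, so norm drift cannot accumulate.
    Deterministic given model and seed chunk.
    """
    seed_chunk = np.asarray(seed_chunk, dtype=float)
    if seed_chunk.shape != (config.chunk_frames, config.features):
        raise ValueError(
            f"seed chunk must have shape ({config.chunk_frames}, {config.features})"
        )
    chunks = []
    current = seed_chunk
    for _ in range(config.recursions):
        raw = model.predict(current[None])[0]
        current = _renorm_chunk(raw, config.joints)
        chunks.append(current)
    feats = np.concatenate(chunks)
    used = int(round(config.used_seconds * config.model_rate))
    feats = feats[:used]
    quats = feats.reshape(feats.shape[0], len(config.joints), 4)
    # Independently predicted chunks meet with a small pose jump; ease each
    # seam with a short spherical crossfade so the avatar never teleports.
    blend = max(2, int(round(1.0 * config.model_rate)))
    C = config.chunk_frames
    J = len(config.joints)
    for m in range(C, quats.shape[0], C):
        stop = min(m + blend, quats.shape[0])
        k = stop - m
        wts = np.repeat(((np.arange(k) + 1.0) / (k + 1.0))[:, None], J, axis=1)
        quats[m:stop] = slerp(
            np.broadcast_to(quats[m - 1], (k, J, 4)), quats[m:stop], wts
        )
    seq = MotionSequence(config.model_rate, config.joints, quats)
    seq = resample(seq, config.rate)
    return with_fk_hand_track(seq)
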