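"""Seeded synthetic dyads: smooth leaders, delayed-and-noised followers,
improvisation trials with known role blocks, and balanced decision tables.

Every generator is deterministic given its seed.  Leader joints follow
band-limited sums of sinusoids in axis-angle space (all spectral content well
below the 4 Hz analysis cutoff); followers are delayed copies with optional
geodesic jitter, so downstream lag and role statistics have exact ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .quaternions import canonicalize, from_axis_angle, qmul, slerp
from .sequence import (
    CANONICAL_RATE,
    MotionSequence,
    hand_track_from_sequence,
)
from .skeleton import MODEL_JOINTS, JointSet

__all__ = [
    "SynthesisConfig",
    "DyadTrial",
    "splitmix64",
    "generate_leader",
    "derive_follower",
    "generate_dyad_corpus",
    "generate_turing_table",
]

#: Joints driven with full amplitude (the active arm); the rest move subtly.
_ACTIVE_PREFIX = "left_"
_SUBTLE_SCALE = 0.15

CONDITIONS = ("lead", "follow", "improvise")


def splitmix64(seed: int, index: int = 0) -> int:
    """Stateless integer hash deriving per-trial seeds from a master seed.

    SplitMix64 finalizer over ``seed + index``; reproducible across
    platforms.  The result is reduced below 2**31 for use with numpy.
    """
    z = (int(seed) + 0x9E3779B97F4A7C15 * (int(index) + 1)) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) % (2**31)


@dataclass(frozen=True)
class SynthesisConfig:
    """Conditions of the synthetic mirror-game world.

    Frequencies stay within ``(0, rate/8]`` so generated motion is
    band-limited far below the 4 Hz low-pass used by the analysis pipeline.
    """

    seed: int = 0
    rate: float = CANONICAL_RATE
    joints: JointSet = MODEL_JOINTS
    n_harmonics: tuple[int, int] = (2, 3)
    freq_band: tuple[float, float] = (0.2, 1.0)  # Hz; slow mirror-game sweeps
    amp_band: tuple[float, float] = (0.15, 0.6)  # radians, per joint total
    lag: int = 20  # frames
    follower_noise: float = 0.02  # radians geodesic jitter s.d.
    improvise_block_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_band[0] <= self.freq_band[1] <= self.rate / 8.0):
            raise ValueError("frequency band must lie within (0, rate/8]")
        if self.amp_band[0] < 0 or self.amp_band[1] < self.amp_band[0]:
            raise ValueError("invalid amplitude band")


@dataclass(frozen=True)
class DyadTrial:
    """Two synchronized sequences with roles and synthetic ground truth.

    ``condition`` is the role of player1 (``lead``: player1 leads).  ``lag``
    is the generative delay in frames (synthetic trials only).  For
    improvisation trials ``role_blocks`` lists ``(start_frame, leader)``
    pairs and ``lead_fraction_p1`` the ground-truth fraction of frames in
    which player1 led.
    """

    player1: MotionSequence
    player2: MotionSequence
    condition: str
    partner_type: str = "human"
    lag: int | None = None
    seed: int = 0
    active_side: str = "left"
    role_blocks: tuple[tuple[int, str], ...] | None = None
    lead_fraction_p1: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.partner_type not in ("human", "artificial"):
            raise ValueError("partner type must be 'human' or 'artificial'")
        if self.player1.rate != self.player2.rate:
            raise ValueError("players must share a frame rate")
        if self.player1.n_frames != self.player2.n_frames:
            raise ValueError("players must share a frame count")

    @property
    def leader(self) -> MotionSequence:
        return self.player1 if self.condition == "lead" else self.player2

    @property
    def follower(self) -> MotionSequence:
        return self.player2 if self.condition == "lead" else self.player1


def generate_leader(config: SynthesisConfig, duration: float) -> MotionSequence:
    """Smooth band-limited leader motion from seeded sinusoid mixtures.

    Each joint rotates about a fixed random axis with angle
    ``sum_k A_k sin(2 pi f_k t + phi_k)`` (2–3 harmonics inside the
    configured bands).  The active arm uses the full amplitude band; torso
    and head joints move at a fraction of it.  The hand track comes from
    forward kinematics of the active arm.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(config.seed)
    T = int(round(duration * config.rate))
    t = np.arange(T) / config.rate
    J = len(config.joints)
    angles = np.zeros((T, J))
    axes = np.zeros((J, 3))
    for j, name in enumerate(config.joints.names):
        axis = rng.normal(size=3)
        axes[j] = axis / np.linalg.norm(axis)
        k = rng.integers(config.n_harmonics[0], config.n_harmonics[1] + 1)
        total_amp = rng.uniform(*config.amp_band)
        if not name.startswith(_ACTIVE_PREFIX):
            total_amp *= _SUBTLE_SCALE
        amps = rng.dirichlet(np.ones(k)) * total_amp
        freqs = rng.uniform(*config.freq_band, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
        angles[:, j] = np.sum(
            amps * np.sin(2 * np.pi * freqs * t[:, None] + phases), axis=1
        )
    quats = canonicalize(from_axis_angle(np.broadcast_to(axes, (T, J, 3)), angles))
    seq = MotionSequence(config.rate, config.joints, quats)
    return replace_hand(seq)


def replace_hand(seq: MotionSequence, side: str = "left") -> MotionSequence:
    return replace(seq, hand_track=hand_track_from_sequence(seq, side))


def _geodesic_jitter(
    quats: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Left-multiply each quaternion by a random rotation whose geodesic
    magnitude is ``|N(0, noise)|`` (rotation angle twice that)."""
    if noise <= 0:
        return quats
    shape = quats.shape[:-1]
    axes = rng.normal(size=shape + (3,))
    axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
    geo = np.abs(rng.normal(0.0, noise, size=shape))
    perturb = from_axis_angle(axes, 2.0 * geo)
    return canonicalize(qmul(perturb, quats))


def derive_follower(
    leader: MotionSequence,
    lag: int,
    noise: float = 0.0,
    seed: int = 0,
) -> MotionSequence:
    """Delayed copy of the leader with geodesic orientation jitter.

    ``follower(t) = leader(t - lag)``; the first *lag* frames hold the
    leader's initial pose.  Each joint is perturbed by a random rotation of
    geodesic magnitude ``|N(0, noise)|`` radians.  The hand track is
    recomputed by forward kinematics from the perturbed orientations.
    """
    if not 0 <= lag < leader.n_frames:
        raise ValueError("lag must satisfy 0 <= lag < sequence length")
    idx = np.maximum(np.arange(leader.n_frames) - lag, 0)
    quats = leader.quats[idx]
    rng = np.random.default_rng(seed)
    quats = _geodesic_jitter(quats, noise, rng)
    seq = MotionSequence(leader.rate, leader.joints, quats)
    return replace_hand(seq)


def _improvise_pair(
    config: SynthesisConfig, duration: float, seed: int
) -> tuple[MotionSequence, MotionSequence, tuple[tuple[int, str], ...], float]:
    """Two players alternating lead/follow in fixed blocks with known lags.

    Each player has a full-length "own" trace (their generated leader motion)
    and a full-length "follow" trace (the partner's motion delayed and
    jittered).  The final trace SLERPs between the two with a weight that
    switches per block and ramps over half a second, so role changes are
    smooth and leave no speed artifacts at block boundaries.
    """
    base1 = generate_leader(replace(config, seed=splitmix64(seed, 1)), duration)
    base2 = generate_leader(replace(config, seed=splitmix64(seed, 2)), duration)
    T = base1.n_frames
    block = max(1, int(round(config.improvise_block_s * config.rate)))
    rng = np.random.default_rng(splitmix64(seed, 3))
    idx = np.maximum(np.arange(T) - config.lag, 0)
    follow1 = _geodesic_jitter(base2.quats[idx], config.follower_noise, rng)
    follow2 = _geodesic_jitter(base1.quats[idx], config.follower_noise, rng)

    blocks: list[tuple[int, str]] = []
    leader = "player1" if rng.random() < 0.5 else "player2"
    lead1 = np.zeros(T)  # 1 where player1 leads
    lead1_frames = 0
    for start in range(0, T, block):
        stop = min(start + block, T)
        blocks.append((start, leader))
        if leader == "player1":
            lead1[start:stop] = 1.0
            lead1_frames += stop - start
        leader = "player2" if leader == "player1" else "player1"
    ramp = max(1, int(round(0.5 * config.rate)))
    kernel = np.ones(ramp) / ramp
    w1 = np.clip(np.convolve(lead1, kernel, mode="same"), 0.0, 1.0)

    J = len(config.joints)
    q1 = slerp(follow1, base1.quats, np.repeat(w1[:, None], J, axis=1))
    q2 = slerp(base2.quats, follow2, np.repeat(w1[:, None], J, axis=1))
    p1 = replace_hand(MotionSequence(config.rate, config.joints, canonicalize(q1)))
    p2 = replace_hand(MotionSequence(config.rate, config.joints, canonicalize(q2)))
    return p1, p2, tuple(blocks), lead1_frames / T


def generate_dyad_corpus(
    config: SynthesisConfig,
    n_trials: int,
    conditions: tuple[str, ...] = CONDITIONS,
    duration: float = 30.0,
    partner_type: str = "human",
) -> list[DyadTrial]:
    """Round-robin corpus of dyad trials with per-trial derived seeds.

    Lead/follow trials pair a generated leader with its delayed follower;
    improvisation trials alternate ground-truth roles in fixed blocks.  The
    whole corpus is bit-reproducible from the master seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not conditions:
        raise ValueError("conditions must be non-empty")
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")
    trials = []
    for i in range(n_trials):
        condition = conditions[i % len(conditions)]
        trial_seed = splitmix64(config.seed, 1000 + i)
        if condition == "improvise":
            p1, p2, blocks, frac = _improvise_pair(config, duration, trial_seed)
            trials.append(
                DyadTrial(
                    player1=p1,
                    player2=p2,
                    condition=condition,
                    partner_type=partner_type,
                    lag=config.lag,
                    seed=trial_seed,
                    role_blocks=blocks,
                    lead_fraction_p1=frac,
                )
            )
        else:
            leader = generate_leader(
                replace(config, seed=splitmix64(trial_seed, 1)), duration
            )
            follower = derive_follower(
                leader, config.lag, config.follower_noise, seed=splitmix64(trial_seed, 2)
            )
            if condition == "lead":
                p1, p2 = leader, follower
            else:
                p1, p2 = follower, leader
            trials.append(
                DyadTrial(
                    player1=p1,
                    player2=p2,
                    condition=condition,
                    partner_type=partner_type,
                    lag=config.lag,
                    seed=trial_seed,
                )
            )
    return trials


def generate_turing_table(
    n: int,
    guesser: str | float = "random",
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced forced-choice decision table for confusion-rate tests.

    ``n`` must be even: ``n/2`` trials have true partner type artificial
    (``s = 1``) and ``n/2`` human (``s = 0``), shuffled.  The guess policy is
    ``"oracle"`` (always right), ``"inverted"`` (always wrong), ``"random"``
    (uniform), or a float ``p`` giving the probability of guessing
    *artificial* regardless of the truth.
    """
    if n % 2 != 0:
        raise ValueError("n must be even for a balanced table")
    rng = np.random.default_rng(seed)
    s = np.concatenate([np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)])
    rng.shuffle(s)
    if guesser == "oracle":
        s_tilde = s.copy()
    elif guesser == "inverted":
        s_tilde = 1 - s
    elif guesser == "random":
        s_tilde = rng.integers(0, 2, size=n)
    elif isinstance(guesser, (int, float)) and not isinstance(guesser, bool):
        p = float(guesser)
        if not 0.0 <= p <= 1.0:
            raise ValueError("biased guesser probability must lie in [0, 1]")
        s_tilde = (rng.random(n) < p).astype(int)
    else:
        raise ValueError(f"unknown guesser policy {guesser!r}")
    conditions = np.array([CONDITIONS[i % 3] for i in range(n)])
    duration_class = np.array(["long" if i % 3 < 2 else "short" for i in range(n)])
    return pd.DataFrame(
        {
            "s": s,
            "s_tilde": s_tilde,
            "epsilon": np.abs(s - s_tilde),
            "condition": conditions,
            "duration_class": duration_class,
            "confidence": rng.random(n),
        }
    )
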