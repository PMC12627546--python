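"""Per-trial motion parameters: filtering, speed, acceleration and hand
distance.

Hand-position jitter is removed with a zero-phase 4 Hz low-pass (order-4
Butterworth, forward-backward).  Velocity is the per-frame displacement
vector between successive samples; analyses use its norm (speed, scene
units/frame).  Acceleration is the per-frame difference of velocity vectors.
Trial summaries are the means over the defined samples, the absolute
between-player differences of those means, and the mean inter-hand distance
``d(t)`` computed on the horizontal-plane (x, y) components by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import DyadTrial

__all__ = [
    "TrajectoryKinematics",
    "DyadKinematics",
    "filter_trajectory",
    "speed_profile",
    "dyad_kinematics",
    "trial_kinematics",
    "hand_distance",
]

CUTOFF_HZ = 4.0
FILTER_ORDER = 4


@dataclass(frozen=True)
class TrajectoryKinematics:
    """Speed/acceleration series and trial means of one hand trajectory."""

    velocity: np.ndarray  # (T-1, 3) scene units / frame
    speed: np.ndarray  # (T-1,)
    acceleration: np.ndarray  # (T-2, 3)
    accel_norm: np.ndarray  # (T-2,)
    v_bar: float
    a_bar: float
    n_frames: int


@dataclass(frozen=True)
class DyadKinematics:
    """Between-player kinematic summary; symmetric in player order."""

    delta_v_bar: float
    delta_a_bar: float
    distance: np.ndarray  # d(t), (T,)
    d_bar: float
    player1: TrajectoryKinematics
    player2: TrajectoryKinematics


def filter_trajectory(track: np.ndarray, rate: float, cutoff: float = CUTOFF_HZ) -> np.ndarray:
    """Zero-phase low-pass of a (T, 3) position track.

    Order-4 Butterworth applied forward and backward (`filtfilt`), so the
    effective magnitude response is the squared filter and the phase is
    zero.  Constant signals pass unchanged; length is preserved.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim == 1:
        track = track[:, None]
    b, a = signal.butter(FILTER_ORDER, cutoff, fs=rate)
    padlen = 3 * max(len(a), len(b))
    if track.shape[0] <= padlen:
        raise ValueError(f"track too short to filter: need > {padlen} samples")
    return signal.filtfilt(b, a, track, axis=0)


def speed_profile(track: np.ndarray) -> TrajectoryKinematics:
    """Displacement-based speed and acceleration series with trial means.

    ``v(t)`` is the displacement between successive frames (units/frame;
    the printed sign convention does not affect the norms used downstream),
    ``a(t)`` the difference of successive velocity vectors.  Means are taken
    over the defined samples (T-1 speeds, T-2 accelerations).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim == 1:
        track = track[:, None]
    T = track.shape[0]
    if T < 3:
        raise ValueError("need at least 3 frames for speed and acceleration")
    velocity = np.diff(track, axis=0)
    speed = np.linalg.norm(velocity, axis=1)
    acceleration = np.diff(velocity, axis=0)
    accel_norm = np.linalg.norm(acceleration, axis=1)
    return TrajectoryKinematics(
        velocity=velocity,
        speed=speed,
        acceleration=acceleration,
        accel_norm=accel_norm,
        v_bar=float(speed.mean()),
        a_bar=float(accel_norm.mean()),
        n_frames=T,
    )


def hand_distance(track1: np.ndarray, track2: np.ndarray, use_3d: bool = False) -> np.ndarray:
    """Inter-hand distance ``d(t)``.

    By default only the (x, y) components enter, matching the analysis
    convention; set ``use_3d`` for the full Euclidean distance.
    """
    track1 = np.asarray(track1, dtype=float)
    track2 = np.asarray(track2, dtype=float)
    if track1.shape != track2.shape:
        raise ValueError("tracks must have equal shapes")
    diff = track1 - track2
    if not use_3d:
        diff = diff[:, :2]
    return np.linalg.norm(diff, axis=1)


def dyad_kinematics(
    track1: np.ndarray, track2: np.ndarray, use_3d_distance: bool = False
) -> DyadKinematics:
    """Between-player kinematics of two aligned (filtered) hand tracks."""
    k1 = speed_profile(track1)
    k2 = speed_profile(track2)
    d = hand_distance(track1, track2, use_3d=use_3d_distance)
    return DyadKinematics(
        delta_v_bar=abs(k1.v_bar - k2.v_bar),
        delta_a_bar=abs(k1.a_bar - k2.a_bar),
        distance=d,
        d_bar=float(d.mean()),
        player1=k1,
        player2=k2,
    )


def trial_kinematics(trial: DyadTrial, use_3d_distance: bool = False) -> DyadKinematics:
    """Filter both players' hand tracks at 4 Hz, then summarize the dyad."""
    if trial.player1.hand_track is None or trial.player2.hand_track is None:
        raise ValueError("trial players need hand tracks")
    rate = trial.player1.rate
    t1 = filter_trajectory(trial.player1.hand_track, rate)
    t2 = filter_trajectory(trial.player2.hand_track, rate)
    return dyad_kinematics(t1, t2, use_3d_distance=use_3d_distance)
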