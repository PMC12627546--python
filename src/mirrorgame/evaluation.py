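"""Turing-test confusion metrics and follow-net joint-sensitivity analysis.

The forced-choice decision error is ``epsilon = |s - s_tilde|`` with true
partner type ``s`` (0 human, 1 artificial).  The false negative rate (FNR)
is the mean error over true-artificial trials (how often the artificial
agent passed as human), the false positive rate (FPR) the mean error over
true-human trials; chance level for both is 50%.

The sensitivity analysis probes what the follow-net learned: one leader
joint is frozen to a replacement pose across the whole input window, and the
mean geodesic displacement of each output (follower) joint measures how
strongly that input joint drives it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .follow_net import FollowNetConfig, _renorm_output
from .nn import RecurrentRegressor
from .quaternions import geodesic_distance
from .skeleton import FOCAL_ARM_JOINTS, MODEL_JOINTS, JointSet

__all__ = [
    "ConfusionSummary",
    "confusion_rates",
    "perturbed_prediction_distance",
    "SensitivityMatrix",
    "sensitivity_matrix",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Error rates in percent; a rate with no trials of its class is NaN."""

    fnr: float
    fpr: float
    accuracy: float
    n_hri: int
    n_hhi: int


def _summary(df: pd.DataFrame) -> ConfusionSummary:
    eps = np.abs(df["s"].to_numpy() - df["s_tilde"].to_numpy())
    art = df["s"].to_numpy() == 1
    n_hri = int(art.sum())
    n_hhi = int((~art).sum())
    fnr = float(eps[art].mean() * 100.0) if n_hri else float("nan")
    fpr = float(eps[~art].mean() * 100.0) if n_hhi else float("nan")
    accuracy = float((1.0 - eps.mean()) * 100.0) if len(df) else float("nan")
    return ConfusionSummary(fnr=fnr, fpr=fpr, accuracy=accuracy, n_hri=n_hri, n_hhi=n_hhi)


def confusion_rates(
    decisions: pd.DataFrame, by: str | None = None
) -> dict[str, ConfusionSummary]:
    """FNR/FPR/accuracy per stratum (percent).

    ``decisions`` needs columns ``s`` and ``s_tilde``; ``by`` may name a
    stratification column (e.g. ``condition`` or ``duration_class``).
    Without it a single ``overall`` stratum is returned.
    """
    if decisions.empty:
        raise ValueError("empty decision table")
    if by is None:
        return {"overall": _summary(decisions)}
    if by not in decisions.columns:
        raise ValueError(f"no column {by!r} in decision table")
    return {str(key): _summary(sub) for key, sub in decisions.groupby(by, sort=True)}


def _joint_slice(joints: JointSet, name: str) -> slice:
    j = joints.index(name)
    return slice(4 * j, 4 * j + 4)


def perturbed_prediction_distance(
    model: RecurrentRegressor,
    windows: np.ndarray,
    perturbed_joint: str,
    replacements: np.ndarray,
    follower_joint: str,
    joints: JointSet = MODEL_JOINTS,
) -> float:
    """Mean geodesic output displacement after freezing one input joint.

    For every window, the chosen leader joint is frozen to the paired
    replacement orientation across all input frames; the return value is the
    mean geodesic distance between the follower joint's predictions on the
    original and perturbed windows.

    ``windows``: (N, input_frames, 4J); ``replacements``: (N, 4) or (4,)
    canonical unit quaternions.
    """
    windows = np.asarray(windows, dtype=float)
    replacements = np.asarray(replacements, dtype=float)
    if replacements.ndim == 1:
        replacements = np.tile(replacements, (windows.shape[0], 1))
    if perturbed_joint not in joints or follower_joint not in joints:
        raise ValueError("joint not in the model joint set")
    sl = _joint_slice(joints, perturbed_joint)
    perturbed = windows.copy()
    perturbed[:, :, sl] = replacements[:, None, :]
    base = _renorm_output(model.predict(windows), joints)
    pert = _renorm_output(model.predict(perturbed), joints)
    jf = joints.index(follower_joint)
    return float(np.mean(geodesic_distance(base[:, jf], pert[:, jf])))


@dataclass(frozen=True)
class SensitivityMatrix:
    """Leader-joint x follower-joint mean geodesic output displacement."""

    values: np.ndarray  # (rows, cols) radians
    leader_joints: tuple[str, ...]
    follower_joints: tuple[str, ...]
    n_sequences: int
    n_replacements: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.leader_joints), columns=list(self.follower_joints)
        )


def sensitivity_matrix(
    model: RecurrentRegressor,
    windows: np.ndarray,
    n_sequences: int = 100,
    n_replacements: int = 10,
    seed: int = 0,
    leader_joints: tuple[str, ...] = FOCAL_ARM_JOINTS,
    follower_joints: tuple[str, ...] = FOCAL_ARM_JOINTS,
    joints: JointSet = MODEL_JOINTS,
    config: FollowNetConfig | None = None,
) -> SensitivityMatrix:
    """Full perturbation grid over leader and follower joints.

    ``n_sequences`` input windows are sampled from the corpus; each is
    perturbed ``n_replacements`` times per leader joint, with replacement
    orientations drawn from the same joint in *other* windows of the corpus
    (a constant frozen pose per perturbed window).  Cells are means over
    windows and replacements; all sampling is seeded.
    """
    windows = np.asarray(windows, dtype=float)
    N = windows.shape[0]
    if N < n_sequences:
        raise ValueError(f"corpus has {N} windows, need at least {n_sequences}")
    rng = np.random.default_rng(seed)
    sel = rng.choice(N, size=n_sequences, replace=False)
    sample = windows[sel]
    base = _renorm_output(model.predict(sample), joints)
    col_idx = [joints.index(fj) for fj in follower_joints]
    values = np.zeros((len(leader_joints), len(follower_joints)))
    for r, lj in enumerate(leader_joints):
        sl = _joint_slice(joints, lj)
        acc = np.zeros(len(follower_joints))
        for _ in range(n_replacements):
            src_win = rng.integers(0, N, size=n_sequences)
            src_frame = rng.integers(0, windows.shape[1], size=n_sequences)
            repl = windows[src_win, src_frame, sl]
            perturbed = sample.copy()
            perturbed[:, :, sl] = repl[:, None, :]
            pert = _renorm_output(model.predict(perturbed), joints)
            for c, jf in enumerate(col_idx):
                acc[c] += float(np.mean(geodesic_distance(base[:, jf], pert[:, jf])))
        values[r] = acc / n_replacements
    return SensitivityMatrix(
        values=values,
        leader_joints=tuple(leader_joints),
        follower_joints=tuple(follower_joints),
        n_sequences=n_sequences,
        n_replacements=n_replacements,
    )
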