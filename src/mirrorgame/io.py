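"""Reading and writing motion files, corpora and trial manifests.

Two on-disk forms share one schema:

* a delimited text table — one row per frame, columns ``frame``, then per
  joint ``<joint>_w, <joint>_x, <joint>_y, <joint>_z``, optionally
  ``hand_x, hand_y, hand_z`` — with a YAML sidecar (``<file>.meta``) holding
  the frame rate, joint names and units;
* an HDF5 container mirroring the same fields for whole corpora.

Readers reject NaNs and rows whose quaternion norm deviates from 1 by more
than 1e-3, and renormalize smaller deviations.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .quaternions import canonicalize
from .sequence import MotionSequence
from .skeleton import JointSet

__all__ = [
    "write_motion_csv",
    "read_motion_csv",
    "save_corpus_h5",
    "load_corpus_h5",
    "write_manifest",
    "read_manifest",
]

_NORM_TOL = 1e-3


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def write_motion_csv(seq: MotionSequence, path: str | Path, sep: str = ",") -> None:
    path = Path(path)
    cols: dict[str, np.ndarray] = {"frame": np.arange(seq.n_frames)}
    for j, name in enumerate(seq.joints.names):
        for k, comp in enumerate("wxyz"):
            cols[f"{name}_{comp}"] = seq.quats[:, j, k]
    if seq.hand_track is not None:
        for k, comp in enumerate("xyz"):
            cols[f"hand_{comp}"] = seq.hand_track[:, k]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
    meta = {
        "rate": float(seq.rate),
        "joints": list(seq.joints.names),
        "units": "scene",
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def _validate_quats(quats: np.ndarray, where: str) -> np.ndarray:
    if not np.all(np.isfinite(quats)):
        raise ValueError(f"{where}: NaN or infinite quaternion components")
    norms = np.linalg.norm(quats, axis=-1)
    if np.any(np.abs(norms - 1.0) > _NORM_TOL):
        raise ValueError(f"{where}: quaternion norm deviates from 1 by more than {_NORM_TOL}")
    return canonicalize(quats)


def read_motion_csv(path: str | Path, sep: str = ",") -> MotionSequence:
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    joints = JointSet(tuple(meta["joints"]))
    df = pd.read_csv(path, sep=sep)
    T = len(df)
    quats = np.empty((T, len(joints), 4))
    for j, name in enumerate(joints.names):
        for k, comp in enumerate("wxyz"):
            quats[:, j, k] = df[f"{name}_{comp}"].to_numpy()
    quats = _validate_quats(quats, str(path))
    hand = None
    if "hand_x" in df.columns:
        hand = df[["hand_x", "hand_y", "hand_z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(hand)):
            raise ValueError(f"{path}: NaN in hand track")
    return MotionSequence(float(meta["rate"]), joints, quats, hand)


def save_corpus_h5(trials, path: str | Path) -> None:
    """Save a list of dyad trials (see :mod:`mirrorgame.synthetic`) to HDF5."""
    with h5py.File(Path(path), "w") as f:
        for i, trial in enumerate(trials):
            g = f.create_group(f"trial_{i:04d}")
            g.attrs["condition"] = trial.condition
            g.attrs["partner_type"] = trial.partner_type
            g.attrs["lag"] = -1 if trial.lag is None else int(trial.lag)
            g.attrs["seed"] = int(trial.seed)
            g.attrs["rate"] = float(trial.player1.rate)
            g.attrs["joints"] = ",".join(trial.player1.joints.names)
            for tag, seq in (("player1", trial.player1), ("player2", trial.player2)):
                sg = g.create_group(tag)
                sg.create_dataset("quats", data=seq.quats)
                if seq.hand_track is not None:
                    sg.create_dataset("hand", data=seq.hand_track)


def load_corpus_h5(path: str | Path):
    from .synthetic import DyadTrial  # deferred: avoids an import cycle

    trials = []
    with h5py.File(Path(path), "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            joints = JointSet(tuple(str(g.attrs["joints"]).split(",")))
            rate = float(g.attrs["rate"])
            seqs = {}
            for tag in ("player1", "player2"):
                quats = _validate_quats(np.asarray(g[tag]["quats"]), f"{path}:{key}/{tag}")
                hand = np.asarray(g[tag]["hand"]) if "hand" in g[tag] else None
                seqs[tag] = MotionSequence(rate, joints, quats, hand)
            lag = int(g.attrs["lag"])
            trials.append(
                DyadTrial(
                    player1=seqs["player1"],
                    player2=seqs["player2"],
                    condition=str(g.attrs["condition"]),
                    partner_type=str(g.attrs["partner_type"]),
                    lag=None if lag < 0 else lag,
                    seed=int(g.attrs["seed"]),
                )
            )
    return trials


def write_manifest(trials, path: str | Path) -> pd.DataFrame:
    """Trial manifest table: id, condition, partner type, lag, seed, duration."""
    rows = [
        {
            "trial": i,
            "condition": t.condition,
            "partner_type": t.partner_type,
            "lag": -1 if t.lag is None else t.lag,
            "seed": t.seed,
            "duration_s": t.player1.duration,
        }
        for i, t in enumerate(trials)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
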