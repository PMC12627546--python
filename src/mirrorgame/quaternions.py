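"""Unit-quaternion algebra for joint rotations.

Quaternions are stored as ``(w, x, y, z)`` arrays; any leading batch shape is
accepted.  Two conventions run through the whole package:

* **Canonical form** — unit norm with ``w >= 0``.  ``q`` and ``-q`` encode the
  same rotation, so fixing the sign gives every rotation a unique
  representative and keeps network inputs in a consistent half-space.
* **Geodesic distance** — the magnitude of the quaternion logarithm of the
  relative rotation, ``d(q, q') = |log(q' q^-1)|``.  For a relative rotation of
  angle ``theta`` (canonical branch, ``theta`` in ``[0, pi]``) this equals
  ``theta / 2``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "QuaternionError",
    "canonicalize",
    "check_unit",
    "qmul",
    "qconj",
    "qlog",
    "qexp",
    "geodesic_distance",
    "slerp",
    "from_axis_angle",
    "rotate_vector",
    "random_canonical",
]

_UNIT_TOL = 1e-6


class QuaternionError(ValueError):
    """Raised for zero-norm or non-unit quaternion inputs."""


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Normalize to unit length and fix the sign so that ``w >= 0``.

    Parameters
    ----------
    q
        Array of shape ``(..., 4)``; any nonzero 4-vector per entry.

    Returns
    -------
    Array of the same shape: unit quaternions with ``w >= 0``, representing
    the same rotations.  ``w == 0`` entries are left with their stored sign.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise QuaternionError(f"expected trailing dimension 4, got {q.shape}")
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12) or not np.all(np.isfinite(q)):
        raise QuaternionError("zero-norm or non-finite quaternion")
    out = q / norm
    flip = out[..., :1] < 0.0
    return np.where(flip, -out, out)


def check_unit(q: np.ndarray, tol: float = _UNIT_TOL) -> np.ndarray:
    """Validate unit norm within *tol*; returns the array unchanged."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if not np.all(np.abs(norm - 1.0) <= tol):
        raise QuaternionError(f"non-unit quaternion (|norm-1| > {tol})")
    return q


def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product ``q1 * q2`` (broadcasting over leading axes)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    """Conjugate; equals the inverse for unit quaternions."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qlog(q: np.ndarray) -> np.ndarray:
    """Logarithm of a unit quaternion as a 3-vector (half-angle times axis).

    The canonical branch is used: the input's sign is first fixed so the
    encoded rotation angle lies in ``[0, pi]`` and ``|log q| = theta / 2``.
    """
    q = canonicalize(q)
    w = np.clip(q[..., 0], -1.0, 1.0)
    vec = q[..., 1:]
    vnorm = np.linalg.norm(vec, axis=-1, keepdims=True)
    half_angle = np.arctan2(vnorm[..., 0], w)[..., None]
    # sinc-safe axis scaling: log q = half_angle * axis
    scale = np.where(vnorm > 1e-12, half_angle / np.maximum(vnorm, 1e-300), 1.0)
    return vec * scale


def qexp(v: np.ndarray) -> np.ndarray:
    """Exponential of a pure 3-vector back to a unit quaternion."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v, axis=-1, keepdims=True)
    w = np.cos(angle)
    scale = np.where(angle > 1e-12, np.sin(angle) / np.maximum(angle, 1e-300), 1.0)
    return np.concatenate([w, v * scale], axis=-1)


def geodesic_distance(q: np.ndarray, q_prime: np.ndarray) -> np.ndarray:
    """Length of the shortest rotation path between two unit quaternions.

    ``d(q, q') = |log(q' q^-1)|`` on the canonical branch: a relative
    rotation of angle ``theta in [0, pi]`` gives ``theta / 2``.  Symmetric
    and zero iff both encode the same rotation.
    """
    q = check_unit(q)
    q_prime = check_unit(q_prime)
    rel = qmul(q_prime, qconj(q))
    return np.linalg.norm(qlog(rel), axis=-1)


def slerp(q1: np.ndarray, q2: np.ndarray, w: float | np.ndarray) -> np.ndarray:
    """Spherical linear interpolation ``q(w) = q1 exp(w log(q1^-1 q2))``.

    Follows the shortest arc: if ``dot(q1, q2) < 0`` the sign of ``q2`` is
    flipped first.  ``w`` must lie in ``[0, 1]``; the angular velocity along
    the returned geodesic is constant in ``w``.
    """
    warr = np.asarray(w, dtype=float)
    if np.any(warr < 0.0) or np.any(warr > 1.0):
        raise ValueError("interpolation weight outside [0, 1]")
    q1 = check_unit(np.asarray(q1, dtype=float), tol=1e-5)
    q2 = check_unit(np.asarray(q2, dtype=float), tol=1e-5)
    dot = np.sum(q1 * q2, axis=-1, keepdims=True)
    q2 = np.where(dot < 0.0, -q2, q2)
    rel = qmul(qconj(q1), q2)
    step = qexp(warr[..., None] * qlog(rel))
    out = qmul(q1, step)
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def from_axis_angle(axis: np.ndarray, angle: float | np.ndarray) -> np.ndarray:
    """Unit quaternion rotating by *angle* (radians) about *axis*."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero-length rotation axis")
    axis = axis / norm
    half = 0.5 * np.asarray(angle, dtype=float)[..., None]
    return np.concatenate([np.cos(half), axis * np.sin(half)], axis=-1)


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply the rotation encoded by unit quaternion ``q`` to 3-vector ``v``."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def random_canonical(rng: np.random.Generator, n: int | tuple = ()) -> np.ndarray:
    """Uniform random rotations as canonical unit quaternions."""
    shape = (n,) if isinstance(n, int) else tuple(n)
    q = rng.normal(size=shape + (4,))
    return canonicalize(q)
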