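"""Windowed time-lag cross-correlation (WTLCC) and derived lag/role
statistics.

For each window of the focal player's speed profile, the signed integer lag
(within a bounded range) that maximizes the Pearson correlation with the
partner's lag-shifted profile is recorded.  Convention: a **positive** lag
means the focal player's signal trails the partner's — the focal player is
following.  The trial summaries are

* ``t_hat`` — the mean absolute per-window lag (frames; a reaction-time-like
  coordination measure), and
* ``r_LF`` — ``(1 + mean(sign(lag))) / 2 * 100%``: 100% when always
  following, 0% when always leading, 50% when balanced (zero lags count as
  50%).

Defaults follow the analysis convention at 90 fps: window 300 frames, step
50, lags within ±90 frames (±1 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WTLCCResult",
    "wtlcc",
    "mean_abs_lag",
    "leader_follower_ratio",
]

WINDOW = 300
STEP = 50
MAX_LAG = 90


@dataclass(frozen=True)
class WTLCCResult:
    """Per-window signed lags and peak correlations of one trial."""

    lags: np.ndarray  # (W,) signed frames; positive = focal follows
    peak_corr: np.ndarray  # (W,)
    window_starts: np.ndarray  # (W,)
    window: int
    step: int
    max_lag: int
    rate: float | None = None

    @property
    def n_windows(self) -> int:
        return len(self.lags)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        return np.nan
    return float(np.dot(xc, yc) / denom)


def _best_lag(
    focal: np.ndarray, partner: np.ndarray, start: int, window: int, max_lag: int
) -> tuple[int, float] | None:
    """Arg-max lag for one window; ties go to the smallest |lag|, then to the
    negative lag.  Returns None if every correlation is undefined."""
    seg = focal[start : start + window]
    if np.ptp(seg) == 0.0:
        return None
    # tie-break order: |lag| ascending, negative before positive
    lag_order = sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l))
    best: tuple[float, int] | None = None
    for lag in lag_order:
        other = partner[start - lag : start - lag + window]
        r = _pearson(seg, other)
        if np.isnan(r):
            continue
        if best is None or r > best[0] + 1e-12:
            best = (r, lag)
    if best is None:
        return None
    return best[1], best[0]


def wtlcc(
    speed_focal: np.ndarray,
    speed_partner: np.ndarray,
    window: int = WINDOW,
    step: int = STEP,
    max_lag: int = MAX_LAG,
    rate: float | None = None,
) -> WTLCCResult:
    """Windowed time-lag cross-correlation of two aligned speed profiles.

    Windows start at ``max_lag`` and advance by ``step`` while the shifted
    partner segment stays in range for every lag.  A window is skipped (and
    excluded from ``W``) when its focal segment — or every admissible
    partner segment — has zero variance.
    """
    a = np.asarray(speed_focal, dtype=float)
    b = np.asarray(speed_partner, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("speed profiles must be equal-length 1-D series")
    T = len(a)
    if T < window + 2 * max_lag:
        raise ValueError(
            f"series too short for one window: need >= {window + 2 * max_lag} samples"
        )
    starts, lags, peaks = [], [], []
    for start in range(max_lag, T - window - max_lag + 1, step):
        hit = _best_lag(a, b, start, window, max_lag)
        if hit is None:
            continue
        starts.append(start)
        lags.append(hit[0])
        peaks.append(hit[1])
    return WTLCCResult(
        lags=np.asarray(lags, dtype=int),
        peak_corr=np.asarray(peaks, dtype=float),
        window_starts=np.asarray(starts, dtype=int),
        window=window,
        step=step,
        max_lag=max_lag,
        rate=rate,
    )


def mean_abs_lag(result: WTLCCResult) -> float:
    """Mean absolute per-window lag ``t_hat`` in frames."""
    if result.n_windows == 0:
        raise ValueError("no valid windows: t_hat undefined")
    return float(np.mean(np.abs(result.lags)))


def leader_follower_ratio(result: WTLCCResult) -> float:
    """Follow-time ratio ``r_LF`` in percent from the signs of the lags."""
    if result.n_windows == 0:
        raise ValueError("no valid windows: r_LF undefined")
    return float(0.5 * (1.0 + np.mean(np.sign(result.lags))) * 100.0)
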