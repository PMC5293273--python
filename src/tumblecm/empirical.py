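"""Empirical conditional moments from tracked 2D positions.

The pipeline is: validate the track table -> derive per-frame headings from
single-frame displacements -> (optionally) filter tracks the way wobbly or
truncated experimental tracks are filtered -> accumulate the kernel-weighted
CM estimator

    m^n(theta) = sum_i,t |Theta_i(t+dt) - Theta_i(t)|_a^n / dt * K_i(t) / Z_K

with Gaussian kernel ``K = exp(-d(Theta_i(t), theta)^2 / (2 dtheta^2))`` on
the wrapped (circular) heading difference ``d``, and ``K = 1`` for the
unconditioned estimate. Every frame is used once as a left endpoint (all lag
shifts are accumulated).

Headings are computed from raw, unsmoothed positions; a Savitzky-Golay
smoothing helper is provided only for the heuristic-recognizer path and the
curvature filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .angles import abs_wrap, wrap_signed
from .simulate import LabeledTrajectory

__all__ = [
    "HeadingSeries",
    "CMEstimate",
    "FilterRules",
    "validate_tracks",
    "headings_from_positions",
    "headings_from_trajectories",
    "smooth_positions",
    "apply_filters",
    "empirical_cms",
    "cm_track_sums",
]

TIME_TOL = 1e-6  # s, tolerance on constant frame spacing


@dataclass
class HeadingSeries:
    """Per-track heading-angle series at the frame rate.

    ``theta[i]`` is the direction of the displacement from frame ``i`` to
    ``i+1`` (one fewer entry than frames); ``valid[i]`` is False where the
    displacement was exactly zero (stalled detection, heading undefined).
    """

    frame_dt: float
    track_ids: list = field(default_factory=list)
    times: list = field(default_factory=list)
    theta: list = field(default_factory=list)
    valid: list = field(default_factory=list)

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)


@dataclass
class CMEstimate:
    """Kernel-weighted empirical conditional moments at one conditioning angle."""

    orders: tuple[int, ...]
    values: np.ndarray
    dt: float
    theta: float | None = None
    delta_theta: float | None = None
    z_k: float = 0.0
    n_pairs: int = 0
    low_confidence: bool = False


@dataclass
class FilterRules:
    """Track-level filtering thresholds (defaults as used for 20 Hz data).

    Applied in order: end-trimming, maximum duration, minimum total
    displacement, removal of the highest-median-curvature quantile, minimum
    duration for CM eligibility.
    """

    trim_time: float = 0.5  # s removed from each end
    max_duration: float = 10.0  # s
    min_displacement: float = 10.0  # um, net start-to-end distance
    curvature_fraction: float = 0.2  # fraction of wobbliest tracks removed
    min_duration: float = 3.0  # s, CM eligibility


def validate_tracks(tracks: pd.DataFrame) -> float:
    """Check the track table contract; return the common frame interval."""
    required = {"track_id", "t", "x", "y"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table is missing columns: {sorted(missing)}")
    if len(tracks) == 0:
        raise ValueError("track table is empty")
    dts = []
    for tid, g in tracks.groupby("track_id", sort=False):
        t = g["t"].to_numpy(dtype=float)
        if len(t) < 2:
            continue
        d = np.diff(t)
        if np.any(d <= 0):
            raise ValueError(f"track {tid}: times are not strictly increasing")
        if d.max() - d.min() > TIME_TOL:
            raise ValueError(f"track {tid}: frame interval is not constant")
        dts.append(d.mean())
    if not dts:
        raise ValueError("no track has >= 2 points")
    dts = np.asarray(dts)
    if dts.max() - dts.min() > TIME_TOL:
        raise ValueError("tracks have inconsistent frame intervals")
    return float(dts.mean())


def headings_from_positions(tracks: pd.DataFrame) -> HeadingSeries:
    """Heading series from single-frame displacements of raw positions."""
    frame_dt = validate_tracks(tracks)
    hs = HeadingSeries(frame_dt=frame_dt)
    for tid, g in tracks.groupby("track_id", sort=False):
        if len(g) < 2:
            warnings.warn(f"track {tid} has < 2 frames; skipped", stacklevel=2)
            continue
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        dx, dy = np.diff(x), np.diff(y)
        valid = (dx != 0.0) | (dy != 0.0)
        theta = np.arctan2(dy, dx)
        hs.track_ids.append(tid)
        hs.times.append(g["t"].to_numpy(dtype=float)[:-1])
        hs.theta.append(theta)
        hs.valid.append(valid)
    return hs


def headings_from_trajectories(
    trajectories: Sequence[LabeledTrajectory],
) -> HeadingSeries:
    """Heading series directly from simulator ground-truth headings."""
    if len(trajectories) == 0:
        raise ValueError("empty ensemble")
    frame_dt = float(trajectories[0].times[1] - trajectories[0].times[0])
    hs = HeadingSeries(frame_dt=frame_dt)
    for tr in trajectories:
        theta = tr.headings[:-1]  # heading applied during each frame
        hs.track_ids.append(tr.track_id)
        hs.times.append(tr.times[:-1])
        hs.theta.append(np.asarray(theta, dtype=float))
        hs.valid.append(np.ones(len(theta), dtype=bool))
    return hs


def smooth_positions(x: np.ndarray, y: np.ndarray, window: int = 5, order: int = 2):
    """Savitzky-Golay-smoothed coordinates (used for curvature filtering and
    the heuristic recognizer, never for the CM path)."""
    if len(x) < window:
        return np.asarray(x, float), np.asarray(y, float)
    return savgol_filter(x, window, order), savgol_filter(y, window, order)


def _median_curvature(x: np.ndarray, y: np.ndarray, frame_dt: float) -> float:
    """Median |turn angle| per unit path length on the smoothed track."""
    xs, ys = smooth_positions(x, y)
    dx, dy = np.diff(xs), np.diff(ys)
    ds = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    if len(theta) < 2:
        return 0.0
    turns = np.abs(wrap_signed(np.diff(theta)))
    step = 0.5 * (ds[:-1] + ds[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where(step > 0, turns / np.maximum(step, 1e-300), np.inf)
    return float(np.median(curv))


def apply_filters(
    tracks: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the track filters in order; return survivors and a removal report."""
    rules = rules or FilterRules()
    validate_tracks(tracks)
    report = {
        "n_input": tracks["track_id"].nunique(),
        "removed_duration": 0,
        "removed_displacement": 0,
        "removed_curvature": 0,
        "removed_min_duration": 0,
    }

    trimmed = []
    for tid, g in tracks.groupby("track_id", sort=False):
        t = g["t"].to_numpy(dtype=float)
        keep = (t >= t[0] + rules.trim_time - TIME_TOL) & (
            t <= t[-1] - rules.trim_time + TIME_TOL
        )
        if keep.sum() >= 2:
            trimmed.append(g.loc[keep])
    if not trimmed:
        raise ValueError("no tracks survive end-trimming")

    survivors = []
    for g in trimmed:
        t = g["t"].to_numpy(dtype=float)
        duration = t[-1] - t[0]
        if duration > rules.max_duration + TIME_TOL:
            report["removed_duration"] += 1
            continue
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        if np.hypot(x[-1] - x[0], y[-1] - y[0]) < rules.min_displacement:
            report["removed_displacement"] += 1
            continue
        survivors.append(g)
    if not survivors:
        raise ValueError("no tracks survive duration/displacement filters")

    frame_dt = validate_tracks(pd.concat(survivors))
    curvs = np.array(
        [
            _median_curvature(
                g["x"].to_numpy(dtype=float), g["y"].to_numpy(dtype=float), frame_dt
            )
            for g in survivors
        ]
    )
    if rules.curvature_fraction > 0 and len(survivors) > 1:
        cutoff = np.quantile(curvs, 1.0 - rules.curvature_fraction)
        keep_idx = [i for i, c in enumerate(curvs) if c <= cutoff]
        # quantile ties can keep more than the target fraction; remove the
        # wobbliest ceil(fraction*n) tracks deterministically instead
        n_remove = int(np.floor(rules.curvature_fraction * len(survivors)))
        if len(survivors) - len(keep_idx) < n_remove:
            order = np.argsort(curvs, kind="stable")
            keep_idx = sorted(order[: len(survivors) - n_remove])
        report["removed_curvature"] = len(survivors) - len(keep_idx)
        survivors = [survivors[i] for i in keep_idx]

    final = []
    for g in survivors:
        t = g["t"].to_numpy(dtype=float)
        if t[-1] - t[0] + TIME_TOL < rules.min_duration:
            report["removed_min_duration"] += 1
            continue
        final.append(g)
    if not final:
        raise ValueError("no tracks survive the minimum-duration filter")
    report["n_surviving"] = len(final)
    return pd.concat(final, ignore_index=True), report


def _lag_steps(dt: float, frame_dt: float) -> int:
    lag = dt / frame_dt
    if abs(lag - round(lag)) > 1e-6 or round(lag) < 1:
        raise ValueError(
            f"lag dt = {dt} s must be a positive integer multiple of the "
            f"frame interval {frame_dt} s"
        )
    return int(round(lag))


def cm_track_sums(
    headings: HeadingSeries,
    dt: float,
    orders: Sequence[int] = (1, 2, 3, 4, 6, 8),
    theta_cond: float | None = None,
    delta_theta: float = 0.125 * np.pi,
):
    """Per-track kernel-weighted sums ``(S, Z, n_pairs)`` of the CM estimator.

    ``S[i, j] = sum_t K * |dTheta|_a^n_j / dt`` over the pairs of track ``i``
    and ``Z[i] = sum_t K``. These sufficient statistics make trajectory
    bootstrap resampling cheap: resampling tracks only re-sums rows.
    """
    if theta_cond is not None and not delta_theta > 0:
        raise ValueError("delta_theta must be positive when conditioning")
    lag = _lag_steps(dt, headings.frame_dt)
    orders = tuple(int(n) for n in orders)
    S = np.zeros((headings.n_tracks, len(orders)))
    Z = np.zeros(headings.n_tracks)
    n_pairs = np.zeros(headings.n_tracks, dtype=int)
    for i in range(headings.n_tracks):
        theta = headings.theta[i]
        valid = headings.valid[i]
        if len(theta) <= lag:
            continue
        ok = valid[:-lag] & valid[lag:]
        if not ok.any():
            continue
        left = theta[:-lag][ok]
        dth = abs_wrap(theta[lag:][ok] - left)
        if theta_cond is None:
            K = np.ones(len(left))
        else:
            d = wrap_signed(left - theta_cond)
            K = np.exp(-(d**2) / (2.0 * delta_theta**2))
        for j, n in enumerate(orders):
            S[i, j] = np.sum(K * dth**n / dt)
        Z[i] = K.sum()
        n_pairs[i] = int(ok.sum())
    return S, Z, n_pairs


def empirical_cms(
    headings: HeadingSeries,
    dt: float,
    orders: Sequence[int] = (1, 2, 3, 4, 6, 8),
    theta_cond: float | None = None,
    delta_theta: float = 0.125 * np.pi,
    min_weight: float = 10.0,
) -> CMEstimate:
    """Kernel-weighted empirical CMs, pooled over all tracks and lag shifts."""
    S, Z, n_pairs = cm_track_sums(headings, dt, orders, theta_cond, delta_theta)
    z_k = float(Z.sum())
    if z_k <= 0:
        raise ValueError("no valid lag pairs (Z_K = 0)")
    values = S.sum(axis=0) / z_k
    low = z_k < min_weight
    if low:
        warnings.warn(
            f"effective sample weight Z_K = {z_k:.2f} is below {min_weight}; "
            "low-confidence estimate",
            stacklevel=2,
        )
    return CMEstimate(
        orders=tuple(int(n) for n in orders),
        values=values,
        dt=dt,
        theta=theta_cond,
        delta_theta=None if theta_cond is None else delta_theta,
        z_k=z_k,
        n_pairs=int(n_pairs.sum()),
        low_confidence=bool(low),
    )
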