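"""Tumble recognizers: the systematic Neyman-Pearson test and a heuristic.

The systematic recognizer is built from the inferred model: over one lag the
angular displacement is either a thermal step (folded normal ``2 N(dTheta)``
of variance ``2 D_rot dt``) or a tumble (density ``P(|dTheta|)``). The
likelihood ratio

    R(dTheta) = 2 N(dTheta) / P(|dTheta|)

is small for tumbles; the hypothesis "tumble" is accepted when
``R < r_crit(alpha1)``, equivalently when ``|dTheta|_a > dTheta_crit`` with
the critical angle fixed by the type-I error (missed-tumble probability)

    alpha1 = integral_0^dTheta_crit P(|dTheta|) d(dTheta).

The type-II error (a Brownian step called a tumble) follows as the folded
normal tail beyond the threshold, up to pi. By the Neyman-Pearson lemma no
other angular threshold with type-I error <= alpha1 has a smaller type-II
error.

The heuristic recognizer mirrors common practice: subsample to ~6.6 Hz,
Savitzky-Golay smooth, and mark local speed minima that are sufficiently
deep or turn-rate maxima that are sufficiently large. Its two thresholds are
configuration knobs, not model quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import savgol_filter
from scipy.stats import norm

from .angles import abs_wrap, wrap_signed
from .distributions import ThermalStep, TumbleAngleDistribution
from .empirical import HeadingSeries

__all__ = [
    "RecognizerThresholds",
    "np_thresholds",
    "systematic_recognize",
    "heuristic_recognize",
    "compare_recognizers",
    "HeuristicParams",
]


@dataclass(frozen=True)
class RecognizerThresholds:
    """Operating point of the systematic recognizer."""

    alpha1: float
    dtheta_crit: float  # rad
    r_crit: float
    alpha2: float


def _folded_normal_pdf(x, std):
    return 2.0 * norm.pdf(x, loc=0.0, scale=std)


def np_thresholds(
    tumble_dist: TumbleAngleDistribution,
    thermal: ThermalStep,
    alpha1: float = 0.05,
) -> RecognizerThresholds:
    """Solve for the critical angle, likelihood-ratio threshold and type-II error."""
    if not 0.0 < alpha1 < 1.0:
        raise ValueError("alpha1 must lie strictly between 0 and 1")
    dcrit = brentq(lambda d: tumble_dist.cdf(d) - alpha1, 1e-12, np.pi - 1e-12)
    std = thermal.std
    if std > 0:
        r_crit = _folded_normal_pdf(dcrit, std) / tumble_dist.pdf(dcrit)
        alpha2 = float(2.0 * (norm.cdf(np.pi / std) - norm.cdf(dcrit / std)))
        # R should fall through r_crit from above at the threshold
        probe = np.linspace(max(dcrit - 0.1, 1e-6), min(dcrit + 0.1, np.pi), 9)
        with np.errstate(divide="ignore"):
            r_probe = _folded_normal_pdf(probe, std) / np.asarray(
                tumble_dist.pdf(probe)
            )
        if np.any(np.diff(r_probe) > 0):
            warnings.warn(
                "likelihood ratio is non-monotone near the threshold; the "
                "angular threshold remains defined by the type-I condition",
                stacklevel=2,
            )
    else:
        r_crit = 0.0
        alpha2 = 0.0
    return RecognizerThresholds(
        alpha1=float(alpha1),
        dtheta_crit=float(dcrit),
        r_crit=float(r_crit),
        alpha2=alpha2,
    )


def systematic_recognize(
    headings: HeadingSeries,
    dt: float,
    thresholds: RecognizerThresholds,
    thermal: ThermalStep | None = None,
    tumble_dist: TumbleAngleDistribution | None = None,
) -> pd.DataFrame:
    """Classify non-overlapping lag steps as run or tumble.

    Returns one row per lag step: (track_id, t, dtheta, R, tumble). ``t`` is
    the left endpoint of the step; endpoints without a full lag are not
    classified. Ties at exactly the critical angle count as runs. The
    likelihood-ratio column is filled when the two densities are supplied.
    """
    lag = dt / headings.frame_dt
    if abs(lag - round(lag)) > 1e-6 or round(lag) < 1:
        raise ValueError("dt must be an integer multiple of the frame interval")
    lag = int(round(lag))
    rows = []
    std = thermal.std if thermal is not None else None
    for i in range(headings.n_tracks):
        theta = headings.theta[i]
        times = headings.times[i]
        valid = headings.valid[i]
        for s in range(0, len(theta) - lag, lag):
            if not (valid[s] and valid[s + lag]):
                continue
            d = float(abs_wrap(theta[s + lag] - theta[s]))
            if std is not None and tumble_dist is not None:
                p = tumble_dist.pdf(min(d, np.pi))
                R = _folded_normal_pdf(d, std) / p if p > 0 else np.inf
            else:
                R = np.nan
            rows.append(
                {
                    "track_id": headings.track_ids[i],
                    "t": float(times[s]),
                    "dtheta": d,
                    "R": float(R),
                    "tumble": bool(d > thresholds.dtheta_crit),
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "t", "dtheta", "R", "tumble"])


@dataclass
class HeuristicParams:
    """Knobs of the speed/turn-rate extrema recognizer (not model-derived).

    A tumble is marked at a local speed minimum below
    ``speed_dip_frac * median(speed)`` or at a local turn-rate maximum above
    ``turn_rate_min`` (rad/s).
    """

    subsample: int = 3
    window: int = 5
    polyorder: int = 2
    speed_dip_frac: float = 0.5
    turn_rate_min: float = 3.0


def heuristic_recognize(
    times: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    params: HeuristicParams | None = None,
) -> pd.DataFrame:
    """Detect tumble events on one track from speed minima / turn-rate maxima.

    Returns one row per retained (subsampled) frame with the smoothed speed,
    turn rate and a boolean tumble label; contiguous flagged frames form one
    event.
    """
    p = params or HeuristicParams()
    times = np.asarray(times, float)[:: p.subsample]
    x = np.asarray(x, float)[:: p.subsample]
    y = np.asarray(y, float)[:: p.subsample]
    if len(x) < p.window:
        raise ValueError("track shorter than the smoothing window")
    xs = savgol_filter(x, p.window, p.polyorder)
    ys = savgol_filter(y, p.window, p.polyorder)
    dt_eff = float(np.mean(np.diff(times)))
    dx, dy = np.diff(xs), np.diff(ys)
    speed = np.hypot(dx, dy) / dt_eff
    theta = np.arctan2(dy, dx)
    omega = np.abs(wrap_signed(np.diff(theta))) / dt_eff  # per interior frame

    n_int = len(omega)  # interior frames 1..n-2
    med_speed = float(np.median(speed))
    tumble = np.zeros(n_int, dtype=bool)
    sp = 0.5 * (speed[:-1] + speed[1:])  # speed centered on interior frames
    for j in range(n_int):
        lo, hi = max(0, j - 1), min(n_int, j + 2)
        if sp[j] == sp[lo:hi].min() and sp[j] < p.speed_dip_frac * med_speed:
            tumble[j] = True
        if omega[j] == omega[lo:hi].max() and omega[j] > p.turn_rate_min:
            tumble[j] = True

    return pd.DataFrame(
        {
            "t": times[1:-1],
            "speed": sp,
            "turn_rate": omega,
            "tumble": tumble,
        }
    )


def events_from_calls(calls: pd.DataFrame) -> np.ndarray:
    """Collapse contiguous flagged frames into event times (turn-rate peak)."""
    t = calls["t"].to_numpy()
    lab = calls["tumble"].to_numpy()
    om = calls["turn_rate"].to_numpy() if "turn_rate" in calls else np.ones_like(t)
    events = []
    j = 0
    while j < len(lab):
        if lab[j]:
            k = j
            while k + 1 < len(lab) and lab[k + 1]:
                k += 1
            seg = slice(j, k + 1)
            events.append(t[seg][np.argmax(om[seg])])
            j = k + 1
        else:
            j += 1
    return np.asarray(events)


def compare_recognizers(calls_a: pd.DataFrame, calls_b: pd.DataFrame):
    """Fraction of co-classified steps plus the 2x2 confusion table.

    Both call sets must live on the same (track_id, t) time base.
    """
    key = ["track_id", "t"] if "track_id" in calls_a and "track_id" in calls_b else ["t"]
    merged = calls_a.merge(calls_b, on=key, suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("call sets share no time points")
    a = merged["tumble_a"].to_numpy(bool)
    b = merged["tumble_b"].to_numpy(bool)
    table = pd.DataFrame(
        [[np.sum(~a & ~b), np.sum(~a & b)], [np.sum(a & ~b), np.sum(a & b)]],
        index=["a_run", "a_tumble"],
        columns=["b_run", "b_tumble"],
    )
    return float(np.mean(a == b)), table
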