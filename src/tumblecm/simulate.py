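"""Shot-noise run-and-tumble trajectory simulator with known ground truth.

The heading angle evolves in discrete frames of length ``frame_dt``: every
frame receives a Gaussian rotational-diffusion increment of variance
``2*d_rot*frame_dt``, and with probability ``frame_dt * lambda(theta)`` a
tumble additionally kicks the heading by a signed angle drawn from the
configured tumble-angle distribution (sign +/- with equal probability). The
position advances with constant speed along the current heading, so speed
dynamics are deliberately absent — the conditional-moment method uses the
heading only.

Chemotactic variants: the tumble rate can be modulated as
``lambda(theta) = lambda0 + a2_rate * cos(theta)`` (classical rate bias; the
gradient points along -x, so ``theta = pi`` is up-gradient and has the lowest
rate), and/or the tumble-angle scale can be modulated as
``sigma * (1 + angle_bias_amp * cos(theta))`` (angle bias: smaller mean turn
up-gradient). ``theta`` is the heading of the current frame, i.e. the
orientation just prior to tumbling.

Run times are exponential by default (per-frame Bernoulli tumbling); a
gamma-distributed run-time mode with matched mean ``1/lambda0`` is available
to probe robustness against non-Poissonian tumbling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import TumbleAngleDistribution

__all__ = [
    "SimConfig",
    "LabeledTrajectory",
    "simulate_ensemble",
    "ensemble_to_table",
    "ground_truth_table",
]


@dataclass
class SimConfig:
    """Configuration of a simulated ensemble.

    Parameters
    ----------
    lambda0 : float
        Base tumble rate (s^-1).
    tumble_dist : TumbleAngleDistribution
        Magnitude distribution of tumble angles.
    seed : int
        RNG seed (required; ensembles are bit-reproducible given the seed).
    a2_rate : float
        Cosine amplitude of the rate modulation (s^-1); requires
        ``|a2_rate| <= lambda0`` so the rate stays non-negative.
    angle_bias_amp : float
        Fractional cosine modulation of the tumble-angle scale parameter;
        ``|angle_bias_amp| < 1``.
    d_rot : float
        Rotational diffusion coefficient (rad^2/s).
    speed : float
        Run speed (um/s), constant.
    frame_dt : float
        Frame interval (s); default 0.05 s (20 Hz acquisition).
    duration : float
        Track length (s).
    n_tracks : int
        Ensemble size.
    run_time_model : str
        "exponential" (default) or "gamma" (shape ``run_time_shape``, mean
        matched to ``1/lambda0``). The gamma mode supports no rate modulation.
    """

    lambda0: float
    tumble_dist: TumbleAngleDistribution
    seed: int
    a2_rate: float = 0.0
    angle_bias_amp: float = 0.0
    d_rot: float = 0.0
    speed: float = 20.0
    frame_dt: float = 0.05
    duration: float = 10.0
    n_tracks: int = 1
    run_time_model: str = "exponential"
    run_time_shape: float = 2.0

    def validate(self) -> None:
        if self.lambda0 < 0 or self.d_rot < 0 or self.speed < 0:
            raise ValueError("rates, d_rot and speed must be non-negative")
        if self.frame_dt <= 0 or self.duration <= 0 or self.n_tracks < 1:
            raise ValueError("frame_dt, duration must be positive; n_tracks >= 1")
        if abs(self.a2_rate) > self.lambda0:
            raise ValueError("|a2_rate| must not exceed lambda0 (rate >= 0)")
        if abs(self.angle_bias_amp) >= 1.0:
            raise ValueError("|angle_bias_amp| must be below 1")
        pmax = self.frame_dt * (self.lambda0 + abs(self.a2_rate))
        if pmax > 0.2:
            raise ValueError(
                f"frame_dt*(lambda0+|a2_rate|) = {pmax:.3f} violates the "
                "at-most-one-tumble-per-frame assumption (must be << 1)"
            )
        if self.run_time_model not in ("exponential", "gamma"):
            raise ValueError("run_time_model must be 'exponential' or 'gamma'")
        if self.run_time_model == "gamma":
            if self.a2_rate != 0.0:
                raise ValueError("rate modulation requires exponential run times")
            if self.run_time_shape <= 0:
                raise ValueError("run_time_shape must be positive")
            if self.lambda0 <= 0:
                raise ValueError("gamma run times require lambda0 > 0")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValueError("an integer RNG seed is required")


@dataclass
class LabeledTrajectory:
    """One simulated track with ground-truth tumble labels.

    ``headings[i]`` is the direction of motion during frame ``i``; positions
    advance by ``speed * frame_dt * (cos, sin)(headings[i])``. Headings are
    cumulative (not wrapped). ``tumble_times`` mark the frame boundary at
    which each tumble kick was applied; ``tumble_angles`` are the signed
    kicks.
    """

    track_id: int
    times: np.ndarray
    positions: np.ndarray
    headings: np.ndarray
    tumble_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    tumble_angles: np.ndarray = field(default_factory=lambda: np.empty(0))


def _gamma_tumble_steps(cfg: SimConfig, rng, n_steps: int) -> np.ndarray:
    """Boolean (n_tracks, n_steps) tumble indicator for gamma run times."""
    tumble = np.zeros((cfg.n_tracks, n_steps), dtype=bool)
    shape = cfg.run_time_shape
    scale = 1.0 / (cfg.lambda0 * shape)  # mean run time 1/lambda0
    n_draw = max(8, int(2 * cfg.duration * cfg.lambda0 + 10 * np.sqrt(cfg.duration * cfg.lambda0)))
    for i in range(cfg.n_tracks):
        t = np.cumsum(rng.gamma(shape, scale, size=n_draw))
        while t[-1] < cfg.duration:
            t = np.concatenate([t, t[-1] + np.cumsum(rng.gamma(shape, scale, size=n_draw))])
        steps = (t[t < cfg.duration] / cfg.frame_dt).astype(int)
        steps = steps[steps < n_steps]
        tumble[i, steps] = True
    return tumble


def simulate_ensemble(config: SimConfig) -> list[LabeledTrajectory]:
    """Simulate an ensemble of labeled run-and-tumble trajectories."""
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    n_steps = int(round(config.duration / config.frame_dt))
    n = config.n_tracks
    h = config.frame_dt

    theta = rng.uniform(-np.pi, np.pi, size=n)
    pos = np.zeros((n, n_steps + 1, 2))
    headings = np.zeros((n, n_steps + 1))
    headings[:, 0] = theta
    brown_std = np.sqrt(2.0 * config.d_rot * h)

    gamma_tumbles = None
    if config.run_time_model == "gamma":
        gamma_tumbles = _gamma_tumble_steps(config, rng, n_steps)

    tumble_rec: list[list[tuple[float, float]]] = [[] for _ in range(n)]

    for i in range(n_steps):
        pos[:, i + 1, 0] = pos[:, i, 0] + config.speed * h * np.cos(theta)
        pos[:, i + 1, 1] = pos[:, i, 1] + config.speed * h * np.sin(theta)

        if gamma_tumbles is not None:
            tum = gamma_tumbles[:, i]
        else:
            rate = config.lambda0 + config.a2_rate * np.cos(theta)
            tum = rng.random(n) < h * rate

        kick = np.zeros(n)
        n_tum = int(tum.sum())
        if n_tum:
            if config.angle_bias_amp != 0.0:
                scale = 1.0 + config.angle_bias_amp * np.cos(theta[tum])
                mag = config.tumble_dist.sample(rng, scale=scale)
            else:
                mag = np.atleast_1d(config.tumble_dist.sample(rng, size=n_tum))
            sign = rng.choice([-1.0, 1.0], size=n_tum)
            kick[tum] = sign * mag
            t_event = (i + 1) * h
            for j, b in zip(np.nonzero(tum)[0], kick[tum]):
                tumble_rec[j].append((t_event, b))

        dB = rng.normal(0.0, brown_std, size=n) if brown_std > 0 else 0.0
        theta = theta + kick + dB
        headings[:, i + 1] = theta

    times = np.arange(n_steps + 1) * h
    out = []
    for j in range(n):
        rec = np.array(tumble_rec[j], dtype=float).reshape(-1, 2)
        out.append(
            LabeledTrajectory(
                track_id=j,
                times=times.copy(),
                positions=pos[j],
                headings=headings[j],
                tumble_times=rec[:, 0],
                tumble_angles=rec[:, 1],
            )
        )
    return out


def ensemble_to_table(trajectories: Sequence[LabeledTrajectory]) -> pd.DataFrame:
    """Long-format track table (track_id, t, x, y) at the frame rate."""
    if len(trajectories) == 0:
        raise ValueError("empty ensemble")
    frames = [
        pd.DataFrame(
            {
                "track_id": tr.track_id,
                "t": tr.times,
                "x": tr.positions[:, 0],
                "y": tr.positions[:, 1],
            }
        )
        for tr in trajectories
    ]
    return pd.concat(frames, ignore_index=True)


def ground_truth_table(trajectories: Sequence[LabeledTrajectory]) -> pd.DataFrame:
    """Ground-truth tumble events (track_id, t_tumble, beta)."""
    rows = [
        pd.DataFrame(
            {
                "track_id": tr.track_id,
                "t_tumble": tr.tumble_times,
                "beta": tr.tumble_angles,
            }
        )
        for tr in trajectories
    ]
    if not rows:
        raise ValueError("empty ensemble")
    return pd.concat(rows, ignore_index=True)
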