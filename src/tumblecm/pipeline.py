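"""End-to-end pipeline: filters -> CMs -> inference -> optional extras.

Each stage failure is re-raised with the stage name attached. Every run
writes a ``summary.json`` with the inferred parameters, the effective
configuration and the seed, so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .distributions import ThermalStep
from .empirical import FilterRules, apply_filters, empirical_cms, headings_from_positions
from .inference import (
    bootstrap_errors,
    cm_ratio_profile,
    fit_parameters,
    infer_vs_theta,
)
from .recognizers import np_thresholds, systematic_recognize

logger = logging.getLogger("tumblecm")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective parameters of one analysis run (defaults: 20 Hz E. coli-style)."""

    tracks_path: str
    out_dir: str
    seed: int
    dt: float = 0.5  # s; 0.3 s suits short-reversal swimmers
    delta_theta: float = 0.125 * np.pi
    family: str = "gamma"
    orders: tuple = (1, 2, 3, 4, 6, 8)
    do_filter: bool = True
    filter_rules: FilterRules = field(default_factory=FilterRules)
    theta_points: int = 0  # 0 disables the direction-resolved profile
    do_ratios: bool = False
    ratio_thetas: tuple = (0.0,)
    bootstrap: int = 0
    alpha1: float = 0.05
    do_recognize: bool = False

    def validate(self, frame_dt: float) -> None:
        if self.dt <= 0 or self.delta_theta <= 0:
            raise ValueError("dt and delta_theta must be positive")
        lag = self.dt / frame_dt
        if abs(lag - round(lag)) > 1e-6:
            raise ValueError(
                f"dt = {self.dt} s is not a multiple of the frame interval "
                f"{frame_dt} s"
            )
        if int(self.seed) != self.seed:
            raise ValueError("an integer seed is required")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; return (and write) the results bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    summary: dict = {"config": _jsonable(config)}
    try:
        tracks = _stage("read")(tio.read_tracks)(config.tracks_path)
        frame_dt = float(
            tracks.groupby("track_id")["t"].diff().dropna().iloc[0]
        )
        config.validate(frame_dt)
        summary["frame_dt"] = frame_dt
        logger.info("read %d tracks", tracks["track_id"].nunique())

        if config.do_filter:
            tracks, report = _stage("filter")(apply_filters)(
                tracks, config.filter_rules
            )
            summary["filter_report"] = report
            logger.info("filter report: %s", report)

        headings = _stage("headings")(headings_from_positions)(tracks)

        cm = _stage("cms")(empirical_cms)(headings, config.dt, config.orders)
        summary["cms"] = {
            "orders": list(cm.orders),
            "values": cm.values.tolist(),
            "z_k": cm.z_k,
        }

        fit = _stage("fit")(fit_parameters)(cm, family=config.family)
        summary["fit"] = fit.as_dict()
        summary["fit"]["residual"] = fit.residual
        logger.info("inferred parameters: %s", summary["fit"])
        with open(out_dir / "params.json", "w") as fh:
            json.dump(_jsonable(fit.as_dict()), fh, indent=2, sort_keys=True)

        if config.bootstrap >= 2:

            def estimator(hs):
                c = empirical_cms(hs, config.dt, config.orders)
                # resamples start from the full-data optimum (cheap refits)
                return fit_parameters(
                    c, family=config.family, x0=fit.x,
                    starts=[[v] for v in fit.x],
                ).as_dict()

            boot = _stage("bootstrap")(bootstrap_errors)(
                headings, estimator, n_resamples=config.bootstrap,
                seed=int(config.seed),
            )
            summary["bootstrap"] = {
                "n_resamples": boot.n_resamples,
                "n_failed": boot.n_failed,
                "mean": _jsonable(boot.mean),
                "std": _jsonable(boot.std),
            }

        if config.theta_points >= 3:
            grid = np.arange(config.theta_points) * 2 * np.pi / config.theta_points
            profile = _stage("profile")(infer_vs_theta)(
                headings, config.dt, config.family, grid, config.delta_theta,
                config.orders,
            )
            pd.DataFrame(
                {
                    "theta": profile.theta_grid,
                    "lambda": profile.lambda_curve,
                    "mean_angle": profile.mean_angle_curve,
                    "valid": profile.valid,
                }
            ).to_csv(out_dir / "profile.csv", index=False)
            summary["profile"] = {"a1": profile.a1, "a2": profile.a2}

        if config.do_ratios:
            ratios = _stage("ratios")(cm_ratio_profile)(
                headings, config.dt, config.ratio_thetas,
                delta_theta=config.delta_theta, seed=int(config.seed),
            )
            ratios.table.to_csv(out_dir / "ratios.csv", index=False)
            summary["ratios"] = {
                "verdicts": _jsonable(ratios.verdicts),
                "slopes": _jsonable(ratios.slopes),
            }

        if config.do_recognize:
            thermal = ThermalStep(d_rot=fit.params.d_rot, dt=config.dt)
            thr = _stage("recognize")(np_thresholds)(
                fit.params.tumble_dist, thermal, config.alpha1
            )
            calls = systematic_recognize(
                headings, config.dt, thr, thermal, fit.params.tumble_dist
            )
            calls.to_csv(out_dir / "tumble_calls.csv", index=False)
            summary["recognizer"] = _jsonable(thr)

        with open(out_dir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
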