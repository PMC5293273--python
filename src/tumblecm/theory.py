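"""Closed-form absolute conditional moments of the shot-noise heading model.

The n-th absolute conditional moment (CM) over a lag ``dt`` is

    m^n = < |Theta(t+dt) - Theta(t)|_a^n > / dt,

a finite-lag, absolute-value analogue of a Kramers-Moyal coefficient. For a
heading driven by Poisson tumbling (rate ``lambda``, angle magnitudes with
moments ``<|beta|^n>``) plus rotational diffusion ``D_rot``, to leading order
in ``lambda*dt`` and ``D_rot*dt``:

    m^1 = lambda <|beta|>   + 2 (1 - lambda dt) sqrt(D_rot / (pi dt))
    m^2 = 2 D_rot           + lambda <beta^2>
    m^3 = lambda <|beta|^3> + (1 - lambda dt) (2 D_rot dt)^{3/2} 2 sqrt(2/pi) / dt
                            + 6 lambda D_rot dt <|beta|>
    m^4 = lambda (<beta^4> + 12 D_rot dt <beta^2>)
    m^6 = lambda (<beta^6> + 30 D_rot dt <beta^4>)
    m^8 = lambda (<beta^8> + 56 D_rot dt <beta^6>)

The n=2 expression is exact (no dt truncation); even orders 4..8 keep only
terms linear in ``D_rot*dt``; odd orders assume tumble angles dominate the
Brownian step within one lag. Validity requires ``lambda*dt < 1`` (at most
one tumble per lag, up to O((lambda dt)^2) corrections) and angular steps
small against the wrap-around at pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distributions import ThermalStep, TumbleAngleDistribution, thermal_abs_moment

__all__ = ["MotilityParams", "CMVector", "theoretical_cms", "cm_ratio_theoretical"]

DEFAULT_ORDERS: tuple[int, ...] = (1, 2, 3, 4, 6, 8)

# coefficient of the mixed term lambda * D_rot * dt * <beta^{n-2}>:
# binom(n, 2) * 2 for even n
_MIXED_COEF = {4: 12.0, 6: 30.0, 8: 56.0}


@dataclass(frozen=True)
class MotilityParams:
    """The inference target: tumble rate, rotational diffusion, angle law."""

    lambda_rate: float
    d_rot: float
    tumble_dist: TumbleAngleDistribution

    def __post_init__(self):
        if self.lambda_rate < 0:
            raise ValueError("lambda_rate must be non-negative")
        if self.d_rot < 0:
            raise ValueError("d_rot must be non-negative")


@dataclass(frozen=True)
class CMVector:
    """Conditional moments for a set of orders at a common lag."""

    orders: tuple[int, ...]
    values: np.ndarray
    dt: float


def theoretical_cms(
    params: MotilityParams,
    dt: float,
    orders: Sequence[int] = DEFAULT_ORDERS,
) -> CMVector:
    """Evaluate the closed-form CMs for orders within {1, 2, 3, 4, 6, 8}."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam, d = params.lambda_rate, params.d_rot
    if lam * dt >= 1.0:
        raise ValueError(
            f"lambda*dt = {lam * dt:.3f} >= 1 breaks the small-probability "
            "tumbling assumption"
        )
    bad = set(orders) - {1, 2, 3, 4, 6, 8}
    if bad:
        raise ValueError(f"no closed form for orders {sorted(bad)}")

    dist = params.tumble_dist
    step = ThermalStep(d_rot=d, dt=dt) if d > 0 else None
    vals = np.empty(len(orders))
    for i, n in enumerate(orders):
        if n == 1:
            brown = thermal_abs_moment(1, step) / dt if step else 0.0
            vals[i] = lam * dist.moment(1) + (1.0 - lam * dt) * brown
        elif n == 2:
            vals[i] = 2.0 * d + lam * dist.moment(2)
        elif n == 3:
            brown = thermal_abs_moment(3, step) / dt if step else 0.0
            vals[i] = (
                lam * dist.moment(3)
                + (1.0 - lam * dt) * brown
                + 6.0 * lam * d * dt * dist.moment(1)
            )
        else:
            vals[i] = lam * (
                dist.moment(n) + _MIXED_COEF[n] * d * dt * dist.moment(n - 2)
            )
    return CMVector(orders=tuple(orders), values=vals, dt=dt)


def cm_ratio_theoretical(
    params_a: MotilityParams, params_b: MotilityParams, n: int
) -> float:
    """Large-order CM ratio ``lambda_a <|beta|^n>_a / (lambda_b <|beta|^n>_b)``.

    For n > 3 the CMs are dominated by the leading shot-noise term, so the
    ratio of CMs at two conditioning angles reduces to this expression: flat
    in n for a pure rate bias, increasing in n when the reference (denominator)
    distribution has the smaller mean angle.
    """
    if n <= 3:
        raise ValueError("the leading-term ratio is only valid for n > 3")
    denom = params_b.lambda_rate * params_b.tumble_dist.moment(n)
    if denom == 0:
        raise ZeroDivisionError("reference CM is zero")
    return params_a.lambda_rate * params_a.tumble_dist.moment(n) / denom
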