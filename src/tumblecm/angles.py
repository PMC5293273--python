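"""Circular-angle arithmetic.

All angles are dimensionless radians. Heading series are kept unbounded
(cumulative); only *differences* of headings are wrapped. Two reductions are
used throughout:

* :func:`wrap_signed` maps a signed angular difference into ``(-pi, pi]``.
* :func:`abs_wrap` maps any angle to the turning magnitude
  ``|alpha|_a = min(|alpha|, 2*pi - |alpha|)`` in ``[0, pi]``, the quantity the
  absolute conditional moments are built from.
"""

from __future__ import annotations

import numpy as np

__all__ = ["abs_wrap", "wrap_signed"]


def wrap_signed(alpha):
    """Reduce a signed angle (difference) to the interval ``(-pi, pi]``.

    Parameters
    ----------
    alpha : float or array_like
        Angle(s) in radians. Must be finite.

    Returns
    -------
    float or ndarray
        Equivalent angle(s) in ``(-pi, pi]``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("wrap_signed requires finite angles")
    wrapped = -np.remainder(-alpha + np.pi, 2.0 * np.pi) + np.pi
    return wrapped if wrapped.ndim else float(wrapped)


def abs_wrap(alpha):
    """Turning magnitude ``min(|alpha mod 2pi|, 2pi - |alpha mod 2pi|)``.

    Even, 2*pi-periodic, bounded by pi; ``abs_wrap(pi) == pi``.

    Parameters
    ----------
    alpha : float or array_like
        Angle(s) in radians. Must be finite.

    Returns
    -------
    float or ndarray
        Magnitude(s) in ``[0, pi]``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("abs_wrap requires finite angles")
    a = np.abs(alpha) % (2.0 * np.pi)
    out = np.minimum(a, 2.0 * np.pi - a)
    return out if out.ndim else float(out)
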