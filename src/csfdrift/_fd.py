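"""Finite-difference and quadrature helpers shared by the solvers.

All grids are uniform: x and eta include both endpoints, s is periodic
without a duplicated endpoint.  Derivatives are second order: centred in
the interior, one-sided three-point stencils at the x/eta ends, periodic
wrap in s.  Integrals use the trapezoidal rule (periodic trapezoid = the
rectangle rule in s).
"""

from __future__ import annotations

import numpy as np


def ddx(f: np.ndarray, dx: float, axis: int = 0) -> np.ndarray:
    """Second-order derivative along a bounded uniform axis."""
    f = np.asarray(f)
    out = np.empty_like(f, dtype=np.result_type(f, float))
    fm = np.moveaxis(f, axis, 0)
    om = np.moveaxis(out, axis, 0)
    om[1:-1] = (fm[2:] - fm[:-2]) / (2.0 * dx)
    om[0] = (-3.0 * fm[0] + 4.0 * fm[1] - fm[2]) / (2.0 * dx)
    om[-1] = (3.0 * fm[-1] - 4.0 * fm[-2] + fm[-3]) / (2.0 * dx)
    return out


def dds_periodic(f: np.ndarray, ds: float, axis: int = -1) -> np.ndarray:
    """Second-order centred derivative along a periodic axis."""
    return (np.roll(f, -1, axis=axis) - np.roll(f, 1, axis=axis)) / (2.0 * ds)


def trapz(f: np.ndarray, dx: float, axis: int = 0) -> np.ndarray:
    """Trapezoidal integral along a bounded axis (endpoints included)."""
    return np.trapezoid(f, dx=dx, axis=axis)


def trapz_periodic(f: np.ndarray, ds: float, axis: int = -1) -> np.ndarray:
    """Integral over one period of a periodic axis (no duplicated endpoint)."""
    return np.sum(f, axis=axis) * ds


def cumtrapz0(f: np.ndarray, dx: float, axis: int = 0) -> np.ndarray:
    """Cumulative trapezoidal integral starting at 0 at the first node."""
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(f, dx=dx, axis=axis, initial=0.0)


def cumtrapz0_periodic(f: np.ndarray, ds: float, axis: int = -1) -> np.ndarray:
    """Cumulative integral from s=0 along a periodic axis.

    Node j holds the trapezoidal integral over [0, s_j]; the first node is 0.
    The value that a (virtual) duplicated endpoint s=1 would carry is the
    full-period integral, obtainable from :func:`trapz_periodic`.
    """
    f = np.moveaxis(np.asarray(f), axis, -1)
    seg = 0.5 * (f + np.roll(f, -1, axis=-1)) * ds  # integral of [s_j, s_{j+1}]
    out = np.zeros_like(f, dtype=np.result_type(f, float))
    out[..., 1:] = np.cumsum(seg[..., :-1], axis=-1)
    return np.moveaxis(out, -1, axis)


def trapz_weights(n: int, dx: float) -> np.ndarray:
    w = np.full(n, dx)
    w[0] = w[-1] = 0.5 * dx
    return w
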