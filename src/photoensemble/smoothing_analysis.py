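"""Closed-form analysis of the assimilation reduction imposed by smoothing.

Quadratic (non-rectangular hyperbola) co-limitation always returns a gross
rate at or below the minimum of the potentially limiting rates.  The largest
reduction occurs at exact co-limitation: with rates normalized to 1, the
single-stage scalar is (1 - sqrt(1-θ))/θ, and the two-stage scalar follows by
smoothing the first-stage result against the third (equal) rate.
"""

from __future__ import annotations

import numpy as np

from .photo_core import smaller_root

__all__ = ["two_rate_scalar", "colimitation_scalar", "reduction_surface"]


def two_rate_scalar(theta):
    """Smoothing scalar at exact two-rate co-limitation, (1 - sqrt(1-θ))/θ.

    θ = 1 gives 1 (no reduction); the θ → 0 rectangular-hyperbola limit is
    0.5 (equal rates halve), returned exactly at θ = 0.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    # algebraically identical cancellation-free form, exact at θ = 0
    return (1.0 / (1.0 + np.sqrt(1.0 - theta)))[()]


def colimitation_scalar(theta_cj, theta_cjp):
    """Two-stage smoothing scalar at exact triple co-limitation.

    With the three rates normalized to 1: stage one smooths the first pair,
    stage two smooths that latent value against the third rate.
    """
    s1 = two_rate_scalar(theta_cj)
    return smaller_root(theta_cjp, s1, np.ones_like(np.asarray(s1, dtype=float)))[()]


def reduction_surface(ac_grid, aj_grid, ap, theta_cj, theta_cjp):
    """Percent reduction of A_g by smoothing relative to the minimum rule.

    Evaluated on the outer grid of ``ac_grid`` × ``aj_grid`` at a fixed TPU
    rate ``ap`` (pass ``None`` to omit the third rate).  Returns
    100·(min - smoothed)/min, which is ≥ 0 everywhere and maximal where the
    rates are equal.
    """
    ac = np.asarray(ac_grid, dtype=float)[:, None]
    aj = np.asarray(aj_grid, dtype=float)[None, :]
    if np.any(ac <= 0) or np.any(aj <= 0) or (ap is not None and ap <= 0):
        raise ValueError("rates must be > 0")
    smoothed = smaller_root(theta_cj, ac, aj)
    mn = np.minimum(ac, aj)
    if ap is not None:
        smoothed = smaller_root(theta_cjp, smoothed, np.asarray(ap, dtype=float))
        mn = np.minimum(mn, ap)
    return 100.0 * (mn - smoothed) / mn
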