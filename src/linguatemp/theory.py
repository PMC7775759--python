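"""Closed-form stationary theory of the lattice transmission model.

In the stationary state of the noisy two-state voter dynamics the feature
frequency rho and the isogloss density sigma obey

    rho   = [(1-q) p_I + q p_I'] / [(1-q) p + q p']
    sigma = 2 H(tau) rho (1 - rho)
    H(tau) = pi (1+tau) / (2 K(1/(1+tau))) - tau
    tau   = [(1-q) p + q p'] / [q (1 - p')]

where p = p_I + p_E and p' = p_I' + p_E' are the total vertical and
horizontal error rates, K is the complete elliptic integral of the first
kind in the *modulus* convention, and tau is the temperature: the ratio of
unfaithful to faithful transmission events.  K is evaluated with the
arithmetic-geometric mean, which is immune to the modulus-vs-parameter
argument ambiguity of library routines.

H is strictly increasing from 0 (tau -> 0, ordered field) to 1
(tau -> infinity, spatially independent field, sigma -> 2 rho (1-rho)).
Inverting H numerically turns an observed (rho, sigma) pair into a
temperature estimate.  Note that H(tau) -> 0 only logarithmically,
H ~ pi / (2 ln(4/sqrt(2 tau))), so the inversion is increasingly
ill-conditioned for very cold features.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .params import FeatureParams

__all__ = [
    "elliptic_K",
    "stationary_frequency",
    "temperature_from_params",
    "interface_factor",
    "analytic_isogloss_density",
    "invert_interface_factor",
    "temperature_from_stats",
    "UndefinedFrequencyError",
]

#: Bracketing interval (in tau) for the numerical inversion of H.
_TAU_LO = 1e-9
_TAU_HI = 1e6


class UndefinedFrequencyError(ValueError):
    """The stationary frequency is undefined (all error rates zero)."""


def elliptic_K(k: float) -> float:
    """Complete elliptic integral of the first kind, modulus convention.

    Computed as K(k) = pi / (2 * AGM(1, sqrt(1 - k^2))).  The AGM
    iteration converges quadratically; machine precision is reached in
    at most a few dozen iterations for any k in [0, 1).

    Parameters
    ----------
    k : float
        Modulus, 0 <= k < 1.  (Not the parameter m = k^2.)

    Raises
    ------
    ValueError
        If k < 0 or k >= 1 (K diverges logarithmically as k -> 1).
    """
    if not 0.0 <= k < 1.0:
        raise ValueError(f"elliptic modulus must be in [0, 1), got {k!r}")
    a, b = 1.0, math.sqrt(1.0 - k * k)
    for _ in range(64):
        if abs(a - b) <= 1e-16 * a:
            break
        a, b = 0.5 * (a + b), math.sqrt(a * b)
    return math.pi / (2.0 * a)


def stationary_frequency(params: FeatureParams) -> float:
    """Stationary feature frequency rho implied by the transmission rates."""
    num = (1.0 - params.q_horizontal_rate) * params.p_ingress_vertical + \
        params.q_horizontal_rate * params.p_ingress_horizontal
    den = (1.0 - params.q_horizontal_rate) * params.total_vertical_error + \
        params.q_horizontal_rate * params.total_horizontal_error
    if den == 0.0:
        raise UndefinedFrequencyError(
            "stationary frequency undefined: all error rates are zero")
    return num / den


def temperature_from_params(params: FeatureParams) -> float:
    """Temperature tau = (mutation rate) / (faithful horizontal rate).

    Returns ``math.inf`` when q = 0 (no horizontal coupling: an iid field,
    formally infinite temperature).
    """
    q = params.q_horizontal_rate
    ph = params.total_horizontal_error
    if ph >= 1.0:
        raise ValueError("total horizontal error p' must be < 1 for finite tau")
    if q == 0.0:
        return math.inf
    p = params.total_vertical_error
    return ((1.0 - q) * p + q * ph) / (q * (1.0 - ph))


def interface_factor(tau: float) -> float:
    """Interface factor H(tau), the height of the sigma-vs-rho parabola.

    H(tau) = pi (1+tau) / (2 K(1/(1+tau))) - tau, strictly increasing on
    (0, inf) with range (0, 1).  Limits: H(0) = 0, H(inf) = 1.
    """
    if tau < 0.0 or math.isnan(tau):
        raise ValueError(f"temperature must be >= 0, got {tau!r}")
    if tau == 0.0:
        return 0.0
    if math.isinf(tau):
        return 1.0
    k = 1.0 / (1.0 + tau)
    return math.pi * (1.0 + tau) / (2.0 * elliptic_K(k)) - tau


def analytic_isogloss_density(rho: float, tau: float) -> float:
    """Stationary isogloss density sigma = 2 H(tau) rho (1 - rho).

    Symmetric under rho -> 1 - rho and bounded by the random-field
    parabola 2 rho (1 - rho) <= 1/2.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {rho!r}")
    return 2.0 * interface_factor(tau) * rho * (1.0 - rho)


def invert_interface_factor(H_obs: float, *, rtol: float = 1e-10) -> float:
    """Unique tau with H(tau) = H_obs, by monotone bracketing on log tau.

    Degenerate inputs are resolved as flagged special values rather than
    clamped: H_obs <= 0 gives 0.0 (frozen field), H_obs >= 1 gives
    ``math.inf`` (spatially independent field).
    """
    if H_obs <= 0.0:
        return 0.0
    if H_obs >= 1.0:
        return math.inf
    lo, hi = _TAU_LO, _TAU_HI
    if interface_factor(lo) >= H_obs:
        return lo
    if interface_factor(hi) <= H_obs:
        return hi
    log_tau = brentq(
        lambda x: interface_factor(10.0 ** x) - H_obs,
        math.log10(lo), math.log10(hi), xtol=1e-13, rtol=8.9e-16)
    return 10.0 ** log_tau


def temperature_from_stats(rho: float, sigma: float) -> float:
    """Infer tau from an observed (rho, sigma) summary pair.

    tau = H^{-1}( sigma / (2 rho (1 - rho)) ).  Returns ``math.inf`` when
    sigma >= 2 rho (1-rho) (the observation is at or beyond the random-field
    parabola).

    Raises
    ------
    ValueError
        If rho is 0 or 1 (the parabola degenerates and tau is undefined).
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(
            f"temperature undefined at degenerate frequency rho={rho!r}")
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"isogloss density must be in [0, 1], got {sigma!r}")
    H_obs = sigma / (2.0 * rho * (1.0 - rho))
    return invert_interface_factor(H_obs)


def theory_curve(tau: float, n_points: int = 101) -> np.ndarray:
    """Tabulate the (rho, sigma) parabola for a given temperature.

    Returns an (n_points, 2) array of (rho, sigma) pairs.
    """
    rho = np.linspace(0.0, 1.0, n_points)
    h = interface_factor(tau)
    return np.column_stack([rho, 2.0 * h * rho * (1.0 - rho)])
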