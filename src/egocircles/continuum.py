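"""Continuum limit of the layered resource-allocation model.

In the limit of infinitely many cost layers, an alter is indexed by a
normalized "distance" ``t in [0, 1]`` (``t = 0`` is the most costly tie,
``t = 1`` the cheapest), and the maximum-entropy allocation of links follows
the truncated-exponential density

    eps(t) = eta * exp(eta * t) / (exp(eta) - 1),

with cumulative circle function ``chi(t) = (exp(eta*t) - 1)/(exp(eta) - 1)``.
The scaling parameter ``eta`` is tied to the mean normalized distance
``t_bar`` through the implicit cost equation ``t_bar = g(eta)`` where

    g(eta) = e^eta / (e^eta - 1) - 1/eta.

``eta > 0`` is the ordinary regime (outer circles progressively larger, the
classic Dunbar-circle scaling); ``eta < 0`` is the inverse regime with an
overpopulated innermost circle.  The discrete r-layer model maps onto this
description via ``eta ~ (r - 1)(e^mu - 1)``; with r = 4 circles and the
empirically ubiquitous layer ratio e^mu ~ 3 this predicts eta ~ 6.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .exceptions import DegenerateSummaryError, DomainError

__all__ = [
    "g",
    "solve_eta",
    "epsilon_density",
    "chi_cdf",
    "eta_from_discrete",
    "log_derivative_chi",
]

# Below this |eta| the closed form of g suffers catastrophic cancellation
# between 1/expm1(eta) and 1/eta; the odd series in eta takes over.
_G_SERIES_SWITCH = 1e-4

# Paper-convention threshold for the removable singularity of chi/eps:
# |e^eta - 1| <= 1e-6, i.e. essentially |eta| <= 1e-6.
_CHI_SERIES_SWITCH = 1e-6

# solve_eta returns exactly 0 when t is indistinguishable from 1/2.
_HALF_TOL = 1e-12


def g(eta: float) -> float:
    """Mean normalized distance implied by scaling parameter ``eta``.

    ``g(eta) = e^eta/(e^eta - 1) - 1/eta``, extended by continuity to
    ``g(0) = 1/2``.  Strictly increasing from 0 (eta -> -inf) to 1
    (eta -> +inf), and satisfies the reflection identity
    ``g(eta) + g(-eta) = 1``.

    Parameters
    ----------
    eta : float
        Scaling parameter, any real value.

    Returns
    -------
    float
        Value in (0, 1).
    """
    eta = float(eta)
    if abs(eta) <= _G_SERIES_SWITCH:
        # g(eta) = 1/2 + eta/12 - eta^3/720 + eta^5/30240 - ...
        return 0.5 + eta / 12.0 - eta**3 / 720.0
    if eta < 0.0:
        return 1.0 - g(-eta)
    # eta > 0: e^eta/(e^eta-1) = 1 + e^-eta/(1 - e^-eta), overflow-free.
    em = math.expm1(-eta)  # in (-1, 0)
    return 1.0 + math.exp(-eta) / (-em) - 1.0 / eta


def solve_eta(t: float, *, xtol: float = 1e-10) -> float:
    """Invert the implicit cost equation: the unique eta with ``g(eta) = t``.

    Parameters
    ----------
    t : float
        Mean normalized distance, strictly inside (0, 1).
    xtol : float, optional
        Absolute tolerance of the bracketed root search (well inside the
        1e-6 contract).

    Returns
    -------
    float
        The root; its sign equals ``sign(t - 1/2)``, and ``t`` within 1e-12
        of 1/2 returns exactly 0.0.

    Raises
    ------
    DegenerateSummaryError
        If ``t`` lies outside the open interval (0, 1).
    """
    t = float(t)
    if not 0.0 < t < 1.0 or not math.isfinite(t):
        raise DegenerateSummaryError(
            f"mean normalized distance t={t!r} must lie strictly in (0, 1); "
            "the implicit equation g(eta) = t has no finite solution"
        )
    if abs(t - 0.5) < _HALF_TOL:
        return 0.0
    # Monotonicity of g guarantees a sign change under bracket doubling.
    lo, hi = -1.0, 1.0
    while g(hi) < t:
        hi *= 2.0
    while g(lo) > t:
        lo *= 2.0
    return brentq(lambda x: g(x) - t, lo, hi, xtol=xtol)


def chi_cdf(t, eta: float):
    """Circle function: fraction of links at normalized distance <= ``t``.

    ``chi(t) = (e^{eta t} - 1)/(e^eta - 1)``, with the eta -> 0 limit
    ``chi(t) = t`` taken through the quadratic expansion
    ``t + (eta/2) t (t - 1)`` when ``|e^eta - 1| <= 1e-6``.

    Parameters
    ----------
    t : float or array_like
        Normalized distance(s) in [0, 1].
    eta : float
        Scaling parameter.

    Returns
    -------
    float or ndarray
        chi(t), nondecreasing in ``t`` with chi(0) = 0 and chi(1) = 1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0.0) | (t_arr > 1.0)):
        raise DomainError("normalized distance t must lie in [0, 1]")
    eta = float(eta)
    if abs(math.expm1(eta) if abs(eta) < 1.0 else 2.0 * eta) <= _CHI_SERIES_SWITCH:
        out = t_arr + 0.5 * eta * t_arr * (t_arr - 1.0)
    elif eta > 700.0:
        # expm1(eta) would overflow; the -1 terms are negligible here.
        out = np.exp(eta * (t_arr - 1.0))
    else:
        out = np.expm1(eta * t_arr) / np.expm1(eta)
    return out if out.ndim else float(out)


def epsilon_density(t, eta: float):
    """Link density over normalized distance: ``eps(t) = chi'(t)``.

    ``eps(t) = eta e^{eta t}/(e^eta - 1)``; normalized to unit mass on
    [0, 1] for every real eta, with the uniform limit eps = 1 at eta = 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0.0) | (t_arr > 1.0)):
        raise DomainError("normalized distance t must lie in [0, 1]")
    eta = float(eta)
    if abs(math.expm1(eta) if abs(eta) < 1.0 else 2.0 * eta) <= _CHI_SERIES_SWITCH:
        out = 1.0 + eta * (t_arr - 0.5)
    elif eta > 0.0:
        # eta * e^{eta(t-1)} / (1 - e^{-eta}): safe for arbitrarily large eta.
        out = eta * np.exp(eta * (t_arr - 1.0)) / (-np.expm1(-eta))
    else:
        out = eta * np.exp(eta * t_arr) / np.expm1(eta)
    return out if out.ndim else float(out)


def eta_from_discrete(mu: float, r: int) -> float:
    """Continuum scaling parameter equivalent to an r-layer model with ``mu``.

    ``eta ~ (r - 1)(e^mu - 1)``.  With the canonical four Dunbar circles
    (r = 4) and layer ratio e^mu = 3 this gives the headline prediction
    eta = 6.
    """
    r = int(r)
    if r < 2:
        raise DomainError("need at least r = 2 layers")
    return (r - 1) * math.expm1(mu)


def log_derivative_chi(t: float, eta: float) -> float:
    """Logarithmic derivative ``chi'(t)/chi(t) = eta e^{eta t}/(e^{eta t} - 1)``.

    Tends to ``eta`` for large positive eta (the geometric circle scaling)
    and to 0 for eta -> -inf; diverges like 1/t at t = 0.

    Raises
    ------
    DomainError
        If ``t`` is not in (0, 1] (t = 0 is a pole).
    """
    t = float(t)
    if not 0.0 < t <= 1.0:
        raise DomainError("t must lie in (0, 1]; t = 0 is a pole")
    x = eta * t
    if abs(x) <= 1e-8:
        # eta e^x/(e^x - 1) = 1/t + eta/2 + O(eta^2 t)
        return 1.0 / t + eta / 2.0
    if x > _CHI_SERIES_SWITCH and x > 34.0:
        return eta * (1.0 + math.exp(-x))
    return eta + eta / math.expm1(x)
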