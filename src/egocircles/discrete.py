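"""The r-layer maximum-entropy model of costly link allocation.

An ego distributes L links over r cost categories ("layers"); layer k = 1 is
the most costly (innermost), k = r the least costly.  With costs on a uniform
grid, the maximum-entropy distribution of layer occupancies is multinomial
with geometric cell probabilities controlled by a single parameter ``mu``,
and the mean cost per link ``sigma`` fixes ``mu`` through a softmin-weighted
mean.  Expected layer fractions and the cumulative "circles" follow in
closed form and converge, as r grows, to the continuum model in
:mod:`egocircles.continuum`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, softmax

from ._stability import log_expm1_ratio
from .exceptions import DomainError, NoSolutionError, ScaleError, ValidationError

__all__ = [
    "DiscreteSpec",
    "LayerCounts",
    "cost_grid",
    "sigma_from_mu",
    "mu_from_sigma",
    "layer_fractions",
    "log_pmf",
]

# Paper-convention Taylor switch for the removable singularity at mu = 0.
_TAYLOR_SWITCH = 1e-6


@dataclass(frozen=True)
class DiscreteSpec:
    """Parameters of an r-layer model.

    Attributes
    ----------
    r : int
        Number of layers, at least 2.
    mu : float
        Layer-scaling exponent; e^mu is the ratio between the expected
        occupancies of consecutive layers.
    sigma : float
        Mean cost per link (total resource / total links).
    s_min, s_max : float
        Cost bounds; layer 1 costs ``s_max``, layer r costs ``s_min``.
    """

    r: int
    mu: float
    sigma: float
    s_min: float = 0.0
    s_max: float = 1.0

    def __post_init__(self) -> None:
        if int(self.r) != self.r or self.r < 2:
            raise ValidationError(f"r must be an integer >= 2, got {self.r!r}")
        if not self.s_max > self.s_min:
            raise ScaleError(f"need s_max > s_min, got ({self.s_min}, {self.s_max})")

    @property
    def costs(self) -> np.ndarray:
        return cost_grid(self.r, self.s_min, self.s_max)


@dataclass(frozen=True)
class LayerCounts:
    """Observed layer occupancies ``ell_1 ... ell_r`` of one ego."""

    counts: np.ndarray = field()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 1 or counts.size < 2:
            raise ValidationError("counts must be a vector of length r >= 2")
        if np.any(counts < 0) or np.any(counts != np.asarray(self.counts)):
            raise ValidationError("layer counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def r(self) -> int:
        return self.counts.size

    @property
    def L(self) -> int:
        """Total number of links."""
        return int(self.counts.sum())

    @property
    def L1(self) -> int:
        """Weighted moment ``sum_k (k - 1) ell_k``."""
        return int(np.arange(self.r) @ self.counts)


def cost_grid(r: int, s_min: float, s_max: float) -> np.ndarray:
    """Uniform cost grid ``s_k = s_max - (s_max - s_min)(k - 1)/(r - 1)``.

    Returns the r costs in layer order: ``s_1 = s_max`` down to
    ``s_r = s_min`` with constant spacing.
    """
    if int(r) != r or r < 2:
        raise DomainError(f"r must be an integer >= 2, got {r!r}")
    if not s_max > s_min:
        raise ScaleError(f"need s_max > s_min, got ({s_min}, {s_max})")
    return np.linspace(float(s_max), float(s_min), int(r))


def sigma_from_mu(mu_hat: float, costs) -> float:
    """Softmin-weighted mean cost at exponent ``mu_hat``.

    ``sigma = sum_k s_k e^{-mu_hat s_k} / sum_k e^{-mu_hat s_k}`` — the
    forward map whose inversion defines :func:`mu_from_sigma`.  Decreasing
    in ``mu_hat``; evaluated through a softmax for overflow safety.
    """
    costs = np.asarray(costs, dtype=float)
    return float(softmax(-float(mu_hat) * costs) @ costs)


def mu_from_sigma(sigma: float, costs, *, xtol: float = 1e-10) -> float:
    """Invert the mean-cost relation: the unique ``mu_hat`` matching ``sigma``.

    Parameters
    ----------
    sigma : float
        Target mean cost per link; must lie strictly between min and max of
        ``costs``.
    costs : array_like
        Cost vector ``s_k`` (any layout; typically :func:`cost_grid`).
    xtol : float, optional
        Root-search tolerance (contract is 1e-6; default is tighter).

    Raises
    ------
    NoSolutionError
        If ``sigma`` is not strictly inside (min(costs), max(costs)).
    """
    costs = np.asarray(costs, dtype=float)
    sigma = float(sigma)
    if not costs.min() < sigma < costs.max():
        raise NoSolutionError(
            f"sigma={sigma} outside the open cost range "
            f"({costs.min()}, {costs.max()}); no mu_hat solves the relation"
        )

    def f(m: float) -> float:
        return sigma_from_mu(m, costs) - sigma

    lo, hi = -1.0, 1.0
    # sigma_from_mu is decreasing: f(lo) > 0 > f(hi) once the bracket is wide.
    while f(lo) < 0.0:
        lo *= 2.0
    while f(hi) > 0.0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=xtol)


def layer_fractions(mu: float, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Expected layer fractions and circles of the r-layer model.

    ``eps_k = (e^{k mu} - e^{(k-1) mu})/(e^{r mu} - 1)`` is the expected
    fraction of links in layer k (k = 1 innermost/most costly), and
    ``chi_k = (e^{k mu} - 1)/(e^{r mu} - 1)`` the cumulative circle sizes,
    with ``chi_r = 1``.  Near mu = 0 the removable singularity is crossed on
    the Taylor form ``chi_k ~ k/r + (k/2r)(e^mu - 1)(k - r)``.

    Returns
    -------
    (ndarray, ndarray)
        ``(eps, chi)``, each of length r.
    """
    if int(r) != r or r < 2:
        raise DomainError(f"r must be an integer >= 2, got {r!r}")
    r = int(r)
    mu = float(mu)
    k = np.arange(1, r + 1, dtype=float)
    em1 = math.expm1(mu) if abs(mu) < 700.0 else math.inf
    if abs(em1) <= _TAYLOR_SWITCH:
        chi = k / r + (k / (2.0 * r)) * em1 * (k - r)
        eps = np.diff(chi, prepend=0.0)
    else:
        # Elementwise on the log scale: both expm1 factors share mu's sign,
        # so each ratio is positive and at most 1.
        log_chi = log_expm1_ratio(k * mu, r * mu)
        log_eps = (k - 1.0) * mu + log_expm1_ratio(mu, r * mu)
        chi = np.exp(log_chi)
        eps = np.exp(log_eps)
    return eps, chi


def log_pmf(counts: LayerCounts, mu: float, r: int | None = None) -> float:
    """Log-probability of observed layer counts under the r-layer model.

    ``P(ell | mu, L) = [(e^mu - 1)/(e^{mu r} - 1)]^L * multinomial(L; ell)
    * e^{mu L1}`` with ``L1 = sum_k (k-1) ell_k``.  At mu = 0 this is the
    uniform multinomial.
    """
    if not isinstance(counts, LayerCounts):
        counts = LayerCounts(np.asarray(counts))
    if r is not None and int(r) != counts.r:
        raise ValidationError(
            f"counts have r={counts.r} layers but r={r} was requested"
        )
    mu = float(mu)
    L, L1 = counts.L, counts.L1
    log_coeff = float(gammaln(L + 1) - gammaln(counts.counts + 1).sum())
    if mu == 0.0:
        log_cell = -math.log(counts.r)
    else:
        log_cell = float(log_expm1_ratio(mu, counts.r * mu))
    return L * log_cell + log_coeff + mu * L1
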