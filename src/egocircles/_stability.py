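"""Overflow- and cancellation-safe primitives shared by the model modules.

Every formula in the package involves ratios of ``e^x - 1`` terms whose naive
evaluation overflows for ``|x|`` of a few hundred or loses all precision near
the removable singularity at ``x = 0``.  The helpers here evaluate logarithms
of those quantities directly, so downstream code can work on the log scale
throughout and exponentiate only at the very end.
"""

from __future__ import annotations

import numpy as np

# exp(x) overflows just above 709; log(expm1(x)) == x to double precision
# well before that.
_EXPM1_LOG_SWITCH = 34.0


def log_abs_expm1(x):
    """log|e^x - 1| for real ``x`` (scalar or array), overflow-safe.

    For ``x > 34`` the result is ``x`` exactly at double precision; elsewhere
    ``np.expm1`` is accurate even for tiny ``|x|``.  ``x == 0`` maps to -inf.
    """
    x = np.asarray(x, dtype=float)
    big = x > _EXPM1_LOG_SWITCH
    safe = np.where(big, 0.0, x)
    with np.errstate(divide="ignore"):
        small = np.log(np.abs(np.expm1(safe)))
    out = np.where(big, x, small)
    return out if out.ndim else float(out)


def log_expm1_ratio(a, b):
    """log[(e^a - 1)/(e^b - 1)] where ``a`` and ``b`` share their sign.

    The ratio is positive whenever ``a`` and ``b`` have the same sign, which
    is the only case the layered model produces (``a = mu``, ``b = r*mu``).
    """
    return log_abs_expm1(a) - log_abs_expm1(b)


def log_eta_over_expm1(eta):
    """log[eta / (e^eta - 1)], finite for every real eta, 0 at eta = 0.

    The argument of the log is positive for all real eta (both factors change
    sign together), so this is a total function.  Accurate for tiny |eta|
    because ``expm1`` is, and overflow-safe for large |eta| via the linear
    branch of :func:`log_abs_expm1`.
    """
    eta = np.asarray(eta, dtype=float)
    zero = eta == 0.0
    safe = np.where(zero, 1.0, eta)
    val = np.log(np.abs(safe)) - log_abs_expm1(safe)
    out = np.where(zero, 0.0, val)
    return out if out.ndim else float(out)
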