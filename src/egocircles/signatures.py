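"""Persistence of an ego's scaling parameter across time windows.

If eta is a genuine individual trait, its value for a given ego should vary
less between that ego's consecutive time windows ("self" distances) than it
does between the ego and the rest of the population within one window
("reference" distances).  Distances are relative changes,

    d_self(i; a, a+1) = |eta_a(i) - eta_{a+1}(i)| / |eta_a(i)|,
    d_ref(i; a)       = mean_{j != i} |eta_a(i) - eta_a(j)| / |eta_a(i)|,

pooled across egos and windows and compared with a two-sided Mann-Whitney U
test.  With W windows, self distances use the W - 1 consecutive pairs and
reference distances the W - 1 later windows of each pair, so N egos yield
N x (W - 1) points per distribution (24 egos x 3 windows -> 48 each).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedDistanceError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDistances",
    "self_distance",
    "reference_distance",
    "build_distributions",
    "compare_distributions",
    "eta_size_correlation",
]


@dataclass(frozen=True)
class SignatureDistances:
    """Pooled self and reference eta-distances with per-point provenance."""

    d_self: np.ndarray
    d_ref: np.ndarray
    self_labels: tuple[tuple[str, str, str], ...]  # (ego, window_a, window_b)
    ref_labels: tuple[tuple[str, str], ...]        # (ego, window)
    n_skipped: int = 0


def self_distance(eta_a: float, eta_b: float) -> float:
    """Relative change between the same ego's eta in two windows."""
    if eta_a == 0.0:
        raise UndefinedDistanceError(
            "relative distance undefined for anchor eta = 0"
        )
    return abs(eta_a - eta_b) / abs(eta_a)


def reference_distance(eta_i: float, etas_other: Sequence[float]) -> float:
    """Mean relative deviation of ego i from all other egos, same window."""
    others = np.asarray(etas_other, dtype=float)
    others = others[np.isfinite(others)]
    if others.size < 1:
        raise ValidationError("need at least one other ego with a valid fit")
    if eta_i == 0.0:
        raise UndefinedDistanceError(
            "relative distance undefined for anchor eta = 0"
        )
    return float(np.mean(np.abs(eta_i - others)) / abs(eta_i))


def _as_eta_table(fits) -> pd.DataFrame:
    """Normalize fits input to a (ego_id x window) table of eta values."""
    if isinstance(fits, pd.DataFrame):
        required = {"ego_id", "window", "eta_hat"}
        if not required.issubset(fits.columns):
            raise ValidationError(
                f"fits frame must have columns {sorted(required)}"
            )
        return fits.pivot_table(
            index="ego_id", columns="window", values="eta_hat", aggfunc="first"
        )
    if isinstance(fits, Mapping):
        return pd.DataFrame(fits).T.rename_axis("ego_id")
    raise ValidationError("fits must be a DataFrame or {ego: {window: eta}}")


def build_distributions(
    fits, window_order: Sequence[str] | None = None
) -> SignatureDistances:
    """Pool self and reference distances from per-ego, per-window fits.

    Parameters
    ----------
    fits : DataFrame or mapping
        Long frame with columns ``ego_id, window, eta_hat`` or a nested
        mapping ``{ego_id: {window: eta}}``.  NaN entries mean no valid fit.
    window_order : sequence of str, optional
        Temporal ordering of the windows; defaults to sorted labels.

    Returns
    -------
    SignatureDistances

    Notes
    -----
    Only egos with valid fits in every window enter; others are counted in
    ``n_skipped``.  Egos whose eta changes sign between windows are kept —
    the relative-change formula applies literally and the distance may
    exceed 1.  Anchor eta exactly 0 makes the distance undefined; such egos
    are skipped with a log message.
    """
    table = _as_eta_table(fits)
    windows = list(window_order) if window_order is not None else sorted(table.columns)
    if len(windows) < 2:
        raise ValidationError("need at least 2 time windows")
    missing = [w for w in windows if w not in table.columns]
    if missing:
        raise ValidationError(f"windows {missing} absent from fits")
    table = table[windows].dropna()
    if len(table) < 2:
        raise ValidationError("need at least 2 egos with fits in every window")
    n_skipped = 0
    d_self, self_labels = [], []
    d_ref, ref_labels = [], []
    for ego, row in table.iterrows():
        etas = row.to_numpy(dtype=float)
        try:
            for a in range(len(windows) - 1):
                d_self.append(self_distance(etas[a], etas[a + 1]))
                self_labels.append((str(ego), windows[a], windows[a + 1]))
            for a in range(1, len(windows)):
                others = table.loc[table.index != ego, windows[a]].to_numpy()
                d_ref.append(reference_distance(etas[a], others))
                ref_labels.append((str(ego), windows[a]))
        except UndefinedDistanceError:
            # Roll back this ego's partial contributions.
            d_self = d_self[: len(d_self) - sum(1 for s in self_labels if s[0] == str(ego))]
            self_labels = [s for s in self_labels if s[0] != str(ego)]
            d_ref = [d for d, lab in zip(d_ref, ref_labels) if lab[0] != str(ego)]
            ref_labels = [lab for lab in ref_labels if lab[0] != str(ego)]
            n_skipped += 1
            logger.info("ego %s skipped: eta = 0 in an anchor window", ego)
    return SignatureDistances(
        d_self=np.asarray(d_self, dtype=float),
        d_ref=np.asarray(d_ref, dtype=float),
        self_labels=tuple(self_labels),
        ref_labels=tuple(ref_labels),
        n_skipped=n_skipped,
    )


def compare_distributions(distances: SignatureDistances) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of self vs reference distances.

    Returns ``(U, p)``.  A degenerate input where every value in both
    samples is identical yields p = 1 with a warning instead of an error.
    """
    x, y = distances.d_self, distances.d_ref
    if x.size == 0 or y.size == 0:
        raise ValidationError("both distance samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all distances identical; Mann-Whitney test degenerate, p = 1",
            stacklevel=2,
        )
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def eta_size_correlation(fits: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (two-tailed) between eta-hat and network size.

    Parameters
    ----------
    fits : DataFrame
        Needs columns ``eta_hat`` and ``L_tilde``; rows with NaN in either
        are dropped.
    """
    sub = fits[["eta_hat", "L_tilde"]].dropna()
    if len(sub) < 3:
        raise ValidationError("need >= 3 egos with valid (eta_hat, L_tilde)")
    eta = sub["eta_hat"].to_numpy(dtype=float)
    size = sub["L_tilde"].to_numpy(dtype=float)
    if np.ptp(eta) == 0.0 or np.ptp(size) == 0.0:
        raise ValidationError("correlation undefined: a variable has zero variance")
    res = stats.pearsonr(eta, size)
    return float(res.statistic), float(res.pvalue)
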