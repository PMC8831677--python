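"""Readers, cost-scale heuristics, filtering and per-ego fit orchestration.

Two input conventions are supported:

* **Edge lists** — delimited text with header, one row per (ego, alter,
  weight[, window]) interaction; duplicate rows are aggregated by summation.
  Weights are per-alter resource totals (number of calls, seconds of
  contact, messages).
* **Contact triplets** — SocioPatterns-style rows ``t i j`` from proximity
  sensors that record co-presence in fixed 20-second intervals; each record
  contributes one interval of face time to both participants' records.

The admissible cost range of an ego is not observable directly and must be
set heuristically: either from the overall extremes of its tie weights
(``global_scale``) or, when interactions are sub-labelled by month-like
windows, as the sums of per-window minima and maxima (``windowed_scale``).
Ties weaker than ``s_min`` are discarded as non-relationships, and egos left
with too few alters are excluded rather than fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateScaleError,
    EgocirclesError,
    ImproperPosteriorError,
    ParseError,
    ScaleError,
    ValidationError,
)
from .inference import (
    ContinuumFit,
    confidence_interval,
    mle_eta,
    summarize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Tie",
    "EgoRecord",
    "CostScale",
    "FilterResult",
    "read_edge_list",
    "write_edge_list",
    "read_contact_triplets",
    "windowed_scale",
    "global_scale",
    "filter_ties",
    "fit_ego",
    "fit_population",
    "summary_stats",
]

DEFAULT_COLUMNS = ("ego", "alter", "weight", "window")


class Tie(NamedTuple):
    """One weighted tie of an ego, optionally labelled with a time window."""

    alter: str
    weight: float
    window: str | None = None


@dataclass(frozen=True)
class EgoRecord:
    """One ego's weighted tie list."""

    ego_id: str
    ties: tuple[Tie, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ties = tuple(Tie(str(a), float(w), None if pd.isna(win) else str(win))
                     for a, w, win in self.ties)
        for t in ties:
            if not np.isfinite(t.weight) or t.weight < 0.0:
                raise ValidationError(
                    f"ego {self.ego_id!r}: tie to {t.alter!r} has invalid "
                    f"weight {t.weight!r}"
                )
        object.__setattr__(self, "ties", ties)

    @property
    def windows(self) -> tuple[str, ...]:
        """Distinct window labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for t in self.ties:
            if t.window is not None:
                seen.setdefault(t.window, None)
        return tuple(seen)

    def alter_totals(self) -> dict[str, float]:
        """Per-alter weight totals aggregated across windows."""
        totals: dict[str, float] = {}
        for t in self.ties:
            totals[t.alter] = totals.get(t.alter, 0.0) + t.weight
        return totals


@dataclass(frozen=True)
class CostScale:
    """Admissible cost range ``[s_min, s_max]`` of one ego."""

    s_min: float
    s_max: float
    method: str = "global-extrema"

    def __post_init__(self) -> None:
        if not np.isfinite(self.s_min) or not np.isfinite(self.s_max):
            raise ScaleError(f"non-finite scale ({self.s_min}, {self.s_max})")
        if self.s_min < 0.0:
            raise ScaleError(f"s_min must be >= 0, got {self.s_min}")
        if not self.s_max > self.s_min:
            raise DegenerateScaleError(
                f"degenerate cost scale: s_min={self.s_min} >= s_max={self.s_max}"
            )


class FilterResult(NamedTuple):
    """Outcome of :func:`filter_ties`; exclusion is a result, not an error."""

    record: EgoRecord
    n_removed: int
    excluded: bool


# -- readers -----------------------------------------------------------------


def read_edge_list(
    path,
    delimiter: str = ",",
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> list[EgoRecord]:
    """Read a delimited edge list into per-ego records.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row.
    delimiter : str, optional
        Field separator.
    columns : sequence of str, optional
        Names of the (ego, alter, weight[, window]) columns, in that role
        order.  The window column is optional in the file.

    Returns
    -------
    list of EgoRecord
        Weights summed per (ego, alter, window); egos, alters and windows
        in sorted order so output is deterministic.
    """
    ego_col, alter_col, weight_col = columns[0], columns[1], columns[2]
    window_col = columns[3] if len(columns) > 3 else None
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    if df.empty:
        logger.warning("edge list %r is empty", path)
        return []
    for col in (ego_col, alter_col, weight_col):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r} in {path!r}")
    weights = pd.to_numeric(df[weight_col], errors="coerce")
    bad = weights.isna()
    if bad.any():
        # +2: one for the header, one for 1-based line numbering.
        lines = [int(i) + 2 for i in df.index[bad][:5]]
        raise ParseError(
            f"non-numeric weight(s) in {path!r} at line(s) {lines}"
        )
    if (weights < 0).any():
        lines = [int(i) + 2 for i in df.index[weights < 0][:5]]
        raise ValidationError(f"negative weight(s) in {path!r} at line(s) {lines}")
    use = df[[ego_col, alter_col]].copy()
    use["weight"] = weights.astype(float)
    if window_col is not None and window_col in df.columns:
        use["window"] = df[window_col]
    else:
        use["window"] = None
    grouped = (
        use.groupby([ego_col, alter_col, "window"], dropna=False, sort=True)["weight"]
        .sum()
        .reset_index()
    )
    records: list[EgoRecord] = []
    for ego_id, sub in grouped.groupby(ego_col, sort=True):
        ties = tuple(
            Tie(str(row[alter_col]), float(row["weight"]),
                None if pd.isna(row["window"]) else str(row["window"]))
            for _, row in sub.iterrows()
        )
        records.append(EgoRecord(ego_id=str(ego_id), ties=ties))
    return records


def write_edge_list(records: Sequence[EgoRecord], path, delimiter: str = ",") -> None:
    """Write ego records in the format :func:`read_edge_list` accepts."""
    rows = [
        {"ego": r.ego_id, "alter": t.alter, "weight": t.weight,
         "window": "" if t.window is None else t.window}
        for r in records
        for t in r.ties
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def read_contact_triplets(path, interval_seconds: float = 20.0) -> list[EgoRecord]:
    """Read SocioPatterns-style ``t i j`` proximity records.

    Each row records one fixed-length co-presence interval between badges
    ``i`` and ``j``; the tie weight between two participants is
    ``interval_seconds`` times their number of joint records, credited
    symmetrically to both egos.  Group contacts appear in the data as one
    row per concurrent pair, so no expansion is needed here.  Self-contacts
    are dropped with a warning.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["t", "i", "j"], dtype=str
    )
    if df.empty:
        logger.warning("contact file %r is empty", path)
        return []
    selfies = df["i"] == df["j"]
    if selfies.any():
        logger.warning("dropping %d self-contact record(s)", int(selfies.sum()))
        df = df[~selfies]
    lo = df[["i", "j"]].min(axis=1)
    hi = df[["i", "j"]].max(axis=1)
    counts = pd.DataFrame({"a": lo, "b": hi}).value_counts().sort_index()
    per_ego: dict[str, list[Tie]] = {}
    for (a, b), n in counts.items():
        w = float(n) * interval_seconds
        per_ego.setdefault(str(a), []).append(Tie(str(b), w))
        per_ego.setdefault(str(b), []).append(Tie(str(a), w))
    return [
        EgoRecord(ego_id=ego, ties=tuple(sorted(ties)))
        for ego, ties in sorted(per_ego.items())
    ]


# -- cost-scale heuristics ---------------------------------------------------


def windowed_scale(ego: EgoRecord, windows: Sequence[str] | None = None) -> CostScale:
    """Scale from sums of per-window extrema.

    ``s_max`` (``s_min``) is the sum over sub-windows of the largest
    (smallest) single-tie weight observed in that sub-window — the cost an
    alter would have accrued had it been the extreme alter in every window.
    Minima are taken over observed interactions only; windows with no ties
    are excluded with a warning.
    """
    labels = list(windows) if windows is not None else list(ego.windows)
    if not labels:
        raise ValidationError(
            f"ego {ego.ego_id!r} has no windowed ties; use global_scale"
        )
    s_min = s_max = 0.0
    for label in labels:
        ws = [t.weight for t in ego.ties if t.window == label]
        if not ws:
            logger.warning(
                "ego %s: window %r has no ties; excluded from scale",
                ego.ego_id, label,
            )
            continue
        s_min += min(ws)
        s_max += max(ws)
    return CostScale(s_min=s_min, s_max=s_max, method="windowed-sum")


def global_scale(ego: EgoRecord) -> CostScale:
    """Scale from the overall extremes of the per-alter weight totals."""
    totals = ego.alter_totals()
    if len(totals) < 2:
        raise DegenerateScaleError(
            f"ego {ego.ego_id!r} needs >= 2 alters for a global scale"
        )
    vals = list(totals.values())
    return CostScale(s_min=min(vals), s_max=max(vals), method="global-extrema")


def filter_ties(
    ego: EgoRecord, scale: CostScale, min_alters: int = 5
) -> FilterResult:
    """Drop sub-``s_min`` ties and flag egos left with too few alters.

    Operates on per-alter totals (windows aggregated).  A weight equal to
    ``s_min`` is retained — the boundary alter defines the scale itself
    under the global-extrema heuristic.  Weights above ``s_max`` (possible
    only for hand-built scales) are clamped with a warning.
    """
    totals = ego.alter_totals()
    kept: list[Tie] = []
    for alter in sorted(totals):
        w = totals[alter]
        if w < scale.s_min:
            continue
        if w > scale.s_max:
            logger.warning(
                "ego %s: weight %g for alter %s exceeds s_max=%g; clamped",
                ego.ego_id, w, alter, scale.s_max,
            )
            w = scale.s_max
        kept.append(Tie(alter, w))
    n_removed = len(totals) - len(kept)
    record = EgoRecord(ego_id=ego.ego_id, ties=tuple(kept))
    return FilterResult(record, n_removed, excluded=len(kept) < min_alters)


# -- fit orchestration -------------------------------------------------------


def fit_ego(
    ego: EgoRecord,
    scale_method: str = "global",
    min_alters: int = 5,
    delta: float = 0.025,
    windows: Sequence[str] | None = None,
    compute_ci: bool = True,
    scale: CostScale | None = None,
) -> ContinuumFit:
    """Full per-ego pipeline: scale -> filter -> summarize -> estimate.

    Failures (degenerate scale, too few alters, boundary t_bar) come back as
    fit records with a diagnostic ``status`` and NaN estimates rather than
    exceptions, so population runs are never derailed by a single ego.

    Parameters
    ----------
    ego : EgoRecord
    scale_method : {"global", "windowed"}, optional
        Ignored when an explicit ``scale`` is passed.
    min_alters : int, optional
        Exclusion floor after filtering (0 disables; the face-to-face rule
        is 5).
    delta : float, optional
        Tail mass on each side of the credible interval.
    windows : sequence of str, optional
        Sub-window labels for the windowed heuristic.
    compute_ci : bool, optional
        Skip the (much costlier) interval when only point estimates matter.
    scale : CostScale, optional
        Known scale, bypassing the heuristics.
    """
    nan_fit = dict(eta_hat=float("nan"), ci_low=float("nan"),
                   ci_high=float("nan"), delta=delta, ego_id=ego.ego_id)
    try:
        if scale is None:
            if scale_method == "global":
                scale = global_scale(ego)
            elif scale_method == "windowed":
                scale = windowed_scale(ego, windows)
            else:
                raise ValidationError(f"unknown scale_method {scale_method!r}")
    except (ScaleError, ValidationError) as exc:
        logger.info("ego %s: degenerate scale (%s)", ego.ego_id, exc)
        return ContinuumFit(summary=None, status="degenerate_scale", **nan_fit)
    filtered = filter_ties(ego, scale, min_alters=min_alters)
    if filtered.excluded:
        logger.info(
            "ego %s: %d alters after filtering < min_alters=%d; excluded",
            ego.ego_id, len(filtered.record.ties), min_alters,
        )
        return ContinuumFit(summary=None, status="excluded", **nan_fit)
    costs = [t.weight for t in filtered.record.ties]
    summary = summarize(costs, scale)
    try:
        eta_hat = mle_eta(summary)
    except (ImproperPosteriorError, EgocirclesError) as exc:
        logger.info("ego %s: improper posterior (%s)", ego.ego_id, exc)
        return ContinuumFit(summary=summary, status="improper", **nan_fit)
    ci_low = ci_high = float("nan")
    if compute_ci:
        ci_low, ci_high = confidence_interval(summary, delta=delta)
    return ContinuumFit(
        eta_hat=eta_hat, ci_low=ci_low, ci_high=ci_high, delta=delta,
        summary=summary, ego_id=ego.ego_id, status="ok",
    )


def fit_population(
    egos: Sequence[EgoRecord], **fit_kwargs
) -> pd.DataFrame:
    """Fit every ego; one row per ego with estimates and status."""
    rows = []
    for ego in egos:
        fit = fit_ego(ego, **fit_kwargs)
        rows.append({
            "ego_id": ego.ego_id,
            "L_tilde": fit.summary.L_tilde if fit.summary else np.nan,
            "t_bar": fit.summary.t_bar if fit.summary else np.nan,
            "eta_hat": fit.eta_hat,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "regime": fit.regime if fit.status == "ok" else "",
            "status": fit.status,
        })
    return pd.DataFrame(
        rows,
        columns=["ego_id", "L_tilde", "t_bar", "eta_hat", "ci_low",
                 "ci_high", "regime", "status"],
    )


def summary_stats(fits: pd.DataFrame, bin_width: float = 1.0) -> dict:
    """Population statistics of the eta estimates.

    The mode is kernel-free: the midpoint of the fullest histogram bin at
    the given width, with bin edges anchored at 0.
    """
    ok = fits[fits["status"] == "ok"]
    eta = ok["eta_hat"].to_numpy(dtype=float)
    out = {
        "n_total": int(len(fits)),
        "n_ok": int(len(ok)),
        "bin_width": float(bin_width),
    }
    if len(ok) == 0:
        return out
    lo = np.floor(eta.min() / bin_width) * bin_width
    hi = np.ceil(eta.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    hist, edges = np.histogram(eta, bins=edges)
    imax = int(np.argmax(hist))
    out.update(
        mean=float(eta.mean()),
        median=float(np.median(eta)),
        std=float(eta.std(ddof=1)) if len(eta) > 1 else 0.0,
        mode=float(0.5 * (edges[imax] + edges[imax + 1])),
        frac_inverse=float(np.mean(eta < 0.0)),
    )
    return out
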