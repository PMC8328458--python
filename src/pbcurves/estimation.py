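"""Estimating the labeling constant c from a naive PR curve.

With a well-discriminating model, the true precision p reaches 1 at
high thresholds, where the naive precision p' approaches c (p' = c
maps to p = 1 in both sampling scenarios). Averaging the p' values that
fall inside a high percentile window (default the 90th-99th
percentiles of the p' multiset, one value per distinct threshold)
therefore estimates c; prevalence follows through the scenario's
conversion formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import prevalence_from_c
from .curves import Curve, ScoredSet, _sweep
from .errors import DegenerateCurveError, TooFewPointsError
from .metrics import Scenario

__all__ = [
    "PercentileWindow",
    "CEstimate",
    "estimate_c",
    "estimate_c_from_scores",
    "estimate_prevalence",
    "relative_error",
]

MIN_POINTS = 5


@dataclass(frozen=True)
class PercentileWindow:
    """Percentile range selecting the high-p' points averaged into c_hat.

    Bounds are inclusive; percentiles use linear interpolation between
    order statistics (numpy's default). The 90-99 default excludes the
    very top of the curve, where tiny predicted-positive counts make p'
    noisy, while staying in the near-zero-FPR region where p ~ 1.
    """

    lo: float = 90.0
    hi: float = 99.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 100.0):
            raise ValueError(f"need 0 <= lo < hi <= 100, got ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class CEstimate:
    """c_hat with the diagnostics needed to judge it."""

    c_hat: float
    j: int                 # number of p' values averaged
    p_naive_max: float
    window: PercentileWindow
    window_values: tuple   # (lo-th, hi-th) percentile values of p'
    spread: float          # std of the selected p' values


def _estimate_from_values(
    p_naive: np.ndarray, window: PercentileWindow
) -> CEstimate:
    if p_naive.size < MIN_POINTS:
        raise TooFewPointsError(
            f"need >= {MIN_POINTS} defined naive-precision points, "
            f"got {p_naive.size}"
        )
    if np.all(p_naive == p_naive[0]):
        raise DegenerateCurveError(
            "all naive precisions identical; percentile window is meaningless"
        )
    lo_v, hi_v = np.percentile(p_naive, [window.lo, window.hi])
    sel = p_naive[(p_naive >= lo_v) & (p_naive <= hi_v)]
    if sel.size == 0:  # cannot happen with inclusive bounds, but be safe
        raise TooFewPointsError("no points inside the percentile window")
    return CEstimate(
        c_hat=float(sel.mean()),
        j=int(sel.size),
        p_naive_max=float(p_naive.max()),
        window=window,
        window_values=(float(lo_v), float(hi_v)),
        spread=float(sel.std()),
    )


def estimate_c(
    naive_pr: Curve, window: "PercentileWindow | None" = None
) -> CEstimate:
    """Percentile-window mean of p' over the curve's distinct thresholds.

    The curve must be a naive (PO-provenance) PR curve; the synthetic
    left-endpoint anchor (threshold +inf) is excluded from the multiset.
    """
    if naive_pr.kind != "pr" or naive_pr.provenance != "PO":
        raise ValueError("c estimation needs a naive (PO) PR curve")
    window = window or PercentileWindow()
    p_naive = np.array(
        [p.y for p in naive_pr.points if np.isfinite(p.threshold)]
    )
    return _estimate_from_values(p_naive, window)


def estimate_c_from_scores(
    data: ScoredSet,
    window: "PercentileWindow | None" = None,
    max_fpr: "float | None" = None,
) -> CEstimate:
    """Estimate c directly from a presence-unlabeled scored set.

    ``max_fpr`` optionally restricts the p' multiset to thresholds whose
    naive FPR' is at most the given value — useful for weakly
    discriminating models, where only the near-zero-FPR points satisfy
    the p ~ 1 premise.
    """
    if data.mode != "pb":
        raise ValueError("c estimation needs a presence-unlabeled set")
    window = window or PercentileWindow()
    sw = _sweep(data)
    p_naive = sw.pos_labeled / sw.pred_pos
    if max_fpr is not None:
        fpr_naive = (sw.pred_pos - sw.pos_labeled) / sw.n0
        p_naive = p_naive[fpr_naive <= max_fpr]
    return _estimate_from_values(np.asarray(p_naive, dtype=float), window)


def estimate_prevalence(
    naive_pr: Curve,
    *,
    scenario: "Scenario | str",
    n1: int,
    n0: "int | None" = None,
    t: "int | None" = None,
    window: "PercentileWindow | None" = None,
) -> tuple[float, CEstimate]:
    """Estimate c from the curve, then convert it to prevalence."""
    est = estimate_c(naive_pr, window)
    prev = prevalence_from_c(est.c_hat, n1=n1, n0=n0, t=t, scenario=scenario)
    return prev, est


def relative_error(true_val: float, est_val: float) -> float:
    """Signed relative error in percent: 100 * (est - true) / true."""
    if true_val == 0:
        raise ZeroDivisionError("relative error undefined for a zero true value")
    return 100.0 * (est_val - true_val) / true_val
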