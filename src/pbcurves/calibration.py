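"""Presence-background calibration of naive curves.

The labeling constant ``c = P(s=1 | y=1)`` — the probability that a
true presence is labeled in the test set — links the naive precision p'
(unlabeled treated as absent) to the true precision p:

* case-control:            p = (1 - c)/c * p' / (1 - p')
* single-training-set:     p = p' / c

and links c to the species prevalence P(y=1):

* case-control:            c = n1 / (n1 + n0 * P)
* single-training-set:     c = n1 / (t * P)

Recall is unaffected (r' = r, the labeled presences being a uniform
subsample of all presences), and the false positive rate follows from
precision through FPR = P(y'=1) * (1 - p) / (1 - P(y=1)) with the
predicted-positive fraction P(y'=1) taken per threshold. Together these
turn a naive (PO) ROC or PR curve into a calibrated (PB) curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .curves import Curve, CurvePoint
from .errors import (
    CountMismatchError,
    DegenerateCurveError,
    InconsistentCountsError,
)
from .metrics import Scenario

__all__ = [
    "CalibrationSpec",
    "Corrected",
    "c_from_prevalence",
    "prevalence_from_c",
    "correct_precision",
    "fpr_from_precision",
    "calibrate_curve",
]


def c_from_prevalence(
    prevalence: float,
    *,
    n1: int,
    n0: "int | None" = None,
    t: "int | None" = None,
    scenario: "Scenario | str",
) -> float:
    """Labeling constant implied by prevalence and the sample counts."""
    scenario = Scenario.parse(scenario)
    if not 0.0 < prevalence <= 1.0:
        raise InconsistentCountsError(f"prevalence must be in (0, 1], got {prevalence}")
    if scenario is Scenario.CASE_CONTROL:
        if n0 is None:
            raise ValueError("case-control conversion needs n0")
        c = n1 / (n1 + n0 * prevalence)
    else:
        if t is None:
            t = n1 + (n0 or 0)
        c = n1 / (t * prevalence)
    if c > 1.0:
        raise InconsistentCountsError(
            f"prevalence {prevalence} implies c = {c:.4f} > 1: "
            "more labeled presences than presences"
        )
    return c


def prevalence_from_c(
    c: float,
    *,
    n1: int,
    n0: "int | None" = None,
    t: "int | None" = None,
    scenario: "Scenario | str",
) -> float:
    """Prevalence implied by the labeling constant (inverse conversion)."""
    scenario = Scenario.parse(scenario)
    if not 0.0 < c <= 1.0:
        raise InconsistentCountsError(f"c must be in (0, 1], got {c}")
    if scenario is Scenario.CASE_CONTROL:
        if n0 is None:
            raise ValueError("case-control conversion needs n0")
        prev = (n1 / c - n1) / n0
    else:
        if t is None:
            t = n1 + (n0 or 0)
        prev = n1 / (t * c)
    if prev > 1.0:
        raise InconsistentCountsError(
            f"c = {c} implies prevalence {prev:.4f} > 1 with these counts"
        )
    return prev


@dataclass(frozen=True)
class CalibrationSpec:
    """Scenario, labeling constant / prevalence, and the counts linking them.

    Exactly one of ``c`` and ``prevalence`` is supplied; the other is
    derived from the scenario's conversion formula at construction.
    """

    scenario: Scenario
    n1: int
    n0: int
    c: "float | None" = None
    prevalence: "float | None" = None
    t: "int | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario.parse(self.scenario))
        if self.n1 < 1 or self.n0 < 1:
            raise InconsistentCountsError("n1 and n0 must each be >= 1")
        if self.t is None:
            object.__setattr__(self, "t", self.n1 + self.n0)
        if (self.c is None) == (self.prevalence is None):
            raise InconsistentCountsError(
                "supply exactly one of c and prevalence"
            )
        kw = dict(n1=self.n1, n0=self.n0, t=self.t, scenario=self.scenario)
        if self.c is None:
            object.__setattr__(
                self, "c", c_from_prevalence(self.prevalence, **kw)
            )
        else:
            if not 0.0 < self.c <= 1.0:
                raise InconsistentCountsError(f"c must be in (0, 1], got {self.c}")
            object.__setattr__(
                self, "prevalence", prevalence_from_c(self.c, **kw)
            )


class Corrected(NamedTuple):
    """A corrected proportion plus a flag set when the raw value had to
    be clipped into [0, 1] (sampling noise or a mis-specified c)."""

    value: float
    clipped: bool


def correct_precision(p_naive: float, spec: CalibrationSpec) -> Corrected:
    """True precision from naive precision via the scenario's formula."""
    if not 0.0 <= p_naive <= 1.0:
        raise ValueError(f"naive precision must be in [0, 1], got {p_naive}")
    c = spec.c
    if spec.scenario is Scenario.CASE_CONTROL:
        if p_naive == 1.0:
            # (1-c)/c * p'/(1-p') diverges; all predicted positives are
            # labeled presences, so true precision is 1.
            return Corrected(1.0, c < 1.0)
        raw = (1.0 - c) / c * p_naive / (1.0 - p_naive)
    else:
        raw = p_naive / c
    if raw > 1.0:
        return Corrected(1.0, True)
    return Corrected(raw, False)


def fpr_from_precision(
    p: float, pred_pos_frac: float, prevalence: float
) -> Corrected:
    """FPR = P(y'=1) * (1 - p) / (1 - P(y=1)), clipped into [0, 1]."""
    if prevalence >= 1.0:
        raise DegenerateCurveError("FPR undefined at prevalence 1 (no absences)")
    raw = pred_pos_frac * (1.0 - p) / (1.0 - prevalence)
    if raw > 1.0:
        return Corrected(1.0, True)
    if raw < 0.0:
        return Corrected(0.0, True)
    return Corrected(raw, False)


def calibrate_curve(naive: Curve, spec: CalibrationSpec) -> Curve:
    """Turn a naive (PO) curve into a calibrated (PB) curve.

    PR curves: each p' is replaced by the corrected precision; recall is
    kept (r' = r). ROC curves: TPR is kept; FPR is recomputed per
    threshold from the corrected precision, the per-threshold
    predicted-positive fraction and the prevalence. Clip flags are
    propagated to the output points.
    """
    if naive.provenance != "PO" or naive.sweep is None:
        raise ValueError("calibration needs a PO-mode curve with its sweep attached")
    sw = naive.sweep
    if sw.n1 != spec.n1 or sw.n0 != spec.n0:
        raise CountMismatchError(
            f"spec counts (n1={spec.n1}, n0={spec.n0}) do not match the "
            f"curve's source set (n1={sw.n1}, n0={sw.n0})"
        )
    # The ROC x-coordinate is P(y'=1)(1-p)/(1-P(y=1)); expanding the
    # product into one integer-combination numerator over a constant
    # denominator keeps thresholds with identical exact FPR bitwise
    # identical, so vertical runs survive the sort in auc().
    c = spec.c
    if spec.scenario is Scenario.CASE_CONTROL:
        fpr_den = sw.n0 * (1.0 - spec.prevalence)
    else:
        fpr_den = sw.t * (1.0 - spec.prevalence)
    pts: list[CurvePoint] = []
    for i, thr in enumerate(sw.thresholds):
        m1 = int(sw.pos_labeled[i])
        k1 = int(sw.pred_pos[i])
        r = m1 / sw.n1
        p, p_clip = correct_precision(m1 / k1, spec)
        if naive.kind == "pr":
            pts.append(CurvePoint(float(thr), r, p, naive=False, clipped=p_clip))
        else:
            if p_clip:  # corrected precision saturated; use clipped p
                if spec.scenario is Scenario.CASE_CONTROL:
                    ppf = (k1 - m1) / sw.n0
                else:
                    ppf = k1 / sw.t
                fpr, f_clip = fpr_from_precision(p, ppf, spec.prevalence)
            else:
                if spec.scenario is Scenario.CASE_CONTROL:
                    num = (k1 - m1) - m1 * (1.0 - c) / c
                else:
                    num = k1 - m1 / c
                raw = num / fpr_den
                f_clip = not 0.0 <= raw <= 1.0
                fpr = min(max(raw, 0.0), 1.0)
            pts.append(
                CurvePoint(float(thr), fpr, r, naive=False, clipped=p_clip or f_clip)
            )
    if naive.kind == "pr":
        pts = [CurvePoint(np.inf, 0.0, pts[0].y)] + pts
    else:
        pts = [CurvePoint(np.inf, 0.0, 0.0)] + pts
        if pts[-1].x != 1.0 or pts[-1].y != 1.0:
            pts.append(CurvePoint(-np.inf, 1.0, 1.0))
    return Curve(kind=naive.kind, provenance="PB", points=pts, sweep=sw)
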