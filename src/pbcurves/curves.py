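"""Threshold sweeps and ROC / precision-recall curve construction.

A record is predicted present iff its score is >= the threshold; the
thresholds are the distinct observed scores in decreasing order (a +inf
anchor stands for the all-negative prediction). Tied scores are
processed as one block and never split.

Curves can be built in three provenances:

``PA``
    presence-absence: full true labels (the benchmark),
``PO``
    presence-only: a presence-unlabeled set with unlabeled records
    naively treated as absences (biased; primed metrics p', FPR'),
``PB``
    presence-background: a PO curve calibrated with the labeling
    constant c (see :mod:`pbcurves.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DegenerateCurveError, UndefinedMetricError
from .metrics import NontraditionalConfusion, Scenario, TraditionalConfusion

__all__ = [
    "ScoredSet",
    "SweepTable",
    "CurvePoint",
    "Curve",
    "sweep_confusions",
    "roc_curve",
    "pr_curve",
    "auc",
    "pa_oracle_set",
    "ordinate_difference",
]

_LABEL_TOKENS = {
    "1": True, "present": True, "presence": True, "labeled": True,
    "0": False, "absent": False, "absence": False, "unlabeled": False,
    "background": False,
}


@dataclass
class ScoredSet:
    """Prediction scores with labels for one test set.

    In ``pa`` mode labels mean present/absent; in ``pb`` mode they mean
    labeled-presence/unlabeled, a scenario tag is required, and
    ``true_labels`` may carry the hidden truth for simulated data.
    """

    scores: np.ndarray
    labels: np.ndarray
    mode: str = "pa"
    scenario: "Scenario | None" = None
    true_labels: "np.ndarray | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.mode not in ("pa", "pb"):
            raise ValueError(f"mode must be 'pa' or 'pb', got {self.mode!r}")
        if self.scores.ndim != 1 or self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if not self.labels.any():
            raise ValueError("need at least one positive/labeled record")
        if self.labels.all():
            raise ValueError("need at least one negative/unlabeled record")
        if self.mode == "pb":
            if self.scenario is None:
                raise ValueError("pb mode requires a sampling scenario")
            self.scenario = Scenario.parse(self.scenario)
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=bool)
            if self.true_labels.shape != self.scores.shape:
                raise ValueError("true_labels must match scores in length")
            if self.mode == "pb" and np.any(self.labels & ~self.true_labels):
                raise ValueError("a labeled record cannot be a true absence")

    def __len__(self) -> int:
        return self.scores.size

    @property
    def n_positive(self) -> int:
        """Labeled presences (n1 in pb mode, TP+FN in pa mode)."""
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        """Unlabeled records (n0) in pb mode, absences in pa mode."""
        return len(self) - self.n_positive


@dataclass(frozen=True)
class SweepTable:
    """Cumulative counts per distinct threshold, highest threshold first.

    ``pos_labeled[i]`` = labeled positives with score >= thresholds[i]
    (tp in pa mode, m1 in pb mode); ``pred_pos[i]`` = all records with
    score >= thresholds[i] (k1). ``pos_true`` counts true presences
    among them when hidden truth is available.
    """

    thresholds: np.ndarray
    pos_labeled: np.ndarray
    pred_pos: np.ndarray
    n1: int
    t: int
    mode: str
    scenario: "Scenario | None" = None
    pos_true: "np.ndarray | None" = None
    unl_true: "np.ndarray | None" = None  # unlabeled true presences >= thr
    n_true: "int | None" = None
    n_unl_true: "int | None" = None

    @property
    def n0(self) -> int:
        return self.t - self.n1


def _sweep(data: ScoredSet) -> SweepTable:
    order = np.argsort(-data.scores, kind="stable")
    s = data.scores[order]
    lab = data.labels[order]
    n = s.size
    last = np.flatnonzero(np.diff(s) != 0)
    last = np.concatenate([last, [n - 1]])
    kwargs: dict = {}
    if data.true_labels is not None:
        truth = data.true_labels[order]
        kwargs["pos_true"] = np.cumsum(truth)[last]
        kwargs["unl_true"] = np.cumsum(truth & ~lab)[last]
        kwargs["n_true"] = int(truth.sum())
        kwargs["n_unl_true"] = int((truth & ~lab).sum())
    return SweepTable(
        thresholds=s[last],
        pos_labeled=np.cumsum(lab)[last],
        pred_pos=last + 1,
        n1=data.n_positive,
        t=n,
        mode=data.mode,
        scenario=data.scenario,
        **kwargs,
    )


def sweep_confusions(
    data: ScoredSet,
) -> Iterator[tuple[float, "TraditionalConfusion | NontraditionalConfusion"]]:
    """Yield (threshold, confusion) for every distinct score, descending.

    PA-mode sets yield :class:`TraditionalConfusion`; pb-mode sets yield
    :class:`NontraditionalConfusion` with hidden cells filled in when
    the set carries simulated truth.
    """
    if len(data) == 0:
        raise ValueError("empty input")
    sw = _sweep(data)
    for i, thr in enumerate(sw.thresholds):
        m1 = int(sw.pos_labeled[i])
        k1 = int(sw.pred_pos[i])
        if data.mode == "pa":
            yield float(thr), TraditionalConfusion(
                tp=m1, fp=k1 - m1, fn=sw.n1 - m1, tn=sw.t - k1 - (sw.n1 - m1)
            )
        else:
            hidden: dict = {}
            if sw.unl_true is not None:
                m2 = int(sw.unl_true[i])
                hidden = {
                    "m2": m2,
                    "m3": k1 - m1 - m2,
                    "m5": sw.n_unl_true - m2,
                    "m6": sw.n0 - (k1 - m1) - (sw.n_unl_true - m2),
                }
            yield float(thr), NontraditionalConfusion(
                m1=m1, m4=sw.n1 - m1, k1=k1, k0=sw.t - k1,
                n1=sw.n1, n0=sw.n0, t=sw.t, **hidden,
            )


@dataclass(frozen=True)
class CurvePoint:
    """One per-threshold point; x/y follow plotting convention
    (ROC: x=FPR, y=TPR; PR: x=recall, y=precision)."""

    threshold: float
    x: float
    y: float
    naive: bool = False
    clipped: bool = False


@dataclass
class Curve:
    """Ordered curve points (thresholds decreasing) plus the sweep they
    came from, kept so calibration can recompute per-threshold counts."""

    kind: str  # "roc" | "pr"
    provenance: str  # "PA" | "PO" | "PB"
    points: list[CurvePoint]
    sweep: "SweepTable | None" = None

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([p.x for p in self.points]),
            np.array([p.y for p in self.points]),
        )

    @property
    def n_clipped(self) -> int:
        return sum(p.clipped for p in self.points)


def _require_modes(data: ScoredSet, mode: str) -> None:
    mode = mode.lower()
    if mode not in ("pa", "po"):
        raise ValueError(f"curve mode must be 'pa' or 'po', got {mode!r}")
    if mode == "pa" and data.mode != "pa":
        raise ValueError("pa-mode curves need a fully labeled ScoredSet")
    if mode == "po" and data.mode != "pb":
        raise ValueError("po-mode curves need a presence-unlabeled ScoredSet")


def roc_curve(data: ScoredSet, mode: str = "pa") -> Curve:
    """ROC curve: TPR vs FPR per threshold (FPR' and TPR'=r' in PO mode).

    Anchored with (0,0) at threshold +inf; (1,1) occurs naturally at the
    lowest threshold where every record is predicted present.
    """
    _require_modes(data, mode)
    sw = _sweep(data)
    npos, nneg = sw.n1, sw.n0
    tpr = sw.pos_labeled / npos
    fpr = (sw.pred_pos - sw.pos_labeled) / nneg
    pts = [CurvePoint(np.inf, 0.0, 0.0, naive=mode.lower() == "po")]
    pts += [
        CurvePoint(float(t), float(x), float(y), naive=mode.lower() == "po")
        for t, x, y in zip(sw.thresholds, fpr, tpr)
    ]
    if pts[-1].x != 1.0 or pts[-1].y != 1.0:
        pts.append(CurvePoint(-np.inf, 1.0, 1.0, naive=mode.lower() == "po"))
    return Curve(kind="roc", provenance=mode.upper(), points=pts, sweep=sw)


def pr_curve(data: ScoredSet, mode: str = "pa") -> Curve:
    """Precision-recall curve: p vs r per threshold (p', r' in PO mode).

    Thresholds with no predicted positives are dropped (precision
    undefined). The left endpoint at r=0 extends the precision of the
    highest defined threshold (constant extension).
    """
    _require_modes(data, mode)
    sw = _sweep(data)
    naive = mode.lower() == "po"
    rec = sw.pos_labeled / sw.n1
    prec = sw.pos_labeled / sw.pred_pos  # pred_pos >= 1 at every threshold
    pts = [
        CurvePoint(float(t), float(r), float(p), naive=naive)
        for t, r, p in zip(sw.thresholds, rec, prec)
    ]
    anchor = CurvePoint(np.inf, 0.0, pts[0].y, naive=naive)
    return Curve(kind="pr", provenance=mode.upper(), points=[anchor] + pts, sweep=sw)


def _collapse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by x ascending (stable) and average y over duplicate x."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
    return ux, uy


def auc(curve: Curve, pr_integration: str = "trapezoid") -> float:
    """Area under the curve over its x axis (FPR for ROC, recall for PR).

    Points are stably sorted by x ascending; duplicate x values form
    vertical segments that contribute nothing, so ROC areas match the
    Mann-Whitney rank statistic exactly even with tied scores. PR curves
    may use step integration (each segment contributes the precision at
    its right end, as in average precision) instead of the default
    trapezoid; ROC curves always use the trapezoid.
    """
    if len(curve.points) < 2:
        raise DegenerateCurveError("need at least 2 points to integrate")
    x, y = curve.xy()
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x[-1] == x[0]:
        raise DegenerateCurveError("curve has zero x-span")
    if curve.kind == "pr" and pr_integration == "step":
        return float(np.sum(np.diff(x) * y[1:]))
    if pr_integration not in ("trapezoid", "step"):
        raise ValueError(f"unknown integration scheme {pr_integration!r}")
    return float(np.trapezoid(y, x))


def pa_oracle_set(data: ScoredSet) -> ScoredSet:
    """Benchmark presence-absence set from a simulated pb-mode set.

    Under case-control sampling only the unlabeled (background) margin
    is a random population sample, so the oracle keeps those records
    with their true labels; under single-training-set sampling the whole
    set is a population sample.
    """
    if data.mode != "pb" or data.true_labels is None:
        raise UndefinedMetricError("oracle needs a simulated pb-mode set")
    if data.scenario is Scenario.CASE_CONTROL:
        keep = ~data.labels
        return ScoredSet(
            scores=data.scores[keep], labels=data.true_labels[keep], mode="pa"
        )
    return ScoredSet(scores=data.scores, labels=data.true_labels, mode="pa")


def ordinate_difference(
    a: Curve, b: Curve, grid: "Sequence[float] | None" = None
) -> float:
    """Mean absolute difference between two curves' ordinates, evaluated
    by linear interpolation on a common x grid (default 201 points)."""
    if a.kind != b.kind:
        raise ValueError("curves must be of the same kind")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(grid, dtype=float)
    ya = np.interp(grid, *_collapse(*a.xy()))
    yb = np.interp(grid, *_collapse(*b.xy()))
    return float(np.mean(np.abs(ya - yb)))
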