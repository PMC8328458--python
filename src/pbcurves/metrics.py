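"""Confusion matrices and scalar metrics for fully labeled and
presence-unlabeled test sets.

Two matrix layouts exist side by side. A *traditional* test set has
complete presence/absence labels and the usual four quadrants (TP, FP,
FN, TN). A *nontraditional* (presence-unlabeled) test set only labels a
subset of the presences; crossing predictions with the labeled/unlabeled
margin gives six cells m1..m6 of which only m1 (labeled, predicted
present) and m4 (labeled, predicted absent) are observable, together
with the margins n1 (labeled), n0 (unlabeled), k1 (predicted present),
k0 (predicted absent) and t (total). The hidden cells m2/m3/m5/m6 are
known only for simulated data, where they serve as test oracles.

Naive metrics computed by treating unlabeled records as absences are
written with a prime in the literature (p', r', FPR'); here they are the
``naive_*`` functions. The labeling constant ``c = P(s=1 | y=1)`` links
them to the true metrics (see :mod:`pbcurves.calibration`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple

from .errors import MissingHiddenCellsError, UndefinedMetricError

__all__ = [
    "Scenario",
    "TraditionalConfusion",
    "NontraditionalConfusion",
    "HiddenTruth",
    "precision",
    "recall",
    "false_positive_rate",
    "prevalence",
    "predicted_positive_fraction",
    "naive_precision",
    "naive_recall",
    "labeling_constant",
    "hidden_truth_metrics",
]


class Scenario(str, enum.Enum):
    """How the presence-unlabeled test set was sampled.

    ``CASE_CONTROL``
        Labeled presences drawn from the presence subset; unlabeled
        ("background") records drawn from the whole population.
    ``SINGLE_TRAINING_SET``
        One random site sample; each presence is labeled (detected)
        independently with probability c.
    """

    CASE_CONTROL = "case_control"
    SINGLE_TRAINING_SET = "single_training_set"

    @classmethod
    def parse(cls, value: "str | Scenario") -> "Scenario":
        if isinstance(value, Scenario):
            return value
        key = str(value).strip().lower().replace("-", "_")
        aliases = {
            "case_control": cls.CASE_CONTROL,
            "cc": cls.CASE_CONTROL,
            "single_training_set": cls.SINGLE_TRAINING_SET,
            "single": cls.SINGLE_TRAINING_SET,
            "sts": cls.SINGLE_TRAINING_SET,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown scenario {value!r}") from None


def _check_count(name: str, value: int) -> int:
    if int(value) != value or value < 0:
        raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class TraditionalConfusion:
    """Four-quadrant confusion matrix from a fully labeled test set."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one record")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class NontraditionalConfusion:
    """Six-cell confusion matrix from a presence-unlabeled test set.

    Observable cells/margins: m1, m4, k1, k0, n1, n0, t. The hidden
    cells m2 (unlabeled presence, predicted present), m3 (absence,
    predicted present), m5 (unlabeled presence, predicted absent) and
    m6 (absence, predicted absent) may be attached for simulated data;
    they are ``None`` for real data.
    """

    m1: int
    m4: int
    k1: int
    k0: int
    n1: int
    n0: int
    t: int
    m2: "int | None" = None
    m3: "int | None" = None
    m5: "int | None" = None
    m6: "int | None" = None

    def __post_init__(self) -> None:
        for name in ("m1", "m4", "k1", "k0", "n1", "n0", "t"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        for name in ("m2", "m3", "m5", "m6"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _check_count(name, v))
        if self.n1 != self.m1 + self.m4:
            raise ValueError("n1 must equal m1 + m4")
        if self.t != self.n1 + self.n0:
            raise ValueError("t must equal n1 + n0")
        if self.k1 + self.k0 != self.t:
            raise ValueError("k1 + k0 must equal t")
        if self.has_hidden_cells:
            if self.k1 != self.m1 + self.m2 + self.m3:
                raise ValueError("k1 must equal m1 + m2 + m3")
            if self.k0 != self.m4 + self.m5 + self.m6:
                raise ValueError("k0 must equal m4 + m5 + m6")
            if self.n0 != self.m2 + self.m3 + self.m5 + self.m6:
                raise ValueError("n0 must equal m2 + m3 + m5 + m6")

    @property
    def has_hidden_cells(self) -> bool:
        return None not in (self.m2, self.m3, self.m5, self.m6)

    @classmethod
    def from_cells(
        cls, m1: int, m2: int, m3: int, m4: int, m5: int, m6: int
    ) -> "NontraditionalConfusion":
        """Build a fully specified table from the six cells."""
        return cls(
            m1=m1,
            m4=m4,
            k1=m1 + m2 + m3,
            k0=m4 + m5 + m6,
            n1=m1 + m4,
            n0=m2 + m3 + m5 + m6,
            t=m1 + m2 + m3 + m4 + m5 + m6,
            m2=m2,
            m3=m3,
            m5=m5,
            m6=m6,
        )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{what} undefined: zero denominator")
    return num / den


def precision(conf: TraditionalConfusion) -> float:
    """p = TP / (TP + FP); undefined when nothing is predicted present."""
    return _ratio(conf.tp, conf.tp + conf.fp, "precision")


def recall(conf: TraditionalConfusion) -> float:
    """r = TP / (TP + FN); undefined when there are no presences."""
    return _ratio(conf.tp, conf.tp + conf.fn, "recall")


def false_positive_rate(conf: TraditionalConfusion) -> float:
    """FPR = FP / (FP + TN); undefined when there are no absences."""
    return _ratio(conf.fp, conf.fp + conf.tn, "false positive rate")


def prevalence(conf: TraditionalConfusion) -> float:
    """P(y=1) = (TP + FN) / total."""
    return (conf.tp + conf.fn) / conf.total


def predicted_positive_fraction(conf: TraditionalConfusion) -> float:
    """P(y'=1) = (TP + FP) / total."""
    return (conf.tp + conf.fp) / conf.total


def naive_precision(conf: NontraditionalConfusion) -> float:
    """p' = m1 / k1 — precision when unlabeled records count as absences."""
    return _ratio(conf.m1, conf.k1, "naive precision")


def naive_recall(conf: NontraditionalConfusion) -> float:
    """r' = m1 / n1 — recall over the labeled presences; equals r in
    expectation because the labeled presences are a uniform subsample."""
    return _ratio(conf.m1, conf.n1, "naive recall")


def labeling_constant(conf: NontraditionalConfusion) -> float:
    """Realized c = n1 / (number of presences in the set).

    Requires the hidden cells: the presences hiding in the unlabeled
    margin are m2 + m5.
    """
    if not conf.has_hidden_cells:
        raise MissingHiddenCellsError("realized c needs hidden cells m2/m5")
    return _ratio(conf.n1, conf.n1 + conf.m2 + conf.m5, "labeling constant")


class HiddenTruth(NamedTuple):
    """True metrics recovered from a fully specified nontraditional table."""

    precision: float
    recall: float
    prevalence: float
    predicted_positive_fraction: float


def hidden_truth_metrics(
    conf: NontraditionalConfusion, scenario: "Scenario | str"
) -> HiddenTruth:
    """True p, r, P(y=1), P(y'=1) from the hidden cells (simulation oracle).

    Under case-control sampling only the unlabeled margin is a random
    population sample, so the truth is computed from m2/m3/m5/m6 alone.
    Under single-training-set sampling the whole set is a population
    sample and the labeled presences participate.
    """
    if not conf.has_hidden_cells:
        raise MissingHiddenCellsError("hidden-truth metrics need m2/m3/m5/m6")
    scenario = Scenario.parse(scenario)
    if scenario is Scenario.CASE_CONTROL:
        return HiddenTruth(
            precision=_ratio(conf.m2, conf.m2 + conf.m3, "precision"),
            recall=_ratio(conf.m2, conf.m2 + conf.m5, "recall"),
            prevalence=_ratio(conf.m2 + conf.m5, conf.n0, "prevalence"),
            predicted_positive_fraction=_ratio(
                conf.k1 - conf.m1, conf.n0, "predicted positive fraction"
            ),
        )
    return HiddenTruth(
        precision=_ratio(conf.m1 + conf.m2, conf.m1 + conf.m2 + conf.m3, "precision"),
        recall=_ratio(
            conf.m1 + conf.m2, conf.m1 + conf.m2 + conf.m4 + conf.m5, "recall"
        ),
        prevalence=_ratio(
            conf.m1 + conf.m2 + conf.m4 + conf.m5, conf.t, "prevalence"
        ),
        predicted_positive_fraction=_ratio(
            conf.k1, conf.t, "predicted positive fraction"
        ),
    )
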