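"""Readers, writers, report assembly and plotting.

Everything is plain text: scored sets and curves travel as delimited
tables (CSV/TSV), reports as JSON validated against the shipped schema.
The method consumes scored samples, not maps — raster extraction is
upstream of this tool.
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import Curve, CurvePoint, ScoredSet, auc
from .errors import SchemaError
from .metrics import Scenario

__all__ = [
    "read_scored_set",
    "write_scored_set",
    "read_curve",
    "write_curve",
    "write_report",
    "validate_report",
    "compare_report",
    "plot_curves",
]

log = logging.getLogger("pbcurves")

_TRUE_TOKENS = {"1", "present", "presence", "labeled", "true"}
_FALSE_TOKENS = {"0", "absent", "absence", "unlabeled", "background", "false"}


def _parse_labels(raw: pd.Series, column: str) -> np.ndarray:
    tokens = raw.astype(str).str.strip().str.lower()
    out = np.empty(len(tokens), dtype=bool)
    for i, tok in enumerate(tokens):
        if tok in _TRUE_TOKENS:
            out[i] = True
        elif tok in _FALSE_TOKENS:
            out[i] = False
        else:
            raise SchemaError(
                f"unknown label token {tok!r} in column {column!r} (row {i})"
            )
    return out


def _read_table(path: "str | Path") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_scored_set(
    path: "str | Path",
    mode: str,
    scenario: "Scenario | str | None" = None,
) -> ScoredSet:
    """Load a scored set from a CSV/TSV with columns ``score``, ``label``
    (optional ``true_label`` sidecar column for simulated data)."""
    df = _read_table(path)
    for col in ("score", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.isna().idxmax())
        raise SchemaError(f"{path}: non-numeric score at row {bad}")
    labels = _parse_labels(df["label"], "label")
    truth = (
        _parse_labels(df["true_label"], "true_label")
        if "true_label" in df.columns
        else None
    )
    data = ScoredSet(
        scores=scores.to_numpy(float),
        labels=labels,
        mode=mode.lower(),
        scenario=Scenario.parse(scenario) if scenario is not None else None,
        true_labels=truth,
    )
    log.info(
        "read %s: %d records (%d positive/labeled, %d negative/unlabeled)",
        path, len(data), data.n_positive, data.n_negative,
    )
    return data


def write_scored_set(data: ScoredSet, path: "str | Path") -> None:
    if data.mode == "pa":
        lab = np.where(data.labels, "present", "absent")
    else:
        lab = np.where(data.labels, "labeled", "unlabeled")
    df = pd.DataFrame({"score": data.scores, "label": lab})
    if data.true_labels is not None:
        df["true_label"] = np.where(data.true_labels, "present", "absent")
    df.to_csv(path, index=False, float_format="%.17g")  # exact round-trip


_CURVE_COLUMNS = [
    "threshold", "x", "y", "kind", "provenance", "naive", "clipped",
    "x_4dp", "y_4dp",
]


def write_curve(curve: Curve, path: "str | Path") -> None:
    """Curve table CSV: full-precision coordinates plus 4-decimal
    presentation columns. Refuses to write an empty curve."""
    if not curve.points:
        raise ValueError("refusing to write an empty curve")
    df = pd.DataFrame(
        {
            "threshold": [p.threshold for p in curve.points],
            "x": [p.x for p in curve.points],
            "y": [p.y for p in curve.points],
            "kind": curve.kind,
            "provenance": curve.provenance,
            "naive": [p.naive for p in curve.points],
            "clipped": [p.clipped for p in curve.points],
        }
    )
    df["x_4dp"] = df["x"].round(4)
    df["y_4dp"] = df["y"].round(4)
    df[_CURVE_COLUMNS].to_csv(path, index=False)
    if (n := curve.n_clipped):
        log.warning("curve %s: %d clipped point(s)", path, n)


def read_curve(path: "str | Path") -> Curve:
    df = _read_table(path)
    missing = [c for c in ("threshold", "x", "y", "kind", "provenance") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing curve columns {missing}")
    points = [
        CurvePoint(
            threshold=float(r.threshold), x=float(r.x), y=float(r.y),
            naive=bool(getattr(r, "naive", False)),
            clipped=bool(getattr(r, "clipped", False)),
        )
        for r in df.itertuples()
    ]
    return Curve(kind=str(df["kind"].iloc[0]), provenance=str(df["provenance"].iloc[0]), points=points)


def _schema() -> dict:
    text = (
        importlib.resources.files("pbcurves")
        .joinpath("report_schema.json")
        .read_text()
    )
    return json.loads(text)


_JSON_TYPES = {
    "string": str,
    "number": (int, float),
    "integer": int,
    "object": dict,
    "array": (list, tuple),
}


def validate_report(report: dict) -> None:
    """Check a report against the shipped schema (required keys and the
    declared types of known keys)."""
    schema = _schema()
    for key in schema.get("required", []):
        if key not in report:
            raise SchemaError(f"report missing required key {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key in report and not isinstance(report[key], _JSON_TYPES[spec["type"]]):
            raise SchemaError(
                f"report key {key!r} should be {spec['type']}, "
                f"got {type(report[key]).__name__}"
            )


def write_report(report: dict, path: "str | Path") -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def compare_report(
    curves: "Mapping[str, Curve | Sequence[Curve]]",
    pr_integration: str = "trapezoid",
) -> dict:
    """Compare curves across approaches (e.g. PA vs PO vs PB).

    Each value is either one curve or a same-length sequence of curves
    (one per model). The report carries per-approach AUCs, pairwise AUC
    differences of the means, and — when three or more models are
    supplied — the Spearman rank correlation of AUCs between approaches.
    """
    from scipy.stats import spearmanr

    norm: dict[str, list[Curve]] = {
        name: list(cs) if isinstance(cs, (list, tuple)) else [cs]
        for name, cs in curves.items()
    }
    if len(norm) < 2:
        raise ValueError("need at least two approaches to compare")
    kinds = {c.kind for cs in norm.values() for c in cs}
    if len(kinds) != 1:
        raise ValueError(f"cannot compare curves of different kinds: {sorted(kinds)}")
    lengths = {len(cs) for cs in norm.values()}
    if len(lengths) != 1:
        raise ValueError("each approach must supply the same number of curves")
    aucs = {
        name: [auc(c, pr_integration=pr_integration) for c in cs]
        for name, cs in norm.items()
    }
    report: dict = {
        "report_type": "comparison",
        "kind": kinds.pop(),
        "auc": {
            name: vals[0] if len(vals) == 1 else vals
            for name, vals in aucs.items()
        },
        "auc_diff": {
            f"{a}-{b}": float(np.mean(aucs[a]) - np.mean(aucs[b]))
            for a, b in itertools.combinations(aucs, 2)
        },
    }
    n_models = lengths.pop()
    if n_models >= 3:
        report["rank_correlation"] = {
            f"{a}~{b}": float(spearmanr(aucs[a], aucs[b]).statistic)
            for a, b in itertools.combinations(aucs, 2)
        }
    return report


def plot_curves(
    curves: "Sequence[Curve]",
    path: "str | Path",
    labels: "Sequence[str] | None" = None,
) -> None:
    """Plot one or more curves of the same kind to a PNG/SVG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kinds = {c.kind for c in curves}
    if len(kinds) != 1:
        raise ValueError("all curves in one plot must share a kind")
    kind = kinds.pop()
    fig, ax = plt.subplots(figsize=(5, 5))
    for i, c in enumerate(curves):
        lbl = labels[i] if labels else c.provenance
        x, y = c.xy()
        order = np.argsort(x, kind="stable")
        ax.plot(x[order], y[order], label=lbl)
    if kind == "roc":
        ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
    else:
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
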