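"""Virtual-species simulator: the package's ground-truth engine.

A virtual species is a known occurrence-probability surface
P(y=1 | x) — the logistic transform of a linear or centered-quadratic
function of three environmental covariates — realized into binary
presence/absence labels cell by cell. Because the truth is known, every
naive and calibrated metric can be checked against an exact oracle.

The environmental covariates are synthetic smooth Gaussian random
fields standing in for standardized climate/terrain layers (think
precipitation, temperature, elevation): three layers with different
spatial correlation lengths and spreads. The default spreads are chosen
so the five packaged coefficient sets (spec1..spec5) span realized
prevalences of roughly 0.05-0.9. Realized prevalence is always computed
from the surface, never assumed.

Both sampling scenarios are provided, plus a model-degradation operator
(swapping P(y=1|x) with P(y=0|x) at a random fraction of cells) that
manufactures scorers of any desired discrimination level.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .curves import ScoredSet
from .errors import InsufficientPresenceError
from .metrics import Scenario

__all__ = [
    "SpeciesModel",
    "EnvironmentalField",
    "Realization",
    "load_species",
    "species_names",
    "synthetic_field",
    "probability_surface",
    "realize",
    "sample_case_control",
    "sample_single_training_set",
    "degrade_model",
]

# Frozen generator defaults: per-covariate smoothing length (cells),
# mean and spread. Heterogeneous on purpose — the three layers emulate
# standardized covariates with different spatial structure.
FIELD_SMOOTHING = (6.0, 12.0, 3.0)
FIELD_MEANS = (0.0, 0.4, 0.2)
FIELD_SDS = (1.0, 0.4, 0.15)


@dataclass(frozen=True)
class SpeciesModel:
    """Logistic occurrence model: coefficients plus functional form."""

    b0: float
    b1: float
    b2: float
    b3: float
    form: str = "linear"
    covariate_means: "tuple[float, float, float] | None" = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"form must be linear or quadratic, got {self.form!r}")


def _species_table() -> dict:
    text = (
        importlib.resources.files("pbcurves").joinpath("species.yaml").read_text()
    )
    return yaml.safe_load(text)


def species_names() -> list[str]:
    """Names of the packaged coefficient sets."""
    return sorted(_species_table())


def load_species(name_or_path: str) -> SpeciesModel:
    """A packaged species by name (spec1..spec5) or a custom YAML file.

    Custom files use the same layout as the packaged table: keys b0..b3,
    form, and optionally covariate_means (3 numbers).
    """
    table = _species_table()
    if name_or_path in table:
        entry = table[name_or_path]
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValueError(
                f"{name_or_path!r} is neither a packaged species "
                f"({', '.join(sorted(table))}) nor a file"
            )
        entry = yaml.safe_load(path.read_text())
    means = entry.get("covariate_means")
    return SpeciesModel(
        b0=float(entry["b0"]),
        b1=float(entry["b1"]),
        b2=float(entry["b2"]),
        b3=float(entry["b3"]),
        form=str(entry["form"]),
        covariate_means=tuple(means) if means is not None else None,
    )


@dataclass
class EnvironmentalField:
    """Three covariate layers over a rectangular grid, flattened to
    shape (n_cells, 3), plus the generator parameters that made them."""

    covariates: np.ndarray
    grid_shape: tuple[int, int]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 2 or self.covariates.shape[1] != 3:
            raise ValueError("covariates must have shape (n_cells, 3)")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates must be finite")

    @property
    def n_cells(self) -> int:
        return self.covariates.shape[0]

    def means(self) -> np.ndarray:
        return self.covariates.mean(axis=0)


def synthetic_field(
    n_cells: int = 100_000,
    seed: "int | None" = None,
    smoothing: tuple = FIELD_SMOOTHING,
    means: tuple = FIELD_MEANS,
    sds: tuple = FIELD_SDS,
) -> EnvironmentalField:
    """Smooth Gaussian random fields on the smallest square grid with at
    least ``n_cells`` cells (periodic smoothing, restandardized, then
    shifted/scaled per covariate)."""
    side = int(np.ceil(np.sqrt(n_cells)))
    rng = np.random.default_rng(seed)
    layers = []
    for sm, mu, sd in zip(smoothing, means, sds):
        z = gaussian_filter(rng.standard_normal((side, side)), sm, mode="wrap")
        z = (z - z.mean()) / z.std()
        layers.append(mu + sd * z)
    return EnvironmentalField(
        covariates=np.stack([z.ravel() for z in layers], axis=1),
        grid_shape=(side, side),
        params={
            "seed": seed, "smoothing": tuple(smoothing),
            "means": tuple(means), "sds": tuple(sds),
        },
    )


def probability_surface(
    model: SpeciesModel, env: EnvironmentalField
) -> np.ndarray:
    """Per-cell P(y=1 | x): logistic of the linear or centered-quadratic
    predictor. expit saturates gracefully at extreme predictors."""
    x = env.covariates
    b = np.array([model.b1, model.b2, model.b3])
    if model.form == "linear":
        eta = model.b0 + x @ b
    else:
        center = (
            np.asarray(model.covariate_means, dtype=float)
            if model.covariate_means is not None
            else env.means()
        )
        eta = model.b0 + ((x - center) ** 2) @ b
    return expit(eta)


@dataclass
class Realization:
    """One Bernoulli draw of the binary occurrence map."""

    probability: np.ndarray
    labels: np.ndarray
    seed: "int | None" = None

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def prevalence(self) -> float:
        """Realized prevalence — fraction of presence cells."""
        return float(self.labels.mean())


def realize(surface: np.ndarray, seed: "int | None" = None) -> Realization:
    """Draw per-cell labels: presence iff q < P(y=1|x) with q ~ U[0,1)."""
    surface = np.asarray(surface, dtype=float)
    rng = np.random.default_rng(seed)
    q = rng.random(surface.shape)
    return Realization(probability=surface, labels=q < surface, seed=seed)


def _scores_for(real: Realization, scores: "np.ndarray | None") -> np.ndarray:
    if scores is None:
        return real.probability
    scores = np.asarray(scores, dtype=float)
    if scores.shape != real.labels.shape:
        raise ValueError("scores must align with the realization's cells")
    return scores


def sample_case_control(
    real: Realization,
    n_presence: int = 1000,
    bg_ratio: float = 5.0,
    seed: "int | None" = None,
    scores: "np.ndarray | None" = None,
) -> ScoredSet:
    """Case-control presence-background test set.

    n1 = ``n_presence`` labeled presences drawn without replacement from
    the presence cells; n0 = round(bg_ratio * n1) background cells drawn
    from all cells (without replacement when the grid allows, with
    replacement — flagged in meta — otherwise). Scores default to the
    true probability surface; pass a degraded surface to emulate a
    weaker model. Hidden truth is retained for oracle checks, and the
    population-implied c (n1 / (n1 + n0 * prevalence)) plus the realized
    in-set c are recorded in ``meta``.
    """
    rng = np.random.default_rng(seed)
    sc = _scores_for(real, scores)
    presence_cells = np.flatnonzero(real.labels)
    if presence_cells.size < n_presence:
        raise InsufficientPresenceError(
            f"map has {presence_cells.size} presence cells, need {n_presence}"
        )
    labeled_idx = rng.choice(presence_cells, size=n_presence, replace=False)
    n0 = int(round(bg_ratio * n_presence))
    with_replacement = n0 > real.n_cells
    bg_idx = rng.choice(real.n_cells, size=n0, replace=with_replacement)
    idx = np.concatenate([labeled_idx, bg_idx])
    labels = np.zeros(idx.size, dtype=bool)
    labels[:n_presence] = True
    truth = real.labels[idx].copy()
    truth[:n_presence] = True  # labeled records are presences by construction
    prev = real.prevalence
    n_bg_presence = int(real.labels[bg_idx].sum())
    return ScoredSet(
        scores=sc[idx],
        labels=labels,
        mode="pb",
        scenario=Scenario.CASE_CONTROL,
        true_labels=truth,
        meta={
            "implied_c": n_presence / (n_presence + n0 * prev),
            "realized_c": n_presence / (n_presence + n_bg_presence),
            "realized_prevalence": prev,
            "cell_indices": idx,
            "bg_with_replacement": with_replacement,
        },
    )


def sample_single_training_set(
    real: Realization,
    t: int = 6000,
    detect_prob: float = 0.5,
    seed: "int | None" = None,
    scores: "np.ndarray | None" = None,
) -> ScoredSet:
    """Single-training-set sample: ``t`` random cells, each presence
    labeled independently with probability ``detect_prob``.

    The realized c (labeled / presences in the set) and the implied
    population c are recorded in ``meta``.
    """
    if t > real.n_cells:
        raise ValueError(f"t = {t} exceeds the map's {real.n_cells} cells")
    rng = np.random.default_rng(seed)
    sc = _scores_for(real, scores)
    idx = rng.choice(real.n_cells, size=t, replace=False)
    truth = real.labels[idx]
    labels = truth & (rng.random(t) < detect_prob)
    n_pres = int(truth.sum())
    return ScoredSet(
        scores=sc[idx],
        labels=labels,
        mode="pb",
        scenario=Scenario.SINGLE_TRAINING_SET,
        true_labels=truth,
        meta={
            "implied_c": detect_prob,
            "realized_c": labels.sum() / n_pres if n_pres else float("nan"),
            "realized_prevalence": real.prevalence,
            "cell_indices": idx,
        },
    )


def degrade_model(
    surface: np.ndarray, swap_fraction: float, seed: "int | None" = None
) -> np.ndarray:
    """Weaken a scorer by swapping P(y=1|x) and P(y=0|x) = 1 - P(y=1|x)
    at a random fraction of cells; swap_fraction 0 is the identity and 1
    inverts the model (AUC of roughly 1 - original)."""
    if not 0.0 <= swap_fraction <= 1.0:
        raise ValueError(f"swap_fraction must be in [0, 1], got {swap_fraction}")
    surface = np.asarray(surface, dtype=float)
    out = surface.copy()
    if swap_fraction > 0:
        rng = np.random.default_rng(seed)
        n_swap = int(round(swap_fraction * surface.size))
        swap = rng.choice(surface.size, size=n_swap, replace=False)
        flat = out.ravel()
        flat[swap] = 1.0 - flat[swap]
    return out
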