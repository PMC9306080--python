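"""Protein-space hit optimization: fingerprint classifier, beta score, ranking.

A four-layer neural network (400, 200, 400, 2; Tanh on the first three
layers, softmax output) is trained on substructure-count fingerprints for
50 epochs with fivefold cross-validation and a grid search over momentum,
learning-rate annealing and input-dropout ratio.  The input layer computes
the affine map alpha = sum_i w_i x_i + b; f(alpha) denotes the network's
positive-class probability.

Hit optimization fuses the classifier with the docking-derived interaction
count: beta = f(alpha) + d_i.  Candidates whose d_i falls inside a
target-specific window (e.g. 9-12 for CXCR4, 6-8 for the androgen
receptor; both ends inclusive) are ranked by beta descending; because
f(alpha) < 1, an integer difference in d_i always dominates the ranking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cs_stack import classification_metrics, make_folds

DEFAULT_PS_FOLDS = 5
DEFAULT_PS_ARCH = (400, 200, 400, 2)


@dataclass
class PSModelConfig:
    """Network architecture, training schedule and hyperparameter grid."""

    layers: tuple[int, ...] = DEFAULT_PS_ARCH
    activation: str = "tanh"
    epochs: int = 50
    folds: int = DEFAULT_PS_FOLDS
    momentum_grid: tuple[float, ...] = (0.9,)
    rate_annealing_grid: tuple[float, ...] = (1e-6,)
    input_dropout_grid: tuple[float, ...] = (0.0,)
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("need at least one hidden layer plus the output layer")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.momentum_grid and self.rate_annealing_grid and self.input_dropout_grid):
            raise ValueError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        return [
            {"momentum": m, "rate_annealing": r, "input_dropout": d}
            for m, r, d in itertools.product(
                self.momentum_grid, self.rate_annealing_grid, self.input_dropout_grid
            )
        ]


def _build_net(cfg: PSModelConfig, point: Mapping[str, float], seed: int):
    from sklearn.neural_network import MLPClassifier

    # Rate annealing maps onto the inverse-scaling schedule of plain SGD:
    # a larger annealing value decays the step size faster.
    power_t = 0.5 * (1.0 + min(1.0, point["rate_annealing"] * 1e4))
    return MLPClassifier(
        hidden_layer_sizes=tuple(cfg.layers[:-1]),
        activation=cfg.activation,
        solver="sgd",
        momentum=point["momentum"],
        learning_rate="invscaling",
        learning_rate_init=cfg.learning_rate,
        power_t=power_t,
        batch_size=32,
        max_iter=cfg.epochs,
        random_state=seed,
    )


def _apply_input_dropout(X: np.ndarray, ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Training-time input masking standing in for an input-dropout layer."""
    if ratio <= 0:
        return X
    mask = rng.random(X.shape) >= ratio
    return X * mask


def _validate_counts(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("fingerprint matrix must be 2-D")
    if (X < 0).any():
        raise ValueError("fingerprint counts must be non-negative")
    if not np.allclose(X, np.round(X)):
        raise ValueError("fingerprint counts must be integers")
    return X


@dataclass
class PSModel:
    """Trained protein-space classifier plus its selection provenance."""

    net: object
    config: PSModelConfig
    best_point: dict
    cv_results: pd.DataFrame
    scale: float

    def predict_f_alpha(self, X) -> np.ndarray:
        """Positive-class probability f(alpha) for each fingerprint row."""
        X = _validate_counts(np.asarray(X, dtype=float)) / self.scale
        proba = self.net.predict_proba(X)
        classes = list(self.net.classes_)
        return proba[:, classes.index(1)]


def fit_ps_model(
    fp_matrix, y: Sequence[int], cfg: PSModelConfig | None = None
) -> PSModel:
    """Grid-searched, cross-validated training of the protein-space network.

    Every grid point is evaluated by stratified k-fold cross-validation
    (default fivefold); the winner has the highest mean CV AUC, ties broken
    by higher mean accuracy then grid order.  The final network is refitted
    on all data at the winning point.  Counts are scaled by their global
    maximum before entering the Tanh network.
    """
    from sklearn.exceptions import ConvergenceWarning

    cfg = cfg or PSModelConfig()
    X = _validate_counts(np.asarray(fp_matrix, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    scale = float(X.max()) or 1.0
    Xs = X / scale
    folds = make_folds(len(y), cfg.folds, cfg.seed, stratify_labels=y)
    rng = np.random.default_rng(cfg.seed)

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for g, point in enumerate(cfg.grid_points()):
            aucs, accs = [], []
            for j in range(folds.J):
                train = np.flatnonzero(folds.fold_of != j)
                test = folds.indices(j)
                net = _build_net(cfg, point, seed=cfg.seed + g)
                Xtr = _apply_input_dropout(Xs[train], point["input_dropout"], rng)
                net.fit(Xtr, y[train])
                proba = net.predict_proba(Xs[test])
                p1 = proba[:, list(net.classes_).index(1)]
                met = classification_metrics(y[test], p1)
                aucs.append(met.auc if met.auc is not None else 0.5)
                accs.append(met.accuracy)
            rows.append({**point, "cv_auc": float(np.mean(aucs)),
                         "cv_accuracy": float(np.mean(accs)), "grid_index": g})
        results = pd.DataFrame(rows)
        best = results.sort_values(
            ["cv_auc", "cv_accuracy", "grid_index"], ascending=[False, False, True]
        ).iloc[0]
        best_point = {k: best[k] for k in ("momentum", "rate_annealing", "input_dropout")}
        final = _build_net(cfg, best_point, seed=cfg.seed + int(best["grid_index"]))
        Xtr = _apply_input_dropout(Xs, best_point["input_dropout"], rng)
        final.fit(Xtr, y)
    return PSModel(net=final, config=cfg, best_point=best_point,
                   cv_results=results, scale=scale)


# --------------------------------------------------------------------------
# Beta score and ranking
# --------------------------------------------------------------------------

def score_beta(f_alpha: float, d_i: int) -> float:
    """Optimization score beta = f(alpha) + d_i."""
    if not 0 <= f_alpha <= 1:
        raise ValueError("f_alpha must be a probability in [0, 1]")
    if d_i < 0 or int(d_i) != d_i:
        raise ValueError("d_i must be a non-negative integer")
    return float(f_alpha) + int(d_i)


@dataclass(frozen=True)
class ThresholdWindow:
    """Inclusive interaction-count window for a target (e.g. 9-12 for CXCR4)."""

    d_min: int
    d_max: int
    target: str = ""

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.d_max < self.d_min:
            raise ValueError("need 0 <= d_min <= d_max")

    def contains(self, d_i: int) -> bool:
        return self.d_min <= d_i <= self.d_max


CXCR4_WINDOW = ThresholdWindow(9, 12, "CXCR4")
AR_WINDOW = ThresholdWindow(6, 8, "AR")


@dataclass
class RankedHit:
    molecule_id: str
    f_alpha: float
    d_i: int
    beta: float
    passed_window: bool
    rank: int | None = None


def rank_hits(
    predictions: Mapping[str, float] | pd.DataFrame,
    profiles: Mapping[str, int],
    window: ThresholdWindow,
    truth: Mapping[str, int] | None = None,
    cut: float = 0.5,
) -> list[RankedHit]:
    """Window-filtered beta ranking of classifier-positive candidates.

    ``predictions`` maps molecule id to f(alpha) (or is a DataFrame with
    columns ``id``/``f_alpha``); ``profiles`` maps id to d_i.  Candidates
    are the predicted positives (f(alpha) >= cut); when ``truth`` is
    supplied only true positives are kept, matching the published
    evaluation mode.  Candidates inside the window are ranked by beta
    descending (ties: higher f_alpha, then id); out-of-window candidates
    follow unranked with ``passed_window=False``.
    """
    if isinstance(predictions, pd.DataFrame):
        predictions = dict(zip(predictions["id"].astype(str), predictions["f_alpha"]))
    candidates = {str(k): float(v) for k, v in predictions.items() if float(v) >= cut}
    if truth is not None:
        candidates = {k: v for k, v in candidates.items() if int(truth[k]) == 1}
    missing = sorted(k for k in candidates if k not in profiles)
    if missing:
        raise ValueError(f"no interaction profile for candidate(s): {missing}")

    hits = []
    for mol_id, f in candidates.items():
        d = int(profiles[mol_id])
        hits.append(RankedHit(
            molecule_id=mol_id, f_alpha=f, d_i=d,
            beta=score_beta(f, d), passed_window=window.contains(d),
        ))
    passing = sorted((h for h in hits if h.passed_window),
                     key=lambda h: (-h.beta, -h.f_alpha, h.molecule_id))
    failing = sorted((h for h in hits if not h.passed_window),
                     key=lambda h: h.molecule_id)
    for i, h in enumerate(passing, start=1):
        h.rank = i
    return passing + failing


def ranked_hits_frame(hits: Sequence[RankedHit]) -> pd.DataFrame:
    """Tidy ranked-hit table (id, f_alpha, d_i, beta, rank, passed_window)."""
    return pd.DataFrame([
        {"id": h.molecule_id, "f_alpha": h.f_alpha, "d_i": h.d_i,
         "beta": h.beta, "rank": h.rank, "passed_window": h.passed_window}
        for h in hits
    ])
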