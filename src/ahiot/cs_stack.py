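"""Chemical-space stacked ensemble and its evaluation metrics.

Stacked generalization on molecular descriptors: tier-0 base learners
(random forest and extreme gradient boosting by default) are evaluated by
J-fold cross-validation, and their *out-of-fold* positive-class
probabilities z_nt — instance n is always predicted by a model trained
without n's fold — form the level-one dataset on which a small neural
network (the super learner, hidden layers 200 and 400 with Tanh, softmax
output, 50 epochs) is trained.  For deployment the base learners are
refitted on the full training matrix and chained with the super learner.

Metrics: accuracy, sensitivity Se, specificity Sp, rank-based AUC, the
balanced classification rate BCR = ((Se+Sp)/2)*(1-|Se-Sp|), and the
ensemble diversity entropy E in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_prep import DescriptorMatrix

DEFAULT_CS_FOLDS = 10
DEFAULT_SUPER_ARCH = (200, 400, 2)
DEFAULT_EPOCHS = 50


# --------------------------------------------------------------------------
# Fold bookkeeping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Assignment of n instances to J approximately uniform folds."""

    n: int
    J: int
    fold_of: np.ndarray
    seed: int

    def indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == j)


def make_folds(
    n: int, J: int, seed: int, stratify_labels: Sequence[int] | None = None
) -> FoldAssignment:
    """Draw a J-fold split with fold sizes differing by at most one.

    With ``stratify_labels`` each class is dealt round-robin so per-fold
    class counts differ from proportionality by at most one instance.
    Deterministic for a fixed ``(n, J, seed)``.
    """
    if not 2 <= J <= n:
        raise ValueError(f"need 2 <= J <= n, got J={J}, n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratify_labels is None:
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            fold_of[idx] = pos % J
    else:
        y = np.asarray(stratify_labels)
        if y.shape != (n,):
            raise ValueError("stratify_labels length must equal n")
        start = 0  # offset so small classes do not pile onto fold 0
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            if len(members) < J:
                raise ValueError(
                    f"class {cls} has {len(members)} members, fewer than J={J}"
                )
            members = rng.permutation(members)
            for pos, idx in enumerate(members):
                fold_of[idx] = (start + pos) % J
            start += len(members)
    return FoldAssignment(n=n, J=J, fold_of=fold_of, seed=seed)


# --------------------------------------------------------------------------
# Base learners
# --------------------------------------------------------------------------

class _MajorityClass:
    """Toy learner: predicts its training majority class with certainty."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self._p = float(vals[np.argmax(counts)])
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self._p)
        return np.column_stack([1 - p, p])


class _Constant:
    """Toy learner: constant positive-class probability."""

    def __init__(self, p: float = 0.5):
        self.p = p

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def make_base_learner(spec: str | Callable, seed: int = 0):
    """Instantiate a base learner from a registry name or a factory callable.

    Registry names: ``random_forest``, ``xgboost``, ``majority_class``,
    ``constant``, ``knn1`` (a memorizing 1-nearest-neighbour, used as a
    leakage sentinel in tests).
    """
    if callable(spec):
        return spec(seed)
    if spec == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if spec == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, max_depth=4, learning_rate=0.2,
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0,
        )
    if spec == "majority_class":
        return _MajorityClass()
    if spec == "constant":
        return _Constant()
    if spec == "knn1":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=1)
    raise ValueError(f"unknown base-learner spec {spec!r}")


DEFAULT_BASE_LEARNERS = ("random_forest", "xgboost")


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probability, robust to models fit on a single class."""
    proba = model.predict_proba(X)
    classes = getattr(model, "classes_", None)
    if classes is None:
        return proba[:, 1]
    classes = list(classes)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(len(X))


# --------------------------------------------------------------------------
# Level-one data and the super learner
# --------------------------------------------------------------------------

@dataclass
class LevelOneData:
    """Out-of-fold base-learner probabilities z (N x T) plus labels."""

    z: np.ndarray
    y: np.ndarray
    learner_names: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.z.ndim != 2 or self.z.shape[0] != len(self.y):
            raise ValueError("z must be N x T aligned with y")
        if self.z.shape[1] != len(self.learner_names):
            raise ValueError("one column per learner required")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite out-of-fold predictions")
        if self.z.min() < 0 or self.z.max() > 1:
            raise ValueError("out-of-fold predictions must be probabilities in [0,1]")


def fit_base_oof(
    m: DescriptorMatrix,
    learners: Sequence[str | Callable] = DEFAULT_BASE_LEARNERS,
    folds: FoldAssignment | None = None,
    seed: int = 0,
) -> LevelOneData:
    """Cross-validated tier-0 training: z_nt from a model that never saw fold(n).

    For each fold j and learner t a fresh model is trained on every fold
    except j and predicts fold j, so each instance receives exactly one
    out-of-fold probability per learner (no label leakage into tier-1 data).
    """
    if m.labels is None:
        raise ValueError("labels required to fit base learners")
    y = np.asarray(m.labels)
    folds = folds or make_folds(m.n, DEFAULT_CS_FOLDS, seed, stratify_labels=y)
    z = np.full((m.n, len(learners)), np.nan)
    names = [spec if isinstance(spec, str) else getattr(spec, "__name__", "custom")
             for spec in learners]
    for t, spec in enumerate(learners):
        for j in range(folds.J):
            test_idx = folds.indices(j)
            train_idx = np.flatnonzero(folds.fold_of != j)
            model = make_base_learner(spec, seed=seed + t)
            try:
                model.fit(m.values[train_idx], y[train_idx])
                z[test_idx, t] = _positive_proba(model, m.values[test_idx])
            except Exception as exc:
                raise RuntimeError(f"base learner {names[t]!r} failed on fold {j}: {exc}") from exc
    return LevelOneData(z=z, y=y, learner_names=names)


@dataclass
class StackedModel:
    """Deployable stacked ensemble: refitted base learners + super learner."""

    base_models: list
    super_model: object
    learner_names: list[str]
    feature_names: list[str] | None
    training_config: dict = field(default_factory=dict)

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([_positive_proba(b, X) for b in self.base_models])

    def predict_proba_z(self, z: np.ndarray) -> np.ndarray:
        return self.super_model.predict_proba(np.asarray(z, dtype=float))


def fit_super_learner(
    l1: LevelOneData,
    arch: Sequence[int] = DEFAULT_SUPER_ARCH,
    activation: str = "tanh",
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    base_training: tuple[DescriptorMatrix, Sequence] | None = None,
) -> StackedModel:
    """Train the tier-1 network on level-one data.

    ``arch`` lists the hidden-layer widths followed by the 2-unit output
    layer; the hidden layers use Tanh and the output is a 2-way normalized
    exponential so class probabilities sum to one.  If ``base_training``
    supplies ``(descriptor_matrix, learner_specs)``, the base learners are
    refitted on the full matrix so the returned model can score raw
    descriptor rows.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPClassifier

    if len(np.unique(l1.y)) < 2:
        raise ValueError("level-one labels contain a single class")
    hidden = tuple(int(h) for h in arch[:-1]) if len(arch) > 1 else tuple(arch)
    net = MLPClassifier(
        hidden_layer_sizes=hidden, activation=activation, solver="adam",
        max_iter=int(epochs), random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(l1.z, l1.y)
    base_models, feature_names = [], None
    if base_training is not None:
        m, specs = base_training
        feature_names = list(m.feature_names)
        for t, spec in enumerate(specs):
            model = make_base_learner(spec, seed=seed + t)
            model.fit(m.values, np.asarray(m.labels))
            base_models.append(model)
    return StackedModel(
        base_models=base_models,
        super_model=net,
        learner_names=list(l1.learner_names),
        feature_names=feature_names,
        training_config={"arch": tuple(arch), "activation": activation,
                         "epochs": int(epochs), "seed": int(seed)},
    )


def train_stacked(
    m: DescriptorMatrix,
    learners: Sequence[str | Callable] = DEFAULT_BASE_LEARNERS,
    J: int = DEFAULT_CS_FOLDS,
    seed: int = 0,
    arch: Sequence[int] = DEFAULT_SUPER_ARCH,
    epochs: int = DEFAULT_EPOCHS,
) -> tuple[StackedModel, LevelOneData]:
    """End-to-end chemical-space training: folds, OOF tier-0, tier-1 network."""
    folds = make_folds(m.n, J, seed, stratify_labels=m.labels)
    l1 = fit_base_oof(m, learners, folds, seed=seed)
    model = fit_super_learner(l1, arch=arch, epochs=epochs, seed=seed,
                              base_training=(m, learners))
    return model, l1


def predict_stacked(model: StackedModel, m: DescriptorMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Score a descriptor matrix with a trained stacked model.

    Feature columns are aligned to the training manifest *by name* (order
    does not matter); missing or extra features raise listing them.  Returns
    ``(positive_probability, label)`` with the documented tie rule
    ``label = 1 iff probability >= 0.5``.
    """
    if model.feature_names is None or not model.base_models:
        raise ValueError("model has no refitted base learners; train with base_training")
    missing = sorted(set(model.feature_names) - set(m.feature_names))
    extra = sorted(set(m.feature_names) - set(model.feature_names))
    if missing or extra:
        raise ValueError(f"feature mismatch: missing={missing}, extra={extra}")
    aligned = m.select_features(model.feature_names)
    z = model.base_probabilities(aligned.values)
    proba = model.predict_proba_z(z)
    classes = list(model.super_model.classes_)
    pos = proba[:, classes.index(1)]
    return pos, (pos >= 0.5).astype(int)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def bcr(se: float, sp: float) -> float:
    """Balanced classification rate: ((Se+Sp)/2) * (1 - |Se-Sp|).

    Penalizes sensitivity/specificity imbalance; 1.0 only for a perfect,
    perfectly balanced classifier.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return ((se + sp) / 2.0) * (1.0 - abs(se - sp))


def ensemble_entropy(pred_matrix: np.ndarray, y: Sequence[int]) -> float:
    """Diversity entropy E of an ensemble's per-instance error pattern.

    E = (1/N) * sum_i min(theta_i, T - theta_i) / (T - ceil(T/2)), where
    theta_i is the number of classifiers misclassifying instance i.  E = 0
    when all classifiers behave identically on every instance and E = 1 at
    maximal disagreement.
    """
    preds = np.asarray(pred_matrix)
    y = np.asarray(y)
    if preds.ndim != 2 or preds.shape[0] != len(y):
        raise ValueError("pred_matrix must be N x T aligned with y")
    n, t = preds.shape
    if t < 2:
        raise ValueError("need at least two classifiers")
    if not np.isin(preds, (0, 1)).all():
        raise ValueError("predictions must be binary")
    theta = (preds != y[:, None]).sum(axis=1)
    denom = t - math.ceil(t / 2)
    return float(np.minimum(theta, t - theta).sum() / (n * denom))


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    bcr: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc, "bcr": self.bcr,
        }


def classification_metrics(
    y_true: Sequence[int], proba: Sequence[float], cut: float = 0.5
) -> ClassificationMetrics:
    """Accuracy, Se, Sp, rank-based AUC and BCR at a probability cut.

    AUC is the Mann–Whitney statistic (ties at mid-rank); with a
    single-class truth vector AUC is reported as ``None`` and the other
    metrics are still computed.  The label rule is ``proba >= cut``.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(y_true, dtype=int)
    p = np.asarray(proba, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y_true and proba must align")
    pred = (p >= cut).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    se = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / len(y)
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
    return ClassificationMetrics(accuracy=acc, sensitivity=se, specificity=sp,
                                 auc=auc, bcr=bcr(se, sp))
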