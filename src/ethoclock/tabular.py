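"""Tabular window classifiers, ensemble vote, and backward feature elimination.

Three classifiers consume the flattened (steps x behaviors) window matrix:
logistic regression (C=0.1, newton-cg, L2 — suited to the heavily collinear
composition columns), a random forest (80 trees, sqrt feature rule, minimum
leaf 40), and an RBF support vector machine (gamma=1, C=10).  Their
equal-weight majority vote forms the ensemble.  Backward elimination removes
whole behaviors (all positional columns at once, re-windowing each time)
until test accuracy starts to decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .core import BehaviorCatalog, PhaseSchedule
from .windows import build_windows, drop_behaviors, flatten_windows, SampleSeries

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "EliminationTrace",
    "EliminationProtocol",
    "SELECTED_BEHAVIORS",
    "default_grid",
    "fit_classifier",
    "grid_search",
    "majority_vote",
    "backward_eliminate",
    "permutation_importance",
]

#: The six behaviors retained by backward elimination on the real recordings
#: (sleep plus the prominent exploratory repertoire).
SELECTED_BEHAVIORS = (
    "Sleep", "Turn", "remain.Hang.Cuddled", "Walk.Left", "Dig", "Forage",
)

_KINDS = ("logistic", "forest", "svm")


def default_grid(kind: str) -> list["ModelSpec"]:
    """Shipped hyperparameter grids for :func:`grid_search`.

    The SVM gamma grid spans down to 1e-3 because with thousands of
    composition columns typical squared distances between windows are of
    order 1e2, so useful RBF widths sit near 1/||dx||^2.  The forest grid
    reaches down to min_leaf 2: per-position composition columns are
    individually weak, and shallow leaves cost the forest several accuracy
    points on this representation.
    """
    if kind == "logistic":
        return [ModelSpec.logistic(C=c) for c in (0.01, 0.1, 1.0, 10.0)]
    if kind == "forest":
        return [
            ModelSpec.forest(n_trees=t, min_leaf=l)
            for t in (80, 160, 320) for l in (2, 10, 40)
        ]
    if kind == "svm":
        return [
            ModelSpec.svm(svm_C=c, gamma=g)
            for c in (1.0, 10.0, 100.0) for g in (1e-3, 1e-2, 1e-1, 1.0)
        ]
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters for one tabular classifier.

    Defaults are the grid-search-tuned values for each kind: logistic
    (C=0.1, L2, newton-cg), forest (80 trees, sqrt features, min leaf 40),
    svm (RBF, gamma=1, C=10).
    """

    kind: str = "logistic"
    C: float = 0.1                # inverse regularization (logistic)
    penalty: str = "l2"
    solver: str = "newton-cg"
    n_trees: int = 80
    max_features: str = "sqrt"
    min_leaf: int = 40
    svm_C: float = 10.0
    gamma: float = 1.0
    kernel: str = "rbf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        for name in ("C", "n_trees", "min_leaf", "svm_C", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def logistic(cls, C: float = 0.1, seed: int = 0) -> "ModelSpec":
        return cls(kind="logistic", C=C, seed=seed)

    @classmethod
    def forest(cls, n_trees: int = 80, min_leaf: int = 40, seed: int = 0) -> "ModelSpec":
        return cls(kind="forest", n_trees=n_trees, min_leaf=min_leaf, seed=seed)

    @classmethod
    def svm(cls, svm_C: float = 10.0, gamma: float = 1.0, seed: int = 0) -> "ModelSpec":
        return cls(kind="svm", svm_C=svm_C, gamma=gamma, seed=seed)


@dataclass
class TrainedModel:
    """A fitted classifier plus the feature manifest it was trained on."""

    spec: ModelSpec
    estimator: object
    n_features: int
    feature_names: tuple[str, ...] | None = None
    window_len: int | None = None
    n_behaviors: int | None = None

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard 0/1 (day/night) labels."""
        return self.estimator.predict(self._check(X)).astype(np.int8)

    def score_night(self, X: np.ndarray) -> np.ndarray:
        """Continuous score in [0, 1] for the night class, for ROC curves.

        Probability for probabilistic models; the SVM decision value is
        mapped through a logistic link (any monotone map preserves the ROC).
        """
        X = self._check(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        return expit(est.decision_function(X))


def _build_estimator(spec: ModelSpec):
    if spec.kind == "logistic":
        if spec.penalty != "l2":
            raise ValueError("only L2 regularization is supported")
        return LogisticRegression(C=spec.C, solver=spec.solver, max_iter=1000)
    if spec.kind == "forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=spec.max_features,
            min_samples_leaf=spec.min_leaf,
            random_state=spec.seed,
            n_jobs=1,
        )
    return SVC(kernel=spec.kernel, gamma=spec.gamma, C=spec.svm_C)


def fit_classifier(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    *,
    catalog: BehaviorCatalog | None = None,
    window_len: int | None = None,
) -> TrainedModel:
    """Fit one tabular classifier on flattened windows.

    ``y`` must contain both classes — a single-class fit would yield a
    silent constant predictor that corrupts ensemble votes.  Deterministic
    given ``spec.seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(np.int8).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    est = _build_estimator(spec)
    est.fit(X, y)
    names = None
    nb = None
    if catalog is not None and window_len is not None:
        nb = catalog.size
        if window_len * nb != X.shape[1]:
            raise ValueError("catalog/window_len inconsistent with feature count")
        names = tuple(
            f"t{t:03d}.{b}" for t in range(window_len) for b in catalog.names
        )
    return TrainedModel(
        spec=spec, estimator=est, n_features=X.shape[1],
        feature_names=names, window_len=window_len, n_behaviors=nb,
    )


def grid_search(
    grid,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    *,
    block_len: int = 1,
) -> ModelSpec:
    """Pick the spec with the highest mean k-fold accuracy.

    Folds are grouped contiguous blocks (``block_len`` windows) so that
    overlapping windows never leak across the split.  Ties break to the
    first spec in grid order.
    """
    from .evaluate import block_kfold  # local import to avoid a cycle

    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    folds = block_kfold(len(y), k=k, block_len=block_len, seed=seed, labels=y)
    best_spec, best_acc = None, -np.inf
    for spec in grid:
        accs = []
        for train_idx, test_idx in folds:
            m = fit_classifier(spec, X[train_idx], y[train_idx])
            accs.append(float(np.mean(m.predict(X[test_idx]) == y[test_idx])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_spec, best_acc = spec, mean_acc
    return best_spec


def majority_vote(pred_a, pred_b, pred_c) -> np.ndarray:
    """Elementwise modal label of three binary prediction vectors.

    With three voters and two classes there are no ties, so no tie-breaking
    rule is needed.
    """
    a, b, c = (np.asarray(p) for p in (pred_a, pred_b, pred_c))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("prediction vectors must have equal length")
    total = a.astype(np.int32) + b.astype(np.int32) + c.astype(np.int32)
    return (total >= 2).astype(a.dtype)


@dataclass(frozen=True)
class EliminationProtocol:
    """Evaluation protocol for backward elimination.

    Windows are rebuilt for each candidate behavior subset, then split by
    shuffled contiguous blocks into 20% tuning / 50% training / 30% test
    (the tuning share is reserved for hyperparameter search and unused when
    the spec is fixed).  Block grouping prevents leakage between
    overlapping windows.
    """

    window_len: int = 100
    stride: int = 1
    encoding: str = "composition"
    fracs: tuple[float, float, float] = (0.2, 0.5, 0.3)  # tune/train/test
    block_len: int | None = None  # default: ceil(window_len / stride)
    seed: int = 0


@dataclass
class EliminationTrace:
    """Record of one backward-elimination run."""

    steps: list  # (removed_behavior, best_accuracy_after_removal)
    retained: tuple[str, ...]
    retained_accuracy: float
    baseline_accuracy: float
    stop_reason: str
    fits_per_iteration: list = field(default_factory=list)

    @property
    def n_fits(self) -> int:
        return int(sum(self.fits_per_iteration))


def _subset_accuracy(
    spec: ModelSpec,
    samples: SampleSeries,
    schedule: PhaseSchedule,
    keep: tuple[str, ...],
    protocol: EliminationProtocol,
) -> float:
    from .evaluate import block_split  # local import to avoid a cycle

    sub = drop_behaviors(samples, keep)
    ws = build_windows(
        sub, schedule, window_len=protocol.window_len,
        stride=protocol.stride, encoding=protocol.encoding,
    )
    X = flatten_windows(ws)
    y = ws.labels
    block_len = protocol.block_len or -(-protocol.window_len // protocol.stride)
    tune_idx, train_idx, test_idx = block_split(
        len(y), protocol.fracs, block_len=block_len, seed=protocol.seed
    )
    model = fit_classifier(spec, X[train_idx], y[train_idx])
    return float(np.mean(model.predict(X[test_idx]) == y[test_idx]))


def backward_eliminate(
    spec: ModelSpec,
    samples: SampleSeries,
    schedule: PhaseSchedule,
    eval_protocol: EliminationProtocol | None = None,
    tolerance: float = 0.005,
    *,
    patience: int = 1,
    start_behaviors=None,
    max_iterations: int | None = None,
) -> EliminationTrace:
    """Drop-one-out backward elimination over whole behaviors.

    Each iteration rebuilds windows without each remaining behavior in turn
    (elimination must happen before windowing, since every behavior owns one
    column per step), removes the behavior whose omission gives the highest
    test accuracy, and stops once the best candidate falls more than
    ``tolerance`` below the best accuracy seen, for ``patience`` consecutive
    iterations.  The retained set is the one at the accuracy peak.
    """
    protocol = eval_protocol or EliminationProtocol()
    remaining = list(start_behaviors or samples.catalog.names)
    if len(remaining) < 2:
        raise ValueError("need at least 2 behaviors to eliminate from")

    baseline = _subset_accuracy(spec, samples, schedule, tuple(remaining), protocol)
    best_acc = baseline
    best_set = tuple(remaining)
    steps: list = []
    fits_per_iter: list = []
    declines = 0
    stop_reason = "exhausted"

    while len(remaining) > 1:
        if max_iterations is not None and len(fits_per_iter) >= max_iterations:
            stop_reason = "max_iterations"
            break
        candidates = []
        for b in remaining:
            keep = tuple(x for x in remaining if x != b)
            acc = _subset_accuracy(spec, samples, schedule, keep, protocol)
            candidates.append((b, acc))
        fits_per_iter.append(len(remaining))
        removed, acc = max(candidates, key=lambda t: t[1])  # first-wins on ties
        steps.append((removed, acc))
        if acc < best_acc - tolerance:
            declines += 1
            if declines >= patience:
                stop_reason = "accuracy declined"
                break
        else:
            declines = 0
        remaining.remove(removed)
        if acc > best_acc:
            best_acc = acc
            best_set = tuple(remaining)

    return EliminationTrace(
        steps=steps,
        retained=best_set,
        retained_accuracy=best_acc,
        baseline_accuracy=baseline,
        stop_reason=stop_reason,
        fits_per_iteration=fits_per_iter,
    )


def permutation_importance(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Accuracy drop when each behavior's columns are jointly shuffled.

    All positional columns of a behavior are permuted with the same row
    permutation, so the behavior's within-window temporal pattern moves to
    another window wholesale.  Returns one mean importance per behavior.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if model.n_behaviors is None or model.window_len is None:
        raise ValueError("model lacks a feature manifest (fit with catalog/window_len)")
    X = np.asarray(X)
    y = np.asarray(y).ravel()
    nb, L = model.n_behaviors, model.window_len
    rng = np.random.default_rng(seed)
    base_acc = float(np.mean(model.predict(X) == y))
    cols_of = [np.arange(L) * nb + b for b in range(nb)]
    imp = np.zeros(nb)
    for b in range(nb):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, cols_of[b]] = X[perm][:, cols_of[b]]
            drops.append(base_acc - float(np.mean(model.predict(Xp) == y)))
        imp[b] = np.mean(drops)
    return imp
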