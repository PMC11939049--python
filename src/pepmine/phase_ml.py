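"""Phase-classification protocol: splits, oversampling, model selection, metrics,
and grouped Shapley feature importance.

The protocol mirrors the study design used for the curated dataset:

* a 60/15/25 train/validation/test split, either fully random or grouped by
  source publication (so the test set comes from unseen studies);
* minority-class oversampling (SMOTE) of the *training* partition only,
  synthesizing points by interpolating between same-class nearest neighbors
  in the encoded feature space;
* grid search over three hyperparameter axes per classifier family
  (random forest, multilayer perceptron, Gaussian process, k-nearest
  neighbors) scored by five-fold cross-validation;
* precision / recall / F1 plus an 8x8 confusion matrix on the held-out test
  set; a uniform random guesser over the 8 phases scores 1/8 = 0.125, the
  chance baseline every model is compared against;
* model interpretation via Shapley values estimated by permutation sampling,
  with per-dimension attributions summed over each named feature's one-hot
  span ("grouped" importance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .dataset_model import PHASES, PeptideRecord
from .encoding import FeatureGroupMap

logger = logging.getLogger(__name__)

SPLIT_FRACTIONS = (0.60, 0.15, 0.25)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split specification."""

    mode: Literal["random", "by_publication"] = "random"
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1 (got {self.fractions})")


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Rounding convention: train = round(f_tr*n), val = round(f_va*n), test = rest."""
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    return n_train, n_val, n - n_train - n_val


def make_splits(
    records: Sequence[PeptideRecord], spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition record indices into disjoint, exhaustive train/val/test sets.

    ``by_publication`` mode splits the *publications* (source_id groups) so
    that no publication contributes to two partitions; all of a paper's
    records follow it into its partition.
    """
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty record list")
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "random":
        perm = rng.permutation(n)
        n_tr, n_va, _ = _partition_sizes(n, spec.fractions)
        return (
            np.sort(perm[:n_tr]),
            np.sort(perm[n_tr : n_tr + n_va]),
            np.sort(perm[n_tr + n_va :]),
        )

    if spec.mode == "by_publication":
        sources = [r.source_id for r in records]
        if any(not s for s in sources):
            raise ValueError("by_publication split requires source_id on every record")
        pubs = sorted(set(sources))
        perm = rng.permutation(len(pubs))
        n_tr, n_va, _ = _partition_sizes(len(pubs), spec.fractions)
        train_pubs = {pubs[i] for i in perm[:n_tr]}
        val_pubs = {pubs[i] for i in perm[n_tr : n_tr + n_va]}
        idx = np.arange(n)
        in_train = np.array([s in train_pubs for s in sources])
        in_val = np.array([s in val_pubs for s in sources])
        return idx[in_train], idx[in_val], idx[~in_train & ~in_val]

    raise ValueError(f"unknown split mode {spec.mode!r}")


def publication_leakage(
    records: Sequence[PeptideRecord], partitions: Sequence[np.ndarray]
) -> int:
    """Number of publications appearing in more than one partition."""
    seen: dict[str, int] = {}
    leaked = set()
    for p, idx in enumerate(partitions):
        for i in idx:
            s = records[int(i)].source_id
            if s in seen and seen[s] != p:
                leaked.add(s)
            seen.setdefault(s, p)
    return len(leaked)


# ---------------------------------------------------------------------------
# SMOTE oversampling
# ---------------------------------------------------------------------------


def oversample_train(
    X: np.ndarray,
    y: np.ndarray,
    *,
    strategy: dict[str, int] | Literal["balance"] = "balance",
    k_neighbors: int = 5,
    seed: int = 0,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: synthesize minority-class points by neighbor interpolation.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``, where
    ``x`` and ``x_nn`` are an existing minority instance and one of its
    ``k_neighbors`` nearest same-class neighbors.  Original rows are
    returned unchanged, followed by the synthetic rows.

    ``strategy='balance'`` raises every class to the majority count; a dict
    gives explicit per-class target counts.  Classes with a single instance
    cannot be interpolated: error under ``strict``, skipped (logged)
    otherwise.  ``k_neighbors`` is reduced to class size - 1 when needed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if strategy == "balance":
        target = {c: int(counts.max()) for c in classes}
    else:
        target = {c: int(strategy.get(c, int((y == c).sum()))) for c in classes}

    new_X, new_y = [X], [y]
    for c in classes:
        idx = np.flatnonzero(y == c)
        n_new = target[c] - idx.size
        if n_new <= 0:
            continue
        if idx.size < 2:
            msg = f"class {c!r} has {idx.size} instance(s); cannot interpolate"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; skipped", msg)
            continue
        k = min(k_neighbors, idx.size - 1)
        if k < k_neighbors:
            logger.info("class %r: k_neighbors reduced to %d", c, k)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
        neighbors = nn.kneighbors(X[idx], return_distance=False)[:, 1:]
        base = rng.integers(0, idx.size, size=n_new)
        pick = rng.integers(0, k, size=n_new)
        u = rng.random(size=n_new)
        x0 = X[idx[base]]
        x1 = X[idx[neighbors[base, pick]]]
        new_X.append(x0 + u[:, None] * (x1 - x0))
        new_y.append(np.full(n_new, c, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# Grid-searched classifier comparison
# ---------------------------------------------------------------------------

#: Three hyperparameter axes per classifier family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [50, 100, 200],
        "max_depth": [10, 20, None],
        "min_samples_split": [2, 5, 10],
    },
    "mlp": {
        "hidden_layer_sizes": [(64,), (128,), (64, 64)],
        "alpha": [1e-4, 1e-3, 1e-2],
        "learning_rate_init": [1e-3, 1e-2],
    },
    "gpc": {
        "kernel": [RBF(0.5), RBF(1.0), RBF(2.0)],
        "n_restarts_optimizer": [0, 1],
        "max_iter_predict": [50, 100],
    },
    "knc": {
        "n_neighbors": [3, 5, 9],
        "weights": ["uniform", "distance"],
        "p": [1, 2],
    },
}


@dataclass(frozen=True)
class GridSearchSpec:
    """Classifier family plus its three-axis hyperparameter grid."""

    family: Literal["rf", "mlp", "gpc", "knc"] = "rf"
    grid: Optional[dict[str, list]] = None
    cv_folds: int = 5
    scoring: str = "f1_weighted"

    def resolved_grid(self) -> dict[str, list]:
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
        if len(grid) != 3:
            raise ValueError(
                f"grid must have exactly 3 hyperparameter axes (got {len(grid)})"
            )
        if any(len(v) < 2 for v in grid.values()):
            raise ValueError("every grid axis needs at least 2 candidates")
        return grid


def _make_estimator(family: str, seed: int):
    if family == "rf":
        return RandomForestClassifier(random_state=seed)
    if family == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500)
    if family == "gpc":
        return GaussianProcessClassifier(random_state=seed)
    if family == "knc":
        return KNeighborsClassifier()
    raise ValueError(f"unknown classifier family {family!r}")


def grid_search_fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: GridSearchSpec,
    seed: int = 0,
) -> tuple[object, pd.DataFrame]:
    """Exhaustive grid search scored by stratified five-fold cross-validation.

    Returns the refitted best estimator and the full selection table (one
    row per grid cell with its mean CV score), sorted by the grid order.
    """
    grid = spec.resolved_grid()
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(spec.family, seed),
        param_grid=grid,
        scoring=spec.scoring,
        cv=cv,
        refit=True,
        n_jobs=1,
        error_score="raise",
    )
    search.fit(X, y)
    table = pd.DataFrame(search.cv_results_["params"])
    table["mean_cv_score"] = search.cv_results_["mean_test_score"]
    table["rank"] = search.cv_results_["rank_test_score"]
    return search.best_estimator_, table


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Test-set metrics with the averaging mode stamped in."""

    precision: float
    recall: float
    f1: float
    averaging: str
    confusion: pd.DataFrame  # rows = true phase, cols = predicted phase
    per_class: pd.DataFrame
    macro: dict[str, float] = field(default_factory=dict)

    @property
    def n_test(self) -> int:
        return int(self.confusion.to_numpy().sum())


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    *,
    labels: Sequence[str] = PHASES,
    averaging: str = "weighted",
) -> EvalResult:
    """Score a fitted classifier on the held-out test set.

    Reports precision/recall/F1 under ``averaging`` (weighted by default,
    with macro alongside) and the phase-by-phase confusion matrix whose
    rows are true labels.
    """
    if len(y_test) == 0:
        raise ValueError("empty test set")
    labels = list(labels)
    y_pred = model.predict(X_test)
    p, r, f1, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average=averaging, zero_division=0
    )
    pm, rm, fm, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average="macro", zero_division=0
    )
    pc_p, pc_r, pc_f, pc_n = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average=None, zero_division=0
    )
    cm = confusion_matrix(y_test, y_pred, labels=labels)
    return EvalResult(
        precision=float(p),
        recall=float(r),
        f1=float(f1),
        averaging=averaging,
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        per_class=pd.DataFrame(
            {"precision": pc_p, "recall": pc_r, "f1": pc_f, "support": pc_n},
            index=labels,
        ),
        macro={"precision": float(pm), "recall": float(rm), "f1": float(fm)},
    )


def random_baseline(n_classes: int) -> float:
    """Expected accuracy of a uniform random guesser: 1 / n_classes.

    With the eight phase categories this is 0.125 — the chance level any
    useful classifier must beat.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


# ---------------------------------------------------------------------------
# Shapley attributions (permutation sampling) and grouped importance
# ---------------------------------------------------------------------------


def shapley_attributions(
    model,
    X_explain: np.ndarray,
    X_background: np.ndarray,
    *,
    n_permutations: int = 16,
    seed: int = 0,
) -> np.ndarray:
    """Per-dimension Shapley values of ``predict_proba`` via permutation sampling.

    For each record, feature dimensions are revealed one at a time in random
    order on top of a background row; a dimension's attribution is its mean
    marginal change in the predicted class probabilities.  The estimator is
    exactly efficient: for every record and class the attributions sum to
    ``f(x) - mean_b f(b)`` over the sampled background rows.

    Returns an array of shape (n_records, n_dims, n_classes).
    """
    X_explain = np.asarray(X_explain, dtype=float)
    X_background = np.asarray(X_background, dtype=float)
    rng = np.random.default_rng(seed)
    n, D = X_explain.shape
    n_classes = len(model.classes_)
    phi = np.zeros((n, D, n_classes))

    for i in range(n):
        x = X_explain[i]
        acc = np.zeros((D, n_classes))
        for _ in range(n_permutations):
            order = rng.permutation(D)
            b = X_background[rng.integers(0, len(X_background))]
            # cumulative reveal: row j has dims order[:j+1] from x, rest from b
            grid = np.tile(b, (D + 1, 1))
            for j, d in enumerate(order):
                grid[j + 1 :, d] = x[d]
            probs = model.predict_proba(grid)
            acc[order] += probs[1:] - probs[:-1]
        phi[i] = acc / n_permutations
    return phi


def group_attributions(
    phi: np.ndarray, group_map: FeatureGroupMap
) -> tuple[np.ndarray, list[str]]:
    """Sum per-dimension attributions over each named feature's span.

    Returns (n_records, n_features, n_classes) and the feature-name order.
    Grouping conserves attribution mass exactly: per (record, class), the
    grouped sum equals the raw per-dimension sum.
    """
    if phi.shape[1] != group_map.n_dims:
        raise ValueError(
            f"attribution dimension {phi.shape[1]} does not match map "
            f"dimension {group_map.n_dims}"
        )
    names = group_map.feature_names()
    grouped = np.stack(
        [phi[:, group_map.dims(f), :].sum(axis=1) for f in names], axis=1
    )
    return grouped, names


def grouped_shap_importance(
    model,
    X_explain: np.ndarray,
    group_map: FeatureGroupMap,
    *,
    X_background: Optional[np.ndarray] = None,
    n_permutations: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped feature-importance summary: mean |Shapley value| per feature.

    One-hot categorical features span several dimensions; their per-dimension
    attributions are summed before taking the magnitude, so each of the 13
    named features gets a single importance per class plus an overall mean.
    """
    if X_background is None:
        X_background = X_explain
    phi = shapley_attributions(
        model, X_explain, X_background, n_permutations=n_permutations, seed=seed
    )
    grouped, names = group_attributions(phi, group_map)
    mean_abs = np.abs(grouped).mean(axis=0)  # (n_features, n_classes)
    out = pd.DataFrame(mean_abs, index=names, columns=list(model.classes_))
    out["overall"] = mean_abs.mean(axis=1)
    return out.sort_values("overall", ascending=False)
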