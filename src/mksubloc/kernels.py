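"""Per-view Gaussian kernels, data-driven kernel weights, scenario transforms.

Each of the six binary feature views yields a Gaussian Gram matrix
``K(x, y) = exp(-gamma * ||x - y||^2)`` (for binary rows the squared distance
is the Hamming distance).  The final kernel is the convex combination
``K = sum_m w_m K_m`` with non-negative weights summing to 1.

The weights are non-parametric: for each view alone, a one-vs-rest classifier
is cross-validated on the training set, the pooled validation predictions
form a multi-label confusion matrix, and the view's score is the
class-averaged ``(SE + max(MCC, 0)) / 2``.  Scores are normalized into
weights, so views dominated by divergent-homolog noise are suppressed.

Three evaluation scenarios transform the test-side kernels:

* optimistic  -- query proteins keep their own GO annotations; all six views.
* moderate    -- query proteins have no GO annotations: for the three target
  views the query's homolog vector is substituted into the cross kernel
  against the training proteins' target vectors; training side unchanged.
* pessimistic -- target views are dropped from both sides; only the three
  homolog views remain, with weights re-estimated on that 3-view system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import build_confusion, class_metrics, locative_expand
from .features import FeatureViews, HOMOLOG_VIEWS, TARGET_VIEWS, VIEW_NAMES
from .io import LabelTable
from .mlsvm import predict_proba, rank_assign_locative, train_ova

SCENARIOS = ("optimistic", "moderate", "pessimistic")


@dataclass
class KernelBundle:
    """Named square Gram matrices with convex combination weights."""

    views: tuple[str, ...]
    grams: dict[str, np.ndarray]
    weights: dict[str, float]
    gamma: float

    def __post_init__(self) -> None:
        if set(self.views) != set(self.grams) or set(self.views) != set(self.weights):
            raise ValueError("views, grams and weights must cover the same names")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        n = None
        for name in self.views:
            g = self.grams[name]
            if g.ndim != 2 or g.shape[0] != g.shape[1]:
                raise ValueError(f"gram {name} is not square")
            n = g.shape[0] if n is None else n
            if g.shape[0] != n:
                raise ValueError("grams differ in dimension")
            if self.weights[name] < 0:
                raise ValueError(f"negative weight for view {name}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")


def gaussian_gram(
    X: np.ndarray, Y: np.ndarray | None = None, gamma: float = 0.125
) -> np.ndarray:
    """``exp(-gamma * ||x_i - y_j||^2)`` for all row pairs.

    For 0/1 rows the squared Euclidean distance equals the Hamming distance,
    so identical rows map to exactly 1.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"column mismatch: {X.shape[1]} vs {Y.shape[1]}")
    sq = (
        (X * X).sum(axis=1)[:, None]
        + (Y * Y).sum(axis=1)[None, :]
        - 2.0 * (X @ Y.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


def combine(bundle: KernelBundle) -> np.ndarray:
    """Convex combination of the bundle's Gram matrices."""
    first = bundle.grams[bundle.views[0]]
    out = np.zeros_like(first, dtype=float)
    for name in bundle.views:
        out += bundle.weights[name] * bundle.grams[name]
    return out


def _stratify_folds(
    labels: LabelTable, accessions: list[str], folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold indices over distinct proteins, stratified by primary label.

    Stratification uses each protein's first catalog-ordered location; when a
    stratum is smaller than the fold count a plain shuffled K-fold is used.
    """
    strata = np.asarray(
        [
            min(labels.labels[a], key=labels.location_catalog.index)
            for a in accessions
        ]
    )
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(len(accessions)), strata))
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(accessions))))


def _single_view_score(
    protein_gram: np.ndarray,
    accessions: list[str],
    labels: LabelTable,
    fold_splits: list[tuple[np.ndarray, np.ndarray]],
    C: float,
    seed: int,
) -> float:
    """Pooled-CV score of one kernel: class-averaged (SE + MCC+)/2."""
    row = {a: i for i, a in enumerate(accessions)}
    assignments: list[tuple[str, str]] = []
    for train_idx, val_idx in fold_splits:
        train_accs = [accessions[i] for i in train_idx]
        inst = [
            (a, loc)
            for a, loc in locative_expand(labels.subset(train_accs))
        ]
        inst_rows = np.asarray([row[a] for a, _ in inst])
        inst_labels = [loc for _, loc in inst]
        if len(set(inst_labels)) < 2:
            continue  # degenerate fold on very small data
        model = train_ova(
            protein_gram[np.ix_(inst_rows, inst_rows)], inst_labels, C=C, seed=seed
        )
        model_classes = set(model.classes)
        for i in val_idx:
            accession = accessions[i]
            true_set = frozenset(
                labels.labels[accession] & model_classes
            )
            if not true_set:
                continue
            probs = predict_proba(
                model, protein_gram[np.ix_([row[accession]], inst_rows)]
            )[0]
            assignments.extend(
                rank_assign_locative(probs, model.classes, true_set)
            )
    if not assignments:
        return 0.0
    confusion = build_confusion(assignments, labels.location_catalog)
    present = confusion.counts.sum(axis=1) > 0
    metrics = class_metrics(confusion)
    per_class = (metrics.se + np.maximum(metrics.mcc, 0.0)) / 2.0
    return float(per_class[present].mean())


def estimate_weights(
    train_views: FeatureViews,
    train_labels: LabelTable,
    active_views: tuple[str, ...] = VIEW_NAMES,
    gamma: float = 0.125,
    C: float = 8.0,
    folds: int = 3,
    seed: int = 0,
    return_scores: bool = False,
) -> dict[str, float] | tuple[dict[str, float], dict[str, float]]:
    """Estimate convex kernel weights by single-view inner cross validation.

    Each active view is scored alone: ``folds``-fold CV (split at the
    distinct-protein level, stratified by primary label) trains one-vs-rest
    classifiers on that view's Gram matrix, validation predictions are pooled
    into one multi-label confusion matrix, and the score is the class mean of
    ``(SE + max(MCC, 0)) / 2``.  Weights are the scores normalized to sum 1
    (uniform if all scores vanish).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    accessions = [a for a in train_views.accessions if a in train_labels.labels]
    if len(accessions) != len(train_views.accessions):
        raise ValueError("every training protein needs a label")
    per_class_counts = {
        c: sum(1 for a in accessions if c in train_labels.labels[a])
        for c in train_labels.location_catalog
    }
    empty = sorted(c for c, n in per_class_counts.items() if n == 0)
    if empty:
        raise ValueError(f"classes with zero locative training instances: {empty}")
    fold_splits = _stratify_folds(train_labels, list(accessions), folds, seed)
    scores = {}
    for name in active_views:
        gram = gaussian_gram(train_views.matrices[name], gamma=gamma)
        scores[name] = _single_view_score(
            gram, list(accessions), train_labels, fold_splits, C, seed
        )
    total = sum(scores.values())
    if total <= 0:
        weights = {name: 1.0 / len(active_views) for name in active_views}
    else:
        weights = {name: scores[name] / total for name in active_views}
    if return_scores:
        return weights, scores
    return weights


def _cross_matrix(test_views: FeatureViews, view: str, scenario: str) -> np.ndarray:
    """Test-side matrix feeding the cross kernel for one view."""
    if scenario == "moderate" and view in TARGET_VIEWS:
        # novel query proteins have no target GO terms; substitute the
        # homolog vector of the same aspect into the target-view cross kernel
        return test_views.matrices["h_" + view[-1]]
    return test_views.matrices[view]


def apply_scenario(
    train_views: FeatureViews,
    test_views: FeatureViews | None,
    scenario: str,
    gamma: float,
    weights: dict[str, float],
) -> tuple[np.ndarray, np.ndarray | None]:
    """Combined training Gram and test-vs-train cross Gram for a scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    active = HOMOLOG_VIEWS if scenario == "pessimistic" else VIEW_NAMES
    if set(weights) != set(active):
        raise ValueError(
            f"scenario {scenario} needs weights for views {sorted(active)}, "
            f"got {sorted(weights)}"
        )
    train_gram = np.zeros(
        (len(train_views.accessions), len(train_views.accessions))
    )
    cross_gram = (
        None
        if test_views is None
        else np.zeros((len(test_views.accessions), len(train_views.accessions)))
    )
    for name in active:
        train_mat = train_views.matrices[name]
        train_gram += weights[name] * gaussian_gram(train_mat, gamma=gamma)
        if test_views is not None:
            cross_gram += weights[name] * gaussian_gram(
                _cross_matrix(test_views, name, scenario), train_mat, gamma=gamma
            )
    return train_gram, cross_gram
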