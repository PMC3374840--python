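"""One-vs-rest max-margin classification with Platt-calibrated probabilities.

For K subcellular locations, K binary support-vector classifiers are trained
on the precomputed combined kernel: the locative instances of location k are
positive, everything else negative.  Each binary decision value f is mapped
to a posterior p = 1/(1 + exp(A f + B)) with (A, B) fitted by regularized
maximum likelihood on cross-validated decision values (Platt scaling), and
the K per-class posteriors are normalized into a probability vector.

Two labelling rules are provided:

* ``threshold_labels`` -- every location with probability >= theta, with a
  top-1 fallback so each protein receives at least one location;
* ``rank_assign_locative`` -- for evaluation over locative copies: the top-N
  locations by probability are matched against the N true locations, missed
  true labels being paired with the distinct non-true predictions, which is
  what populates the multi-label confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class OvaModel:
    """K fitted binary classifiers on a shared precomputed kernel."""

    classes: tuple[str, ...]
    svms: list[SVC]
    platt: list[tuple[float, float]]  # (A, B) per class
    n_train: int

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def train_ova(
    train_gram: np.ndarray,
    labels: list[str],
    C: float = 8.0,
    seed: int = 0,
    platt_folds: int = 3,
) -> OvaModel:
    """Train one binary SVC per class on a precomputed Gram matrix.

    ``labels`` are per-locative-instance class names (a multiplex protein
    contributes one instance per location).  Decision values for Platt
    calibration come from an internal ``platt_folds``-fold CV so the sigmoid
    is never fitted on resubstitution outputs.
    """
    train_gram = np.asarray(train_gram, dtype=float)
    n = train_gram.shape[0]
    if train_gram.shape != (n, n):
        raise ValueError(f"train gram must be square, got {train_gram.shape}")
    if len(labels) != n:
        raise ValueError("label count must match gram dimension")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError(
            f"need >= 2 distinct classes to train one-vs-rest, got {classes}"
        )
    y_arr = np.asarray(labels)
    svms, platt = [], []
    for cls in classes:
        y = np.where(y_arr == cls, 1, -1)
        if not (y == 1).any():
            raise ValueError(f"class {cls!r} has no positive training instance")
        svm = SVC(kernel="precomputed", C=C, random_state=seed)
        svm.fit(train_gram, y)
        decision = _cv_decision_values(train_gram, y, C, seed, platt_folds)
        a, b = fit_platt(decision, y)
        svms.append(svm)
        platt.append((a, b))
    return OvaModel(classes=classes, svms=svms, platt=platt, n_train=n)


def _cv_decision_values(
    gram: np.ndarray, y: np.ndarray, C: float, seed: int, folds: int
) -> np.ndarray:
    """Out-of-fold decision values for calibration.

    Falls back to resubstitution values when a class is too small to split.
    """
    n = len(y)
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    folds = min(folds, n_pos, n_neg)
    if folds < 2:
        svm = SVC(kernel="precomputed", C=C, random_state=seed)
        svm.fit(gram, y)
        return svm.decision_function(gram)
    decision = np.zeros(n)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, val_idx in splitter.split(np.zeros(n), y):
        svm = SVC(kernel="precomputed", C=C, random_state=seed)
        svm.fit(gram[np.ix_(train_idx, train_idx)], y[train_idx])
        decision[val_idx] = svm.decision_function(gram[np.ix_(val_idx, train_idx)])
    return decision


def fit_platt(
    decision_values: np.ndarray,
    binary_labels: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Fit the sigmoid p = 1/(1+exp(A f + B)) by regularized log-likelihood.

    Uses the prior-corrected targets t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2) and Newton iterations with backtracking line search.
    Both label values must be present.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(binary_labels)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt fitting requires both classes present")
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(pos, hi, lo)

    def objective(a: float, b: float) -> float:
        z = a * f + b
        # stable log(1+exp(z)) and t*z + log(1+exp(-z)) forms
        return float(
            np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                            (t - 1.0) * z + np.log1p(np.exp(z))))
        )

    a = 0.0
    b = np.log((n_neg + 1.0) / (n_pos + 1.0))
    value = objective(a, b)
    sigma = 1e-12  # Hessian ridge
    for _ in range(max_iter):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)),
                     1.0 / (1.0 + np.exp(z)))
        d1 = t - p  # dF/dz of the negative log-likelihood
        w = p * (1.0 - p)
        g_a = float(np.dot(f, d1))
        g_b = float(np.sum(d1))
        if abs(g_a) < tol and abs(g_b) < tol:
            break
        h_aa = float(np.dot(f * f, w)) + sigma
        h_bb = float(np.sum(w)) + sigma
        h_ab = float(np.dot(f, w))
        det = h_aa * h_bb - h_ab * h_ab
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(h_aa * g_b - h_ab * g_a) / det
        gd = g_a * da + g_b * db
        step = 1.0
        while step >= 1e-10:
            new_a, new_b = a + step * da, b + step * db
            new_value = objective(new_a, new_b)
            if new_value < value + 1e-4 * step * gd:
                a, b, value = new_a, new_b, new_value
                break
            step /= 2.0
        else:
            break
    return a, b


def _sigmoid(a: float, b: float, f: np.ndarray) -> np.ndarray:
    z = a * f + b
    return np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))


def predict_proba(model: OvaModel, cross_gram: np.ndarray) -> np.ndarray:
    """Normalized per-class probability vectors for query rows.

    ``cross_gram`` holds kernel values between m query proteins (rows) and
    the n training instances (columns).  Raw per-class Platt posteriors are
    normalized to sum to 1; a pathological all-zero row maps to the uniform
    vector.
    """
    cross_gram = np.asarray(cross_gram, dtype=float)
    if cross_gram.ndim == 1:
        cross_gram = cross_gram[None, :]
    if cross_gram.shape[1] != model.n_train:
        raise ValueError(
            f"cross gram has {cross_gram.shape[1]} columns, model expects {model.n_train}"
        )
    q = np.column_stack(
        [
            _sigmoid(a, b, svm.decision_function(cross_gram))
            for svm, (a, b) in zip(model.svms, model.platt)
        ]
    )
    totals = q.sum(axis=1, keepdims=True)
    uniform = np.full(model.n_classes, 1.0 / model.n_classes)
    probs = np.where(totals > 0, q / np.where(totals == 0, 1.0, totals), uniform)
    return probs


def threshold_labels(
    probabilities: np.ndarray, classes: tuple[str, ...], theta: float
) -> frozenset[str]:
    """All locations with probability >= theta; top-1 fallback if none pass."""
    if not 0.0 < theta < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {theta}")
    p = np.asarray(probabilities, dtype=float)
    chosen = {classes[i] for i in np.flatnonzero(p >= theta)}
    if not chosen:
        chosen = {classes[int(np.argmax(p))]}
    return frozenset(chosen)


def rank_assign_locative(
    probabilities: np.ndarray,
    classes: tuple[str, ...],
    true_set: frozenset[str],
) -> list[tuple[str, str]]:
    """Pair each true location of a multiplex protein with a predicted column.

    With N = |true set|, the predicted set is the top-N locations by
    probability (ties broken by catalog order).  A true location found in the
    top-N maps to itself (a hit on the confusion diagonal); each missed true
    location is paired, in descending order of its probability, with a
    distinct top-N location outside the true set, also taken in descending
    probability order.  Singlex proteins reduce to plain argmax.
    """
    p = np.asarray(probabilities, dtype=float)
    n_true = len(true_set)
    if n_true < 1:
        raise ValueError("true set must be non-empty")
    if n_true > len(classes):
        raise ValueError("true set larger than the location catalog")
    # stable sort on (-p, catalog order)
    order = sorted(range(len(classes)), key=lambda i: (-p[i], i))
    top = [classes[i] for i in order[:n_true]]
    top_set = set(top)
    pairs = [(t, t) for t in top if t in true_set]
    missed = sorted(true_set - top_set, key=lambda c: (-p[classes.index(c)], classes.index(c)))
    wrong = [c for c in top if c not in true_set]
    pairs.extend(zip(missed, wrong))
    return pairs
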