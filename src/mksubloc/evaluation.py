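"""Multi-label evaluation: locative expansion, confusion matrix, metrics.

A protein residing in m compartments is expanded into m "locative" copies,
one per location, and the classifier is scored per copy: a copy is correct
when the ranked prediction hits its location.  This yields a K x K
multi-label confusion matrix M whose rows are true locations and whose
columns are the predicted columns of the ranked assignment.  Per class,
with TP = M[c,c], FN = rowsum - TP, FP = colsum - TP, TN = rest:

* SE (sensitivity / recall)            = TP / (TP + FN)
* SP (here positive predictive value)  = TP / (TP + FP)
* MCC                                  = (TP*TN - FP*FN) / sqrt(prod of margins)

with 0 substituted whenever a denominator factor vanishes.  Overall accuracy
is trace/total and overall MCC is the K-category correlation coefficient
(Gorodkin's R_K) of M.

For multiplex proteins three set-valued measures compare the thresholded
prediction P with the true set T within each cardinality group N = |T|:

* LHR_n    -- fraction with |T intersect P| = n (n = N is the complete hit rate);
* PLMR     -- fraction with P = T exactly;
* NT-LHR_n -- fraction with |P - T| = n extra, misleading labels (n >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import LabelTable


@dataclass
class MultiLabelConfusion:
    """K x K count matrix over locative instances."""

    catalog: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.catalog)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    catalog: tuple[str, ...]
    size: np.ndarray  # locative instances per true class (row sums)
    se: np.ndarray
    sp: np.ndarray
    mcc: np.ndarray
    overall_accuracy: float
    overall_mcc: float

    def to_rows(self) -> list[tuple[str, int, float, float, float]]:
        return [
            (c, int(self.size[i]), float(self.sp[i]), float(self.se[i]), float(self.mcc[i]))
            for i, c in enumerate(self.catalog)
        ]


@dataclass
class MultiplexMetrics:
    """Per-cardinality-group LHR array, PLMR scalar and NT-LHR array."""

    groups: dict[int, dict]  # N -> {size, lhr (len N+1), plmr, nt_lhr (len K-N)}
    n_locations: int


def locative_expand(labels: LabelTable) -> list[tuple[str, str]]:
    """One (accession, location) instance per membership, in catalog order."""
    instances = []
    for accession in labels.accessions():
        for location in sorted(
            labels.labels[accession], key=labels.location_catalog.index
        ):
            instances.append((accession, location))
    return instances


def build_confusion(
    assignments: Iterable[tuple[str, str]], catalog: Sequence[str]
) -> MultiLabelConfusion:
    """Tally (true label, predicted column) pairs into the K x K matrix."""
    catalog = tuple(catalog)
    index = {c: i for i, c in enumerate(catalog)}
    counts = np.zeros((len(catalog), len(catalog)), dtype=np.int64)
    for true_label, predicted in assignments:
        if true_label not in index:
            raise ValueError(f"unknown true label {true_label!r}")
        if predicted not in index:
            raise ValueError(f"unknown predicted label {predicted!r}")
        counts[index[true_label], index[predicted]] += 1
    return MultiLabelConfusion(catalog, counts)


def _binary_metrics(tp: float, fp: float, fn: float, tn: float) -> tuple[float, float, float]:
    se = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tp / (tp + fp) if tp + fp > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return se, sp, mcc


def _gorodkin_rk(counts: np.ndarray) -> float:
    """K-category correlation coefficient of a confusion matrix."""
    counts = counts.astype(float)
    total = counts.sum()
    trace = np.trace(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    cov = trace * total - float(row @ col)
    d_true = total**2 - float(row @ row)
    d_pred = total**2 - float(col @ col)
    if d_true <= 0 or d_pred <= 0:
        return 0.0
    return cov / np.sqrt(d_true * d_pred)


def class_metrics(confusion: MultiLabelConfusion) -> ClassMetrics:
    """Per-class SE/SP/MCC and overall accuracy / overall MCC."""
    counts = confusion.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = len(confusion.catalog)
    se = np.zeros(k)
    sp = np.zeros(k)
    mcc = np.zeros(k)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    for c in range(k):
        tp = counts[c, c]
        fn = row[c] - tp
        fp = col[c] - tp
        tn = total - tp - fn - fp
        se[c], sp[c], mcc[c] = _binary_metrics(tp, fp, fn, tn)
    return ClassMetrics(
        catalog=confusion.catalog,
        size=row.astype(int),
        se=se,
        sp=sp,
        mcc=mcc,
        overall_accuracy=float(np.trace(counts) / total),
        overall_mcc=_gorodkin_rk(confusion.counts),
    )


def multiplex_metrics(
    true_sets: Sequence[frozenset[str]],
    predicted_sets: Sequence[frozenset[str]],
    n_locations: int,
) -> MultiplexMetrics:
    """LHR / PLMR / NT-LHR per true-set cardinality group."""
    if len(true_sets) != len(predicted_sets):
        raise ValueError("true and predicted set lists differ in length")
    groups: dict[int, dict] = {}
    for t, p in zip(true_sets, predicted_sets):
        cardinality = len(t)
        if cardinality < 2:
            raise ValueError("multiplex metrics require true sets of cardinality >= 2")
        if not p:
            raise ValueError("predicted sets must be non-empty")
        g = groups.setdefault(
            cardinality,
            {
                "size": 0,
                "hits": np.zeros(cardinality + 1, dtype=int),
                "perfect": 0,
                "extras": np.zeros(max(n_locations - cardinality, 0) + 1, dtype=int),
            },
        )
        g["size"] += 1
        g["hits"][len(t & p)] += 1
        g["perfect"] += int(p == t)
        g["extras"][len(p - t)] += 1
    out: dict[int, dict] = {}
    for cardinality, g in sorted(groups.items()):
        size = g["size"]
        out[cardinality] = {
            "size": size,
            "lhr": g["hits"] / size,
            "plmr": g["perfect"] / size,
            "nt_lhr": g["extras"][1:] / size,  # n >= 1 extras only
        }
    return MultiplexMetrics(groups=out, n_locations=n_locations)


def select_threshold(
    probabilities: np.ndarray,
    true_sets: Sequence[frozenset[str]],
    catalog: tuple[str, ...],
    grid: Sequence[float] = tuple(np.round(np.arange(0.01, 0.301, 0.01), 2)),
) -> float:
    """Pick the probability threshold maximizing size-weighted PLMR.

    Evaluated on multiplex validation proteins only.  Ties are broken by the
    smaller mean number of non-target (extra) labels, then by the larger
    threshold, making the choice deterministic.
    """
    from .mlsvm import threshold_labels

    grid = list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if len(true_sets) == 0:
        raise ValueError("empty validation set")
    probabilities = np.asarray(probabilities, dtype=float)
    best: tuple[float, float, float] | None = None
    best_theta = grid[0]
    for theta in grid:
        predicted = [
            threshold_labels(probabilities[i], catalog, theta)
            for i in range(len(true_sets))
        ]
        n_perfect = sum(int(p == t) for p, t in zip(predicted, true_sets))
        mean_extras = float(
            np.mean([len(p - t) for p, t in zip(predicted, true_sets)])
        )
        key = (n_perfect / len(true_sets), -mean_extras, theta)
        if best is None or key > best:
            best = key
            best_theta = theta
    return float(best_theta)


def write_class_report(metrics: ClassMetrics, path: str | Path) -> Path:
    """One row per location (size, SP, SE, MCC) plus an overall footer."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("location\tsize\tSP\tSE\tMCC\n")
        for name, size, sp, se, mcc in metrics.to_rows():
            fh.write(f"{name}\t{size}\t{sp:.4f}\t{se:.4f}\t{mcc:.4f}\n")
        fh.write(
            f"overall\t{int(metrics.size.sum())}\t-\t"
            f"{metrics.overall_accuracy:.4f}\t{metrics.overall_mcc:.4f}\n"
        )
    return path


def write_multiplex_report(metrics: MultiplexMetrics, path: str | Path) -> Path:
    """Per-cardinality LHR / PLMR / NT-LHR rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cardinality\tsize\tLHR(0..N)\tPLMR\tNT-LHR(1..K-N)\n")
        for cardinality, g in metrics.groups.items():
            lhr = ",".join(f"{x:.4f}" for x in g["lhr"])
            nt = ",".join(f"{x:.4f}" for x in g["nt_lhr"])
            fh.write(f"{cardinality}\t{g['size']}\t{lhr}\t{g['plmr']:.4f}\t{nt}\n")
    return path
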