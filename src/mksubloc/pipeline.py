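"""Two-level cross-validation experiments over the localization model.

Performance estimation follows two protocols:

* locative CV -- outer stratified 5-fold CV over distinct proteins; each
  fold rebuilds vocabularies, views and kernel weights (inner 3-fold CV)
  from the training side only, trains the one-vs-rest model, rank-assigns
  the test fold's locative instances and pools one multi-label confusion
  matrix across folds;
* multiplex CV -- only multiplex proteins rotate through 5 near-even test
  folds; singlex proteins are always training data.  Thresholded label sets
  are scored with the LHR/PLMR/NT-LHR measures.

``sweep_homologs`` repeats the locative CV across values of H, the number of
pooled homologs, tracing how performance degrades as increasingly divergent
homologs are transferred.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import (
    ClassMetrics,
    MultiLabelConfusion,
    MultiplexMetrics,
    build_confusion,
    class_metrics,
    locative_expand,
    multiplex_metrics,
    select_threshold,
)
from .features import HOMOLOG_VIEWS, VIEW_NAMES, build_vocabularies, encode_views
from .io import (
    AnnotationTable,
    HomologTable,
    LabelTable,
    read_blast_tab,
    read_gaf,
    read_label_table,
)
from .kernels import SCENARIOS, _stratify_folds, apply_scenario, estimate_weights
from .mlsvm import (
    predict_proba,
    rank_assign_locative,
    threshold_labels,
    train_ova,
)
from .synthetic import WorldConfig, generate_world

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.01, 0.301, 0.01), 2))


@dataclass
class ExperimentConfig:
    """Everything one CV experiment needs: data source + hyperparameters."""

    scenario: str = "optimistic"
    n_homologs: int = 1
    gamma: float = 0.125
    C: float = 8.0
    threshold: float | None = 0.09
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    outer_folds: int = 5
    inner_folds: int = 3
    seed: int = 0
    gaf_path: str | None = None
    blast_path: str | None = None
    label_path: str | None = None
    world: WorldConfig | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_homologs < 1:
            raise ValueError("n_homologs must be >= 1")
        paths = (self.gaf_path, self.blast_path, self.label_path)
        if self.world is not None and any(p is not None for p in paths):
            raise ValueError("give either file paths or a synthetic world, not both")

    def load_world(self) -> tuple[LabelTable, AnnotationTable, HomologTable]:
        if self.world is not None:
            return generate_world(self.world)
        if not all((self.gaf_path, self.blast_path, self.label_path)):
            raise ValueError("config needs gaf/blast/label paths or a world")
        return (
            read_label_table(self.label_path),
            read_gaf(self.gaf_path),
            read_blast_tab(self.blast_path),
        )


def _fit_fold(
    train_accs: list[str],
    labels: LabelTable,
    annotations: AnnotationTable,
    homologs: HomologTable,
    config: ExperimentConfig,
):
    """Vocabularies, views, weights and OVA model from one training fold."""
    vocabs = build_vocabularies(
        annotations, train_accs, homologs, config.n_homologs
    )
    train_views = encode_views(
        train_accs, annotations, homologs, config.n_homologs, vocabs
    )
    train_labels = labels.subset(train_accs)
    active = HOMOLOG_VIEWS if config.scenario == "pessimistic" else VIEW_NAMES
    weights = estimate_weights(
        train_views,
        train_labels,
        active_views=active,
        gamma=config.gamma,
        C=config.C,
        folds=config.inner_folds,
        seed=config.seed,
    )
    instances = locative_expand(train_labels)
    inst_rows = np.asarray([train_views.row(a) for a, _ in instances])
    inst_labels = [loc for _, loc in instances]
    missing = set(labels.location_catalog) - set(inst_labels)
    if missing:
        raise ValueError(
            f"classes absent from a training fold: {sorted(missing)}; "
            "use fewer folds or more data"
        )
    train_gram, _ = apply_scenario(
        train_views, None, config.scenario, config.gamma, weights
    )
    ova = train_ova(
        train_gram[np.ix_(inst_rows, inst_rows)],
        inst_labels,
        C=config.C,
        seed=config.seed,
    )
    return vocabs, train_views, weights, inst_rows, ova


def _fold_probabilities(
    test_accs,
    annotations,
    homologs,
    config,
    vocabs,
    train_views,
    weights,
    inst_rows,
    ova,
) -> np.ndarray:
    test_views = encode_views(
        list(test_accs), annotations, homologs, config.n_homologs, vocabs
    )
    _, cross = apply_scenario(
        train_views, test_views, config.scenario, config.gamma, weights
    )
    return predict_proba(ova, cross[:, inst_rows])


def run_locative_cv(
    config: ExperimentConfig,
    data: tuple[LabelTable, AnnotationTable, HomologTable] | None = None,
) -> tuple[ClassMetrics, MultiLabelConfusion]:
    """Outer stratified CV over distinct proteins; pooled locative metrics."""
    labels, annotations, homologs = data if data is not None else config.load_world()
    accessions = labels.accessions()
    folds = _stratify_folds(labels, accessions, config.outer_folds, config.seed)
    assignments: list[tuple[str, str]] = []
    for train_idx, test_idx in folds:
        train_accs = [accessions[i] for i in train_idx]
        test_accs = [accessions[i] for i in test_idx]
        vocabs, train_views, weights, inst_rows, ova = _fit_fold(
            train_accs, labels, annotations, homologs, config
        )
        probs = _fold_probabilities(
            test_accs, annotations, homologs, config,
            vocabs, train_views, weights, inst_rows, ova,
        )
        for i, accession in enumerate(test_accs):
            assignments.extend(
                rank_assign_locative(probs[i], ova.classes, labels.labels[accession])
            )
    confusion = build_confusion(assignments, labels.location_catalog)
    return class_metrics(confusion), confusion


def run_multiplex_cv(
    config: ExperimentConfig,
    data: tuple[LabelTable, AnnotationTable, HomologTable] | None = None,
) -> MultiplexMetrics:
    """CV over multiplex proteins only; singlex proteins always train."""
    labels, annotations, homologs = data if data is not None else config.load_world()
    singlex = labels.singlex()
    multiplex = labels.multiplex()
    if not multiplex:
        raise ValueError("no multiplex proteins in the dataset")
    n_folds = min(config.outer_folds, len(multiplex))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(multiplex))
    fold_of = np.arange(len(multiplex)) % n_folds
    true_sets: list[frozenset[str]] = []
    predicted_sets: list[frozenset[str]] = []
    for fold in range(n_folds):
        test_accs = [multiplex[i] for i in order[fold_of == fold]]
        train_mpx = [multiplex[i] for i in order[fold_of != fold]]
        train_accs = sorted(singlex + train_mpx)
        vocabs, train_views, weights, inst_rows, ova = _fit_fold(
            train_accs, labels, annotations, homologs, config
        )
        if config.threshold is not None:
            theta = config.threshold
        else:
            tune_probs = _fold_probabilities(
                train_mpx, annotations, homologs, config,
                vocabs, train_views, weights, inst_rows, ova,
            )
            theta = select_threshold(
                tune_probs,
                [labels.labels[a] for a in train_mpx],
                ova.classes,
                config.threshold_grid,
            )
        probs = _fold_probabilities(
            test_accs, annotations, homologs, config,
            vocabs, train_views, weights, inst_rows, ova,
        )
        for i, accession in enumerate(test_accs):
            true_sets.append(labels.labels[accession])
            predicted_sets.append(threshold_labels(probs[i], ova.classes, theta))
    return multiplex_metrics(true_sets, predicted_sets, labels.n_locations)


def sweep_homologs(
    config: ExperimentConfig,
    h_values: tuple[int, ...],
    data: tuple[LabelTable, AnnotationTable, HomologTable] | None = None,
) -> dict[int, float]:
    """Overall locative accuracy per number of pooled homologs H."""
    if not h_values:
        raise ValueError("empty H list")
    loaded = data if data is not None else config.load_world()
    curve: dict[int, float] = {}
    for h in h_values:
        metrics, _ = run_locative_cv(replace(config, n_homologs=h), data=loaded)
        curve[h] = metrics.overall_accuracy
    return curve
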