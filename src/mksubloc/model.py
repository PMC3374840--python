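"""Model/Results interface tying the pipeline stages together.

``LocalizationModel`` holds the data (labels, GO annotations, homolog hits)
and hyperparameters; ``fit()`` runs the full training stack -- vocabulary
construction, six-view encoding, inner-CV kernel-weight estimation, combined
kernel, one-vs-rest SVMs with Platt calibration -- and returns a
``LocalizationResults`` carrying the estimates (kernel weights, Platt
coefficients), prediction methods and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import locative_expand
from .features import (
    FeatureViews,
    HOMOLOG_VIEWS,
    VIEW_NAMES,
    build_vocabularies,
    encode_views,
)
from .io import (
    AnnotationTable,
    HomologTable,
    LabelTable,
    load_bundle,
    read_blast_tab,
    read_gaf,
    read_label_table,
    save_bundle,
)
from .kernels import SCENARIOS, apply_scenario, estimate_weights
from .mlsvm import OvaModel, predict_proba, threshold_labels, train_ova


class LocalizationModel:
    """Multi-kernel multi-label subcellular localization model.

    Parameters
    ----------
    labels, annotations, homologs
        Training data: label table, GO annotation table and ranked homolog
        hits.
    scenario
        ``optimistic`` (queries keep their own GO terms), ``moderate``
        (queries are novel: homolog vectors substitute for target vectors in
        the test kernels) or ``pessimistic`` (target views dropped entirely,
        3-kernel homolog-only system).
    n_homologs
        Number of top-ranked homologs whose GO terms are pooled (H).
    gamma, C
        Gaussian kernel width and SVM regularization.
    inner_folds, seed
        Folds for the kernel-weight inner CV and the random seed governing
        every stochastic step.
    """

    def __init__(
        self,
        labels: LabelTable,
        annotations: AnnotationTable,
        homologs: HomologTable,
        scenario: str = "optimistic",
        n_homologs: int = 1,
        gamma: float = 0.125,
        C: float = 8.0,
        inner_folds: int = 3,
        seed: int = 0,
    ) -> None:
        if scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        self.labels = labels
        self.annotations = annotations
        self.homologs = homologs
        self.scenario = scenario
        self.n_homologs = n_homologs
        self.gamma = gamma
        self.C = C
        self.inner_folds = inner_folds
        self.seed = seed

    @classmethod
    def from_files(
        cls, gaf_path, blast_path, label_path, **kwargs
    ) -> "LocalizationModel":
        return cls(
            read_label_table(label_path),
            read_gaf(gaf_path),
            read_blast_tab(blast_path),
            **kwargs,
        )

    def fit(self, weights: dict[str, float] | None = None) -> "LocalizationResults":
        """Fit vocabularies, kernel weights and the one-vs-rest classifiers.

        ``weights`` may be supplied to skip the inner-CV estimation (e.g.
        when reusing weights across a hyperparameter sweep).
        """
        accessions = self.labels.accessions()
        vocabs = build_vocabularies(
            self.annotations, accessions, self.homologs, self.n_homologs
        )
        views = encode_views(
            accessions, self.annotations, self.homologs, self.n_homologs, vocabs
        )
        active = HOMOLOG_VIEWS if self.scenario == "pessimistic" else VIEW_NAMES
        if weights is None:
            weights = estimate_weights(
                views,
                self.labels,
                active_views=active,
                gamma=self.gamma,
                C=self.C,
                folds=self.inner_folds,
                seed=self.seed,
            )
        train_gram, _ = apply_scenario(views, None, self.scenario, self.gamma, weights)
        instances = locative_expand(self.labels)
        inst_rows = np.asarray([views.row(a) for a, _ in instances])
        inst_labels = [loc for _, loc in instances]
        ova = train_ova(
            train_gram[np.ix_(inst_rows, inst_rows)],
            inst_labels,
            C=self.C,
            seed=self.seed,
        )
        return LocalizationResults(
            model=self,
            vocabs=vocabs,
            train_views=views,
            weights=dict(weights),
            ova=ova,
            instance_rows=inst_rows,
            instance_labels=tuple(inst_labels),
        )


@dataclass
class LocalizationResults:
    """Fitted estimates plus prediction and persistence methods."""

    model: LocalizationModel
    vocabs: dict
    train_views: FeatureViews
    weights: dict[str, float]
    ova: OvaModel
    instance_rows: np.ndarray
    instance_labels: tuple[str, ...]

    @property
    def catalog(self) -> tuple[str, ...]:
        return self.model.labels.location_catalog

    def _encode_queries(
        self, accessions, annotations: AnnotationTable, homologs: HomologTable
    ) -> FeatureViews:
        return encode_views(
            tuple(accessions), annotations, homologs, self.model.n_homologs, self.vocabs
        )

    def predict_proba(
        self,
        accessions,
        annotations: AnnotationTable,
        homologs: HomologTable,
    ) -> np.ndarray:
        """Per-location probability vectors (rows sum to 1)."""
        query_views = self._encode_queries(accessions, annotations, homologs)
        _, cross = apply_scenario(
            self.train_views,
            query_views,
            self.model.scenario,
            self.model.gamma,
            self.weights,
        )
        return predict_proba(self.ova, cross[:, self.instance_rows])

    def predict(
        self,
        accessions,
        annotations: AnnotationTable,
        homologs: HomologTable,
        theta: float = 0.09,
    ) -> list[frozenset[str]]:
        """Thresholded multi-label predictions (>= 1 location each)."""
        probs = self.predict_proba(accessions, annotations, homologs)
        return [
            threshold_labels(probs[i], self.ova.classes, theta)
            for i in range(len(probs))
        ]

    def summary(self) -> str:
        """Human-readable fit summary: setup, kernel weights, calibration."""
        m = self.model
        lines = [
            "Multi-kernel subcellular localization model",
            "=" * 60,
            f"scenario: {m.scenario}    proteins: {len(m.labels.labels)}"
            f"    locative instances: {len(self.instance_labels)}",
            f"locations (K): {len(self.catalog)}    homologs pooled (H): {m.n_homologs}",
            f"gamma: {m.gamma}    C: {m.C}    seed: {m.seed}",
            "",
            "Kernel weights (inner {0}-fold CV)".format(m.inner_folds),
            "-" * 40,
        ]
        for name in sorted(self.weights, key=lambda n: -self.weights[n]):
            lines.append(f"  {name:<6s} {self.weights[name]:8.4f}")
        lines += ["", "Platt calibration (A, B) per location", "-" * 40]
        for cls, (a, b) in zip(self.ova.classes, self.ova.platt):
            lines.append(f"  {cls:<24s} A={a:+9.4f}  B={b:+9.4f}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Persist as a model bundle (JSON metadata + npz arrays)."""
        metadata = {
            "scenario": self.model.scenario,
            "n_homologs": self.model.n_homologs,
            "gamma": self.model.gamma,
            "C": self.model.C,
            "seed": self.model.seed,
            "catalog": list(self.catalog),
            "weights": self.weights,
            "platt": [[a, b] for a, b in self.ova.platt],
            "classes": list(self.ova.classes),
            "vocabularies": {a: list(v.terms) for a, v in self.vocabs.items()},
            "train_accessions": list(self.train_views.accessions),
            "instance_labels": list(self.instance_labels),
        }
        arrays = {"instance_rows": self.instance_rows}
        for name, mat in self.train_views.matrices.items():
            arrays["view_" + name] = mat
        save_bundle(directory, metadata, arrays)

    @classmethod
    def load(
        cls,
        directory,
        labels: LabelTable,
        annotations: AnnotationTable,
        homologs: HomologTable,
    ) -> "LocalizationResults":
        """Rebuild a results object from a bundle plus its training data.

        The SVMs are retrained deterministically from the stored views and
        hyperparameters (training is cheap relative to storing dual
        coefficients portably).
        """
        metadata, _ = load_bundle(directory)
        model = LocalizationModel(
            labels,
            annotations,
            homologs,
            scenario=metadata["scenario"],
            n_homologs=metadata["n_homologs"],
            gamma=metadata["gamma"],
            C=metadata["C"],
            seed=metadata["seed"],
        )
        return model.fit(weights=metadata["weights"])
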