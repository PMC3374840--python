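"""Six-view binary GO feature encoding.

A protein is represented by six binary indicator vectors over closed,
per-aspect vocabularies fixed at training time:

* ``t_F``, ``t_C``, ``t_P`` -- the protein's own GO terms, split by aspect
  (molecular function F, cellular component C, biological process P);
* ``h_F``, ``h_C``, ``h_P`` -- the union (logical OR) of the GO terms of its
  top-H homologs, ranked by BLAST E-value.

Keeping the target and homolog information in separate views is what lets
the kernel-weighting stage suppress noise from divergent homologs instead of
mixing it irreversibly into a single vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AnnotationTable, HomologTable

ASPECTS = ("F", "C", "P")
TARGET_VIEWS = ("t_F", "t_C", "t_P")
HOMOLOG_VIEWS = ("h_F", "h_C", "h_P")
VIEW_NAMES = TARGET_VIEWS + HOMOLOG_VIEWS


@dataclass
class AspectVocabulary:
    """Ordered, closed vocabulary of GO terms for one aspect."""

    aspect: str
    terms: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise ValueError(f"aspect must be one of {ASPECTS}, got {self.aspect!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in vocabulary")
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def encode(self, go_ids: Iterable[str]) -> np.ndarray:
        """Binary indicator over the vocabulary; unknown terms are ignored."""
        vec = np.zeros(len(self.terms), dtype=np.uint8)
        for go_id in go_ids:
            pos = self.index.get(go_id)
            if pos is not None:
                vec[pos] = 1
        return vec


@dataclass
class FeatureViews:
    """Stacked per-protein feature matrices, one (n x u_aspect) per view."""

    accessions: tuple[str, ...]
    matrices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.accessions)
        for name, mat in self.matrices.items():
            if mat.shape[0] != n:
                raise ValueError(f"view {name}: {mat.shape[0]} rows for {n} proteins")
        self._row = {a: i for i, a in enumerate(self.accessions)}

    def row(self, accession: str) -> int:
        return self._row[accession]

    def subset(self, accessions: Sequence[str]) -> "FeatureViews":
        idx = [self._row[a] for a in accessions]
        return FeatureViews(
            tuple(accessions), {k: v[idx] for k, v in self.matrices.items()}
        )


def build_vocabularies(
    annotations: AnnotationTable,
    training_accessions: Iterable[str],
    homologs: HomologTable | None = None,
    n_homologs: int = 0,
) -> dict[str, AspectVocabulary]:
    """Fix the per-aspect term vocabularies from the training side only.

    The vocabulary of each aspect is the sorted set of terms of that aspect
    seen on any training protein or on any of its selected top-``n_homologs``
    homologs.  Terms first seen at prediction time are dropped at encode
    time; vocabularies never grow after fitting.
    """
    seen: dict[str, set[str]] = {a: set() for a in ASPECTS}
    training_accessions = list(training_accessions)
    for accession in training_accessions:
        pool = [accession]
        if homologs is not None and n_homologs > 0:
            pool.extend(select_homologs(accession, homologs, n_homologs))
        for acc in pool:
            for go_id, aspect in annotations.terms(acc):
                seen[aspect].add(go_id)
    vocabs = {
        aspect: AspectVocabulary(aspect, tuple(sorted(terms)))
        for aspect, terms in seen.items()
    }
    if all(len(v) == 0 for v in vocabs.values()):
        warnings.warn("all aspect vocabularies are empty", stacklevel=2)
    return vocabs


def encode_target_views(
    accession: str,
    annotations: AnnotationTable,
    vocabs: dict[str, AspectVocabulary],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indicator vectors of the protein's own annotations, one per aspect."""
    by_aspect: dict[str, list[str]] = {a: [] for a in ASPECTS}
    for go_id, aspect in annotations.terms(accession):
        by_aspect[aspect].append(go_id)
    return tuple(vocabs[a].encode(by_aspect[a]) for a in ASPECTS)


def select_homologs(
    accession: str, table: HomologTable, n_homologs: int
) -> list[str]:
    """The first ``min(H, available)`` homolog subjects by E-value rank."""
    if n_homologs < 1:
        raise ValueError(f"number of homologs must be >= 1, got {n_homologs}")
    return table.subjects(accession)[:n_homologs]


def encode_homolog_views(
    accession: str,
    table: HomologTable,
    annotations: AnnotationTable,
    n_homologs: int,
    vocabs: dict[str, AspectVocabulary],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OR-aggregated indicator vectors of the top-H homologs' annotations.

    A protein with no homologs, or whose homologs carry no known terms,
    gets all-zero vectors.
    """
    by_aspect: dict[str, list[str]] = {a: [] for a in ASPECTS}
    for subject in select_homologs(accession, table, n_homologs):
        for go_id, aspect in annotations.terms(subject):
            by_aspect[aspect].append(go_id)
    return tuple(vocabs[a].encode(by_aspect[a]) for a in ASPECTS)


def encode_views(
    accessions: Sequence[str],
    annotations: AnnotationTable,
    homologs: HomologTable,
    n_homologs: int,
    vocabs: dict[str, AspectVocabulary],
) -> FeatureViews:
    """Encode all six views for a list of proteins into stacked matrices."""
    rows: dict[str, list[np.ndarray]] = {v: [] for v in VIEW_NAMES}
    for accession in accessions:
        t_vecs = encode_target_views(accession, annotations, vocabs)
        h_vecs = encode_homolog_views(accession, homologs, annotations, n_homologs, vocabs)
        for name, vec in zip(TARGET_VIEWS, t_vecs):
            rows[name].append(vec)
        for name, vec in zip(HOMOLOG_VIEWS, h_vecs):
            rows[name].append(vec)
    matrices = {
        name: (
            np.vstack(vecs)
            if vecs
            else np.zeros((0, len(vocabs[name[-1]])), dtype=np.uint8)
        )
        for name, vecs in rows.items()
    }
    return FeatureViews(tuple(accessions), matrices)
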