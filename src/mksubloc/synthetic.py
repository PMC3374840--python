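"""Synthetic protein worlds for end-to-end benchmarking without downloads.

The generator emulates the statistical structure the method is built for:

* each subcellular location (class) owns a disjoint signature of GO terms in
  every aspect, with the cellular-component (C) aspect carrying the largest
  signature, so C views are the most discriminative;
* a protein draws one or more locations (multiplex fractions configurable),
  annotates itself with its classes' signature terms minus random dropout,
  plus sparse background terms;
* each protein receives a ranked list of homologs.  A homolog is *convergent*
  (re-samples the protein's own class signatures, with extra annotation
  loss) or *divergent* (samples a random non-member class's signatures) with
  a divergence probability that by default grows with homolog rank --
  remote homologs are noisier, which is exactly the negative-transfer
  phenomenon the kernel weighting must suppress.

Worlds are emitted in the same GAF / BLAST-tabular / label-TSV formats the
readers consume, so the whole pipeline round-trips through files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import ASPECTS
from .io import (
    AnnotationTable,
    HomologTable,
    LabelTable,
    write_blast_tab,
    write_gaf,
    write_label_table,
)

# the 14 human compartments, reused as realistic synthetic class names
_LOCATION_POOL = (
    "Nucleus", "Cytoplasm", "Mitochondrion", "Extracell", "Plasma membrane",
    "Endoplasmic reticulum", "Golgi apparatus", "Cytoskeleton", "Centrosome",
    "Lysosome", "Peroxisome", "Endosome", "Microsome", "Synapse",
)


@dataclass
class WorldConfig:
    """Parameters of the synthetic protein world.

    Defaults define the standard benchmark conditions used throughout the
    test-suite: 600 proteins over 6 locations, C-dominant signatures, 20%
    multiplex proteins and rank-increasing homolog divergence.
    """

    n_classes: int = 6
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {"F": 120, "C": 80, "P": 150}
    )
    signature_sizes: dict[str, int] = field(
        default_factory=lambda: {"F": 4, "C": 8, "P": 4}
    )
    dropout: float = 0.2
    background: float = 0.02
    n_proteins: int = 600
    multiplex_fractions: dict[int, float] = field(
        default_factory=lambda: {2: 0.15, 3: 0.04, 4: 0.01}
    )
    n_homologs: int = 7
    divergence_base: float = 0.1
    divergence_step: float = 0.1
    annotation_loss: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if sum(self.multiplex_fractions.values()) > 1.0:
            raise ValueError("multiplex fractions sum above 1")
        if self.multiplex_fractions and max(self.multiplex_fractions) > self.n_classes:
            raise ValueError(
                "multiplex cardinality cannot exceed the number of classes"
            )
        for rate in (
            self.dropout, self.background, self.annotation_loss,
            self.divergence_base,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        for aspect in ASPECTS:
            if self.n_classes * self.signature_sizes[aspect] > self.vocab_sizes[aspect]:
                raise ValueError(f"aspect {aspect}: signatures exceed vocabulary")

    def divergence(self, rank: int) -> float:
        """Probability that the rank-r homolog is divergent."""
        return float(
            np.clip(self.divergence_base + self.divergence_step * (rank - 1), 0.0, 1.0)
        )

    def class_names(self) -> tuple[str, ...]:
        if self.n_classes <= len(_LOCATION_POOL):
            return tuple(sorted(_LOCATION_POOL[: self.n_classes]))
        extra = tuple(
            f"Compartment{i:02d}" for i in range(self.n_classes - len(_LOCATION_POOL))
        )
        return tuple(sorted(_LOCATION_POOL + extra))


def _vocabulary(config: WorldConfig) -> dict[str, tuple[str, ...]]:
    """Per-aspect synthetic GO term identifiers (disjoint across aspects)."""
    offsets = {"F": 1_000_000, "C": 2_000_000, "P": 3_000_000}
    return {
        aspect: tuple(
            f"GO:{offsets[aspect] + i:07d}" for i in range(config.vocab_sizes[aspect])
        )
        for aspect in ASPECTS
    }


def _signatures(
    config: WorldConfig, vocab: dict[str, tuple[str, ...]]
) -> dict[str, dict[str, tuple[str, ...]]]:
    """class -> aspect -> disjoint signature term tuple."""
    classes = config.class_names()
    sigs: dict[str, dict[str, tuple[str, ...]]] = {c: {} for c in classes}
    for aspect in ASPECTS:
        size = config.signature_sizes[aspect]
        for k, cls in enumerate(classes):
            sigs[cls][aspect] = vocab[aspect][k * size : (k + 1) * size]
    return sigs


def _sample_annotation(
    classes: frozenset[str],
    signatures: dict[str, dict[str, tuple[str, ...]]],
    vocab: dict[str, tuple[str, ...]],
    config: WorldConfig,
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Signature terms minus dropout, plus background terms, as (go, aspect)."""
    terms: set[tuple[str, str]] = set()
    for aspect in ASPECTS:
        signature = sorted(
            set().union(*(signatures[c][aspect] for c in sorted(classes)))
        )
        keep = rng.random(len(signature)) >= config.dropout
        terms.update((t, aspect) for t, k in zip(signature, keep) if k)
        if config.background > 0:
            noise = rng.random(len(vocab[aspect])) < config.background
            terms.update(
                (t, aspect) for t, k in zip(vocab[aspect], noise) if k
            )
    return terms


def generate_world(
    config: WorldConfig,
) -> tuple[LabelTable, AnnotationTable, HomologTable]:
    """Generate labels, GO annotations and homolog hits for one world."""
    rng = np.random.default_rng(config.seed)
    classes = config.class_names()
    vocab = _vocabulary(config)
    signatures = _signatures(config, vocab)

    cardinalities = sorted(config.multiplex_fractions)
    probs = [1.0 - sum(config.multiplex_fractions.values())] + [
        config.multiplex_fractions[c] for c in cardinalities
    ]
    choices = [1] + cardinalities

    labels: dict[str, frozenset[str]] = {}
    annotations = AnnotationTable()
    homolog_records: list[tuple[str, str, float, float]] = []
    homolog_counter = 0

    for i in range(config.n_proteins):
        accession = f"SYNP{i:05d}"
        cardinality = int(rng.choice(choices, p=probs))
        member = frozenset(
            rng.choice(len(classes), size=cardinality, replace=False).tolist()
        )
        member_names = frozenset(classes[k] for k in member)
        labels[accession] = member_names
        for go_id, aspect in _sample_annotation(
            member_names, signatures, vocab, config, rng
        ):
            annotations.add(accession, go_id, aspect)
        non_members = [c for c in classes if c not in member_names]
        for rank in range(1, config.n_homologs + 1):
            homolog_counter += 1
            hom_acc = f"SYNH{homolog_counter:06d}"
            if rng.random() < config.divergence(rank) and non_members:
                source = frozenset(
                    {non_members[int(rng.integers(len(non_members)))]}
                )
                hom_terms = _sample_annotation(source, signatures, vocab, config, rng)
            else:
                hom_terms = _sample_annotation(
                    member_names, signatures, vocab, config, rng
                )
                if config.annotation_loss > 0:
                    hom_terms = {
                        t for t in hom_terms
                        if rng.random() >= config.annotation_loss
                    }
            for go_id, aspect in hom_terms:
                annotations.add(hom_acc, go_id, aspect)
            evalue = 10.0 ** -(80 - 10 * rank)
            identity = max(25.0, 95.0 - 10.0 * (rank - 1))
            homolog_records.append((accession, hom_acc, identity, evalue))

    label_table = LabelTable(labels, tuple(classes))
    homolog_table = HomologTable.from_records(homolog_records)
    return label_table, annotations, homolog_table


def write_fixture(
    labels: LabelTable,
    annotations: AnnotationTable,
    homologs: HomologTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a world to disk in the three standard input formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "gaf": write_gaf(annotations, out_dir / "annotations.gaf"),
        "blast": write_blast_tab(homologs, out_dir / "homologs.blast.tsv"),
        "labels": write_label_table(labels, out_dir / "labels.tsv"),
    }
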