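"""Readers and writers for the file formats the pipeline touches.

Three plain-text formats are consumed:

* GAF 2.x -- GO annotations (tab-separated, ``!`` comment lines); only the
  DB Object ID (column 2), GO ID (column 5) and aspect (column 9) are used.
* BLAST tabular ``outfmt 6`` -- precomputed homolog hits (query, subject,
  percent identity, ..., E-value in column 11).
* Label table TSV -- accession TAB comma-joined location names, with an
  optional ``#catalog:`` header fixing the location order.

Writers exist for all three so that synthetic worlds round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

VALID_ASPECTS = frozenset({"F", "C", "P"})


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class AnnotationTable:
    """Protein accession -> set of (GO term id, aspect) pairs."""

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, accession: str, go_id: str, aspect: str) -> None:
        if aspect not in VALID_ASPECTS:
            raise ParseError(f"invalid GO aspect {aspect!r} for {accession}")
        if not accession:
            raise ParseError("empty accession")
        self.entries.setdefault(accession, set()).add((go_id, aspect))

    def terms(self, accession: str) -> set[tuple[str, str]]:
        return self.entries.get(accession, set())

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationTable) and self.entries == other.entries


@dataclass(frozen=True)
class HomologHit:
    query: str
    subject: str
    identity: float
    evalue: float
    rank: int


@dataclass
class HomologTable:
    """Per-query homolog hits ordered by ascending E-value.

    Ranks are 1..n within each query; ties on E-value are broken by
    descending identity, then lexicographic subject, so the order is a
    deterministic function of the set of hits.
    """

    hits: dict[str, list[HomologHit]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]]
    ) -> "HomologTable":
        """Build from (query, subject, identity, evalue) tuples.

        Self-hits (subject == query) are dropped; duplicate (query, subject)
        pairs keep the most significant hit.
        """
        by_query: dict[str, dict[str, tuple[float, float]]] = {}
        for query, subject, identity, evalue in records:
            if subject == query:
                continue
            if not 0.0 <= identity <= 100.0:
                raise ParseError(
                    f"identity {identity} outside [0, 100] for {query}/{subject}"
                )
            if evalue < 0:
                raise ParseError(f"negative E-value for {query}/{subject}")
            prev = by_query.setdefault(query, {}).get(subject)
            if prev is None or (evalue, -identity) < (prev[1], -prev[0]):
                by_query[query][subject] = (identity, evalue)
        table = cls()
        for query, subjects in by_query.items():
            ordered = sorted(
                subjects.items(), key=lambda kv: (kv[1][1], -kv[1][0], kv[0])
            )
            table.hits[query] = [
                HomologHit(query, subj, ident, ev, rank)
                for rank, (subj, (ident, ev)) in enumerate(ordered, start=1)
            ]
        return table

    def subjects(self, query: str) -> list[str]:
        return [h.subject for h in self.hits.get(query, [])]

    def __eq__(self, other) -> bool:
        return isinstance(other, HomologTable) and self.hits == other.hits


@dataclass
class LabelTable:
    """Protein accession -> non-empty set of subcellular locations."""

    labels: dict[str, frozenset[str]] = field(default_factory=dict)
    location_catalog: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.location_catalog:
            self.location_catalog = tuple(
                sorted(set().union(*self.labels.values())) if self.labels else ()
            )
        catalog = set(self.location_catalog)
        for acc, locs in self.labels.items():
            if not locs:
                raise ParseError(f"empty label set for {acc}")
            unknown = locs - catalog
            if unknown:
                raise ParseError(f"labels {sorted(unknown)} of {acc} not in catalog")

    @property
    def n_locations(self) -> int:
        return len(self.location_catalog)

    def accessions(self) -> list[str]:
        return sorted(self.labels)

    def singlex(self) -> list[str]:
        return [a for a in self.accessions() if len(self.labels[a]) == 1]

    def multiplex(self) -> list[str]:
        return [a for a in self.accessions() if len(self.labels[a]) > 1]

    def subset(self, accessions: Iterable[str]) -> "LabelTable":
        keep = set(accessions)
        return LabelTable(
            {a: s for a, s in self.labels.items() if a in keep},
            self.location_catalog,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LabelTable)
            and self.labels == other.labels
            and self.location_catalog == other.location_catalog
        )


# ---------------------------------------------------------------------------
# GAF


def read_gaf(path: str | Path) -> AnnotationTable:
    """Read a GAF 2.x file into an :class:`AnnotationTable`.

    Only columns 2 (DB Object ID), 5 (GO ID) and 9 (aspect) are consumed;
    qualifier and evidence-code columns are ignored.  Duplicate associations
    collapse to one entry.
    """
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(
                    f"{path}:{lineno}: GAF line has {len(cols)} columns, need >= 9"
                )
            accession, go_id, aspect = cols[1], cols[4], cols[8]
            if aspect not in VALID_ASPECTS:
                raise ParseError(
                    f"{path}:{lineno}: aspect {aspect!r} not one of F/C/P"
                )
            table.add(accession, go_id, aspect)
    return table


def write_gaf(table: AnnotationTable, path: str | Path, db: str = "SYN") -> Path:
    """Write an :class:`AnnotationTable` as minimal GAF 2.2."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for accession in sorted(table.entries):
            for go_id, aspect in sorted(table.entries[accession]):
                cols = [
                    db, accession, accession, "", go_id, "SYN:ref", "IEA", "",
                    aspect, "", "", "protein", "taxon:9606", "20091130", db,
                    "", "",
                ]
                fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tab(path: str | Path) -> HomologTable:
    """Read BLAST ``outfmt 6`` hits into a :class:`HomologTable`.

    Hits are grouped per query and ranked by ascending E-value (ties:
    descending identity, then subject id); self-hits are removed.  An empty
    file yields an empty table.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ParseError(
                    f"{path}:{lineno}: outfmt-6 line has {len(cols)} columns, need >= 11"
                )
            try:
                identity = float(cols[2])
                evalue = float(cols[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            records.append((cols[0], cols[1], identity, evalue))
    return HomologTable.from_records(records)


def write_blast_tab(table: HomologTable, path: str | Path) -> Path:
    """Write a :class:`HomologTable` as 12-column BLAST outfmt 6."""
    path = Path(path)
    with open(path, "w") as fh:
        for query in sorted(table.hits):
            for hit in table.hits[query]:
                cols = [
                    hit.query, hit.subject, f"{hit.identity:.2f}", "100", "0",
                    "0", "1", "100", "1", "100", f"{hit.evalue:.2e}", "200.0",
                ]
                fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# Label table


def read_label_table(path: str | Path) -> LabelTable:
    """Read a two-column TSV of accession TAB comma-joined locations.

    A ``#catalog:`` header (comma-joined names) fixes the catalog order;
    otherwise the catalog is the sorted union of all observed locations.
    """
    labels: dict[str, frozenset[str]] = {}
    catalog: tuple[str, ...] = ()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#catalog:"):
                catalog = tuple(
                    name.strip() for name in line[len("#catalog:"):].split(",")
                )
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            accession = cols[0].strip()
            locs = frozenset(
                name.strip() for name in cols[1].split(",") if name.strip()
            )
            if not locs:
                raise ParseError(f"{path}:{lineno}: empty location field for {accession}")
            if accession in labels and labels[accession] != locs:
                raise ParseError(
                    f"{path}:{lineno}: conflicting labels for duplicate accession {accession}"
                )
            labels[accession] = locs
    return LabelTable(labels, catalog)


def write_label_table(table: LabelTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#catalog: " + ", ".join(table.location_catalog) + "\n")
        for accession in table.accessions():
            fh.write(accession + "\t" + ",".join(sorted(table.labels[accession])) + "\n")
    return path


# ---------------------------------------------------------------------------
# Prediction report and model bundle


def write_prediction_report(
    accessions: list[str],
    probabilities: np.ndarray,
    predicted: list[frozenset[str]],
    catalog: tuple[str, ...],
    path: str | Path,
) -> Path:
    """TSV report: accession, one probability column per location, label set."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("accession\t" + "\t".join(catalog) + "\tpredicted\n")
        for i, accession in enumerate(accessions):
            probs = "\t".join(f"{p:.6f}" for p in probabilities[i])
            fh.write(f"{accession}\t{probs}\t" + ",".join(sorted(predicted[i])) + "\n")
    return path


def read_prediction_report(path: str | Path) -> tuple[list[str], np.ndarray, list[frozenset[str]], tuple[str, ...]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        catalog = tuple(header[1:-1])
        accessions, rows, predicted = [], [], []
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            accessions.append(cols[0])
            rows.append([float(v) for v in cols[1:-1]])
            predicted.append(frozenset(cols[-1].split(",")) if cols[-1] else frozenset())
    return accessions, np.asarray(rows), predicted, catalog


def save_bundle(directory: str | Path, metadata: Mapping, arrays: Mapping[str, np.ndarray]) -> Path:
    """Persist a fitted model: JSON metadata plus ``.npz`` numeric arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=1, sort_keys=True)
    np.savez(directory / "arrays.npz", **arrays)
    return directory


def load_bundle(directory: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    directory = Path(directory)
    with open(directory / "metadata.json") as fh:
        metadata = json.load(fh)
    with np.load(directory / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    return metadata, arrays
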