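"""Domain types and I/O for labeled marker-sequence datasets.

A dataset is an ordered collection of short marker sequences (e.g. the
nuclear ribosomal ITS2 region, ~200 bp in plants), each carrying a species
label and optional higher-rank taxonomy. Sequences arrive as FASTA; labels
arrive as a separate tab-separated metadata table keyed by sequence ID —
the table is authoritative for taxonomy, FASTA headers are treated as
opaque identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "GC_FRACTION",
    "SequenceRecord",
    "Dataset",
    "SequenceSummary",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "summarize",
    "gc_percent",
]

#: Unambiguous plus ambiguous IUPAC DNA codes accepted in residues.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Fraction of G+C among the bases each IUPAC code can resolve to.
GC_FRACTION: Mapping[str, float] = {
    "A": 0.0, "C": 1.0, "G": 1.0, "T": 0.0,
    "R": 0.5, "Y": 0.5, "S": 1.0, "W": 0.0,
    "K": 0.5, "M": 0.5,
    "B": 2 / 3, "V": 2 / 3, "D": 1 / 3, "H": 1 / 3,
    "N": 0.5,
}

#: Bases each IUPAC code can stand for (used by alignment scoring).
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class FastaError(ValueError):
    """Malformed FASTA input (names the offending entry)."""


class MetadataError(ValueError):
    """Metadata table violates the expected schema or coverage."""


@dataclass(frozen=True)
class SequenceRecord:
    """One marker sequence with its taxonomy labels and provenance.

    ``species`` is the operational taxonomic unit (OTU) label; named
    infraspecific varieties count as distinct OTUs. ``role`` separates
    study-group samples ("ingroup") from rooting taxa ("outgroup").
    """

    id: str
    residues: str
    species: str | None = None
    subgenus: str | None = None
    section: str | None = None
    accession: str | None = None
    role: str = "ingroup"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.role not in ("ingroup", "outgroup"):
            raise ValueError(f"record {self.id!r}: role must be ingroup/outgroup")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """Ordered collection of :class:`SequenceRecord` with unique IDs."""

    records: list[SequenceRecord]
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        """Map record id -> species label (labeled records only)."""
        return {r.id: r.species for r in self.records if r.species is not None}

    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.species is not None and rec.species not in out:
                out.append(rec.species)
        return out

    def ingroup(self) -> "Dataset":
        return Dataset([r for r in self.records if r.role == "ingroup"],
                       name=self.name)

    def require_labels(self) -> None:
        missing = [r.id for r in self.records if r.species is None]
        if missing:
            raise MetadataError(f"records lacking a species label: {missing}")


@dataclass(frozen=True)
class SequenceSummary:
    """Dataset-level descriptive statistics (lengths in bp, GC in percent)."""

    n_records: int
    n_species: int
    length_min: int
    length_max: int
    length_mean: float
    gc_min: float
    gc_max: float
    gc_mean: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def to_tsv(self) -> str:
        keys = list(self.__dict__)
        vals = [str(self.__dict__[k]) for k in keys]
        return "\t".join(keys) + "\n" + "\t".join(vals) + "\n"


def gc_percent(residues: str) -> float:
    """GC content in percent, resolving ambiguity codes fractionally.

    S counts 1 (it is G or C); two-fold codes like R count 0.5; three-fold
    codes 1/3 or 2/3 by composition; N counts 0.5. The denominator is the
    full sequence length, so the result is deterministic and independent
    of record order.
    """
    if not residues:
        raise ValueError("empty sequence")
    return 100.0 * sum(GC_FRACTION[c] for c in residues) / len(residues)


def _canonical(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, name: str | None = None) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Residues are upper-cased and U is mapped to T. The first whitespace-
    delimited token of each header is the record ID. Duplicate IDs, empty
    sequences and non-IUPAC characters raise :class:`FastaError` naming
    the offending entry.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _canonical(str(entry.seq))
        try:
            records.append(SequenceRecord(id=entry.id, residues=seq))
        except ValueError as exc:
            raise FastaError(f"{path.name}: entry {entry.id!r}: {exc}") from exc
    if not records:
        raise FastaError(f"{path.name}: no FASTA entries found")
    try:
        return Dataset(records, name=name or path.stem)
    except ValueError as exc:  # duplicate ids
        raise FastaError(f"{path.name}: {exc}") from exc


def write_fasta(dataset: Dataset | Iterable[SequenceRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA wrapped at ``width`` columns."""
    records = dataset.records if isinstance(dataset, Dataset) else list(dataset)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


_META_COLUMNS = ("id", "species", "subgenus", "section", "accession", "role")
_MANDATORY = ("id", "species")


def read_metadata(path: str | Path, dataset: Dataset,
                  ) -> tuple[Dataset, list[str]]:
    """Attach taxonomy labels from a TSV table to ``dataset`` by record ID.

    The table must have a header row with at least ``id`` and ``species``
    columns; ``subgenus``, ``section``, ``accession`` and ``role`` are
    optional. Returns the labeled dataset plus the list of table IDs with
    no matching FASTA record (reported, not fatal). A FASTA record with no
    table row is an error: every analyzed sequence needs a species label.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in _MANDATORY if c not in table.columns]
    if missing_cols:
        raise MetadataError(f"metadata missing mandatory column(s): {missing_cols}")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise MetadataError(f"duplicate metadata ids: {dups}")

    rows = {row["id"]: row for _, row in table.iterrows()}
    unmatched = [rid for rid in rows if rid not in set(dataset.ids)]

    labeled: list[SequenceRecord] = []
    missing_meta = [rid for rid in dataset.ids if rid not in rows]
    if missing_meta:
        raise MetadataError(f"FASTA ids absent from metadata: {missing_meta}")
    for rec in dataset:
        row = rows[rec.id]
        species = row["species"].strip()
        if not species:
            raise MetadataError(f"record {rec.id!r}: empty species label")
        labeled.append(replace(
            rec,
            species=species,
            subgenus=row.get("subgenus", "").strip() or None,
            section=row.get("section", "").strip() or None,
            accession=row.get("accession", "").strip() or None,
            role=(row.get("role", "").strip() or "ingroup"),
        ))
    return Dataset(labeled, name=dataset.name), unmatched


def write_metadata(dataset: Dataset, path: str | Path) -> None:
    """Write the six-column metadata TSV (UTF-8, header row)."""
    rows = [
        {
            "id": r.id,
            "species": r.species or "",
            "subgenus": r.subgenus or "",
            "section": r.section or "",
            "accession": r.accession or "",
            "role": r.role,
        }
        for r in dataset
    ]
    pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def summarize(dataset: Dataset) -> SequenceSummary:
    """Lengths and GC content across the dataset (arithmetic means)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    lengths = [len(r) for r in dataset]
    gcs = [gc_percent(r.residues) for r in dataset]
    species = {r.species for r in dataset if r.species is not None}
    return SequenceSummary(
        n_records=len(dataset),
        n_species=len(species),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=sum(lengths) / len(lengths),
        gc_min=min(gcs),
        gc_max=max(gcs),
        gc_mean=sum(gcs) / len(gcs),
    )
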