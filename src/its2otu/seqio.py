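"""Sequence and table I/O plus the core in-memory data model.

All nucleotide strings are stored uppercase over ``{A, C, G, T, N}`` for
reads; primers and reference sequences may additionally carry IUPAC
ambiguity codes.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "MappingRow",
    "MappingTable",
    "UniqueSequence",
    "CountTable",
    "ReferenceEntry",
    "ReferenceDB",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_mapping",
    "write_mapping",
    "read_count_table",
    "write_count_table",
    "read_reference_fasta",
    "sequence_id",
]

IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "U": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"G", "C"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_READ_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _normalize_read_seq(seq: str) -> str:
    """Uppercase and map any IUPAC ambiguity in a read to N."""
    seq = seq.upper()
    if set(seq) <= _READ_ALPHABET:
        return seq
    return "".join(c if c in _READ_ALPHABET else "N" for c in seq)


@dataclass(frozen=True)
class SequenceRecord:
    """One read or reference sequence.

    Parameters
    ----------
    id : str
        Non-empty label, unique within one file.
    seq : str
        Nucleotide string over ``{A, C, G, T, N}``, stored uppercase.
    qual : tuple of int, optional
        Per-base Phred quality scores, same length as ``seq``.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"sequence {self.id!r}: qual length {len(self.qual)} "
                f"!= seq length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MappingRow:
    sample_id: str
    barcode: str
    forward_primer: str
    reverse_primer: str


@dataclass
class MappingTable:
    """Sample → barcode/primer mapping for demultiplexing.

    Barcodes must be unique and equal length within one run; primers may
    carry IUPAC degeneracies.
    """

    rows: list[MappingRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in mapping")
        barcodes = [r.barcode for r in self.rows]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcode in mapping")
        lengths = {len(b) for b in barcodes}
        if len(lengths) > 1:
            raise ValueError(f"barcodes have unequal lengths: {sorted(lengths)}")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    @property
    def barcode_length(self) -> int:
        if not self.rows:
            raise ValueError("empty mapping table")
        return len(self.rows[0].barcode)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[MappingRow]:
        return iter(self.rows)


def sequence_id(seq: str) -> str:
    """Stable 12-hex-digit identifier for a nucleotide string (sha1 prefix)."""
    return hashlib.sha1(seq.encode("ascii")).hexdigest()[:12]


@dataclass
class UniqueSequence:
    """A dereplicated variant with per-sample read counts."""

    seq: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty variant sequence")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        self.counts = {s: c for s, c in self.counts.items() if c > 0}
        if self.total < 1:
            raise ValueError("variant with zero total count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def id(self) -> str:
        return sequence_id(self.seq)


class CountTable:
    """Unique variants × samples count matrix.

    Variants are kept in a stable order (descending total count, then
    lexicographic sequence) so that all downstream outputs are
    bit-reproducible.
    """

    def __init__(self, variants: Iterable[UniqueSequence], samples: Sequence[str]):
        self.samples = list(samples)
        variants = list(variants)
        seqs = [v.seq for v in variants]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate variant sequence in CountTable")
        sample_set = set(self.samples)
        for v in variants:
            unknown = set(v.counts) - sample_set
            if unknown:
                raise ValueError(f"counts reference unknown samples: {sorted(unknown)}")
        self.variants = sorted(variants, key=lambda v: (-v.total, v.seq))

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[UniqueSequence]:
        return iter(self.variants)

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def total_reads(self) -> int:
        return sum(v.total for v in self.variants)

    def variant_by_id(self, vid: str) -> UniqueSequence:
        for v in self.variants:
            if v.id == vid:
                return v
        raise KeyError(vid)

    def sample_counts(self, sample_id: str) -> dict[str, int]:
        """Variant id → count for one sample (zero counts omitted)."""
        if sample_id not in self.samples:
            raise KeyError(sample_id)
        out: dict[str, int] = {}
        for v in self.variants:
            c = v.counts.get(sample_id, 0)
            if c:
                out[v.id] = c
        return out

    def sample_total(self, sample_id: str) -> int:
        return sum(v.counts.get(sample_id, 0) for v in self.variants)

    def subset(self, ids: Iterable[str]) -> "CountTable":
        wanted = set(ids)
        return CountTable(
            [v for v in self.variants if v.id in wanted], self.samples
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sequence_id": [v.id for v in self.variants],
            "sequence": [v.seq for v in self.variants],
        }
        for s in self.samples:
            data[s] = [v.counts.get(s, 0) for v in self.variants]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.samples == other.samples and [
            (v.seq, v.counts) for v in self.variants
        ] == [(v.seq, v.counts) for v in other.variants]


@dataclass(frozen=True)
class ReferenceEntry:
    type_name: str
    seq: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"reference {self.type_name!r} has empty sequence")


class ReferenceDB:
    """Annotated ITS2 type sequences used for nearest-reference annotation."""

    def __init__(self, entries: Iterable[ReferenceEntry]):
        self.entries = list(entries)
        keys = [(e.type_name, e.source_tag) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (type_name, source_tag) in reference DB")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self.entries)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, ambiguity → N)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"{path}: record {i + 1} has an empty header")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} (#{i + 1}) has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_read_seq(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line Phred+33 FASTQ into SequenceRecords with integer quals."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            quals = tuple(rec.letter_annotations["phred_quality"])
            records.append(
                SequenceRecord(rec.id, _normalize_read_seq(str(rec.seq)), quals)
            )
    except ValueError as exc:  # biopython signals seq/qual length mismatch etc.
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        qual = list(r.qual) if r.qual is not None else [40] * len(r.seq)
        b = _BioRecord(Seq(r.seq), id=r.id, description="")
        b.letter_annotations["phred_quality"] = qual
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


# ---------------------------------------------------------------------------
# Mapping table (TSV: sample, barcode, fwd_primer, rev_primer)
# ---------------------------------------------------------------------------

_MAPPING_COLS = ["sample", "barcode", "fwd_primer", "rev_primer"]


def read_mapping(path: str | Path) -> MappingTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _MAPPING_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mapping columns {missing}")
    rows = [
        MappingRow(
            sample_id=str(r["sample"]),
            barcode=str(r["barcode"]).upper(),
            forward_primer=str(r["fwd_primer"]).upper(),
            reverse_primer=str(r["rev_primer"]).upper(),
        )
        for _, r in df.iterrows()
    ]
    try:
        return MappingTable(rows)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_mapping(mapping: MappingTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": [r.sample_id for r in mapping],
            "barcode": [r.barcode for r in mapping],
            "fwd_primer": [r.forward_primer for r in mapping],
            "rev_primer": [r.reverse_primer for r in mapping],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Count table (TSV: sequence_id, sequence, then one column per sample)
# ---------------------------------------------------------------------------


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "sequence": str},
                     comment="#")
    for col in ("sequence_id", "sequence"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    samples = [c for c in df.columns if c not in ("sequence_id", "sequence")]
    variants = []
    for _, row in df.iterrows():
        counts = {s: int(row[s]) for s in samples if int(row[s]) > 0}
        variants.append(UniqueSequence(str(row["sequence"]), counts))
    return CountTable(variants, samples)


# ---------------------------------------------------------------------------
# Reference database FASTA (header: "<type_name> <source_tag>")
# ---------------------------------------------------------------------------


def read_reference_fasta(path: str | Path) -> ReferenceDB:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        type_name = parts[0]
        source_tag = parts[1] if len(parts) > 1 else ""
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: reference {type_name!r} has empty sequence")
        entries.append(ReferenceEntry(type_name, str(rec.seq).upper(), source_tag))
    return ReferenceDB(entries)


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in db:
            header = f">{e.type_name} {e.source_tag}".rstrip()
            fh.write(f"{header}\n{e.seq}\n")
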