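"""Reading, writing and validating alignments and metadata tables.

File parsing is delegated to Biopython (:mod:`Bio.AlignIO`) for the two
supported formats, aligned FASTA and Clustal; this module owns the
validation layer: equal record lengths, unique identifiers, a declared
residue alphabet, and case/gap normalization (lower case folded to upper,
``.`` folded to ``-``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import SEQUENCE_ALPHABET
from .errors import AlignmentError, MetadataError

FORMATS = ("fasta", "clustal")


@dataclass(frozen=True)
class Alignment:
    """An ordered, identified, equal-length gapped protein alignment.

    Depth 0 is permitted only as a query result (e.g. an empty cell
    selection); such alignments cannot be written to disk.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        validate_records(self.records)

    @property
    def depth(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise AlignmentError(f"unknown sequence id: {record_id!r}")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)


def _normalize_sequence(record_id: str, raw: str) -> str:
    """Upper-case, fold '.' to '-', and reject out-of-alphabet symbols."""
    seq = raw.upper().replace(".", "-")
    for pos, sym in enumerate(seq, start=1):
        if sym not in SEQUENCE_ALPHABET:
            raise AlignmentError(
                f"illegal symbol {sym!r} at position {pos} of sequence {record_id!r}"
            )
    return seq


def validate_records(records: Iterable[tuple[str, str]]) -> None:
    records = tuple(records)
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise AlignmentError(f"duplicate sequence id: {rid!r}")
        seen.add(rid)
    if records:
        length = len(records[0][1])
        for rid, seq in records:
            if len(seq) != length:
                raise AlignmentError(
                    f"not aligned: sequence {rid!r} has length {len(seq)}, "
                    f"expected {length}"
                )


def make_alignment(records: Iterable[tuple[str, str]]) -> Alignment:
    """Build a validated Alignment from (id, sequence) pairs, normalizing case/gaps."""
    normalized = tuple((rid, _normalize_sequence(rid, seq)) for rid, seq in records)
    return Alignment(normalized)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into a validated Alignment.

    Record order is preserved; ids are the first whitespace-delimited
    header token (FASTA) or the Clustal record name.
    """
    if format not in FORMATS:
        raise AlignmentError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        # Biopython raises ValueError for empty files and for FASTA files
        # whose records differ in length; re-check lengths ourselves so the
        # message names the offending record.
        records = _raw_records(path, format)
        if not records:
            raise AlignmentError(f"empty alignment file: {path}") from exc
        validate_records(records)
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(msa) == 0:
        raise AlignmentError(f"empty alignment file: {path}")
    return make_alignment((rec.id, str(rec.seq)) for rec in msa)


def _raw_records(path: Path, format: str) -> list[tuple[str, str]]:
    """Length-tolerant record scan used only to produce better error messages."""
    if format != "fasta":
        return []
    records: list[tuple[str, str]] = []
    rid, chunks = None, []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if rid is not None:
                records.append((rid, "".join(chunks)))
            rid, chunks = line[1:].split()[0] if line[1:].split() else "", []
        elif rid is not None:
            chunks.append(line.strip())
    if rid is not None:
        records.append((rid, "".join(chunks)))
    return records


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an Alignment; round-trips ids, order and sequences exactly."""
    if format not in FORMATS:
        raise AlignmentError(f"unknown format {format!r}; expected one of {FORMATS}")
    if aln.depth == 0:
        raise AlignmentError("cannot write an empty alignment")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln
    )
    with open(path, "w") as handle:
        AlignIO.write(msa, handle, format)


@dataclass(frozen=True)
class MetadataTable:
    """Per-sequence annotations keyed by sequence id (a thin pandas wrapper)."""

    frame: pd.DataFrame = field(compare=False)
    key_column: str = "id"

    def __post_init__(self) -> None:
        if self.key_column not in self.frame.columns:
            raise MetadataError(f"missing key column {self.key_column!r}")
        keys = self.frame[self.key_column]
        dupes = keys[keys.duplicated()]
        if not dupes.empty:
            raise MetadataError(f"duplicate key {dupes.iloc[0]!r} in metadata table")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def value(self, record_id: str, column: str):
        """Return the cell for (record_id, column), or None if the id is absent."""
        if column not in self.frame.columns:
            raise MetadataError(f"unknown metadata column {column!r}")
        sub = self.frame.loc[self.frame[self.key_column] == record_id, column]
        return None if sub.empty else sub.iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


def read_metadata(path: str | Path, key_column: str = "id") -> MetadataTable:
    """Read a TSV/CSV metadata table (delimiter sniffed by extension, then content)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".tab"}:
        sep = "\t"
    elif suffix == ".csv":
        sep = ","
    else:
        sample = path.read_text()[:4096]
        try:
            sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
        except csv.Error:
            sep = "\t"
    frame = pd.read_csv(io.StringIO(path.read_text()), sep=sep, dtype=str)
    return MetadataTable(frame=frame, key_column=key_column)
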