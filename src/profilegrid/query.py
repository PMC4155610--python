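"""Treat the alignment as a searchable database of sequence records.

Cell queries (which sequences carry residue r at column c), frequency
threshold highlighting, reference/highlight consensus diffing, and
metadata-driven subsetting.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Optional

import numpy as np

from .alphabet import ROW_ALPHABET_X, fold_symbol
from .errors import MetadataError, ProfileError
from .msa_io import Alignment, MetadataTable
from .profile import FrequencyMatrix


class CellAddress(NamedTuple):
    """A (residue row, 1-based column) cell of a ProfileGrid."""

    residue: str
    column: int


class DiffMark(NamedTuple):
    """A column where highlight differs from reference, with the highlight symbol."""

    column: int
    residue: str


CellMask = frozenset  # of CellAddress
DiffMarks = frozenset  # of DiffMark

_OPS = {
    "ge": np.greater_equal,
    "le": np.less_equal,
    "gt": np.greater,
    "lt": np.less,
}


def select_cell(aln: Alignment, cell: CellAddress) -> Alignment:
    """Extract the sub-alignment of records matching a ProfileGrid cell.

    A record matches when its ambiguity-folded symbol at ``cell.column``
    equals ``cell.residue``. Original order is preserved; the result depth
    equals the ProfileMatrix count at that cell. A zero-count cell yields
    an empty (depth-0) alignment, valid as a query result only.
    """
    residue = fold_symbol(cell.residue.upper())
    if residue not in ROW_ALPHABET_X:
        raise ProfileError(f"unknown residue row {cell.residue!r}")
    if not 1 <= cell.column <= aln.length:
        raise ProfileError(f"column {cell.column} out of range 1..{aln.length}")
    hits = tuple(
        (rid, seq)
        for rid, seq in aln
        if fold_symbol(seq[cell.column - 1]) == residue
    )
    return Alignment(hits)


def highlight_by_threshold(
    freqs: FrequencyMatrix,
    op: str,
    threshold: float,
    rows: Optional[Iterable[str]] = None,
) -> CellMask:
    """Cells whose frequency satisfies ``f op threshold``.

    Zero-frequency cells are never returned (absence is already encoded by
    the white shade, not by marks). ``rows`` optionally restricts the mask
    to a subset of residue rows.
    """
    if op not in _OPS:
        raise ProfileError(f"unknown operator {op!r}; expected one of {sorted(_OPS)}")
    if not 0.0 <= threshold <= 1.0:
        raise ProfileError(f"threshold {threshold} outside [0, 1]")
    row_filter = None if rows is None else {fold_symbol(r.upper()) for r in rows}
    hits = _OPS[op](freqs.freqs, threshold) & (freqs.freqs > 0)
    mask = set()
    for r, c in zip(*np.nonzero(hits)):
        sym = freqs.row_alphabet[r]
        if row_filter is None or sym in row_filter:
            mask.add(CellAddress(sym, int(c) + 1))
    return frozenset(mask)


def diff_sequences(reference: str, highlight: str) -> DiffMarks:
    """Columns where the highlight sequence differs from the reference.

    Case is folded before comparison; the gap symbol participates as an
    ordinary symbol. Each mark records the highlight symbol, which is the
    cell that gets the pink border in a rendered figure.
    """
    if len(reference) != len(highlight):
        raise ProfileError(
            f"length mismatch: reference {len(reference)} vs highlight {len(highlight)}"
        )
    ref, hil = reference.upper(), highlight.upper()
    return frozenset(
        DiffMark(c, hil[c - 1])
        for c in range(1, len(ref) + 1)
        if ref[c - 1] != hil[c - 1]
    )


def filter_by_metadata(
    aln: Alignment,
    table: MetadataTable,
    column: str,
    predicate: str,
    value,
) -> Alignment:
    """Sub-alignment of records whose metadata satisfies the predicate.

    Predicates: ``equals``, ``not_equals``, ``in_set`` (value is an
    iterable). Records absent from the table never match any predicate
    (fail-safe subsetting); order is preserved.
    """
    if column not in table.columns:
        raise MetadataError(f"unknown metadata column {column!r}")
    if predicate not in ("equals", "not_equals", "in_set"):
        raise MetadataError(f"unknown predicate {predicate!r}")
    if predicate == "in_set":
        wanted = {str(v) for v in value}

    def matches(rid: str) -> bool:
        cell = table.value(rid, column)
        if cell is None:
            return False
        if predicate == "equals":
            return str(cell) == str(value)
        if predicate == "not_equals":
            return str(cell) != str(value)
        return str(cell) in wanted

    return Alignment(tuple((rid, seq) for rid, seq in aln if matches(rid)))
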