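"""Reduce an alignment to per-column residue counts and frequencies.

The ProfileGrid core: an alignment of N sequences and L columns becomes a
21-row count matrix (20 residues + gap; an X row is appended only when
ambiguity codes occur), a depth-normalized frequency matrix, and a
plurality ("majority") consensus sequence with explicit tie records.

Columns are 1-based everywhere they are reported or rendered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import GAP, ROW_ALPHABET, ROW_ALPHABET_X, X, fold_symbol
from .errors import ProfileError
from .msa_io import Alignment

# uint8 lookup: ASCII byte of each (folded) symbol -> row index in ROW_ALPHABET_X.
_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _sym in enumerate(ROW_ALPHABET_X):
    _LOOKUP[ord(_sym)] = _i
for _amb in "BZJUO":
    _LOOKUP[ord(_amb)] = ROW_ALPHABET_X.index(X)


@dataclass(frozen=True)
class ProfileMatrix:
    """Integer residue counts per alignment column.

    ``counts[r, c]`` is the number of sequences whose (ambiguity-folded)
    symbol at column c+1 equals ``row_alphabet[r]``. The gap row absorbs
    gaps, so every column sums to the alignment depth.
    """

    row_alphabet: tuple[str, ...]
    counts: np.ndarray  # shape (rows, L), int64
    depth: int

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def row_index(self, residue: str) -> int:
        try:
            return self.row_alphabet.index(residue)
        except ValueError:
            raise ProfileError(f"unknown residue row {residue!r}") from None

    def count(self, residue: str, column: int) -> int:
        """Count at a 1-based (residue, column) cell."""
        if not 1 <= column <= self.length:
            raise ProfileError(f"column {column} out of range 1..{self.length}")
        return int(self.counts[self.row_index(residue), column - 1])

    def to_tsv(self) -> str:
        """TSV export: header of 1-based column indices, one row per symbol."""
        lines = ["residue\t" + "\t".join(str(c) for c in range(1, self.length + 1))]
        for r, sym in enumerate(self.row_alphabet):
            lines.append(sym + "\t" + "\t".join(str(int(v)) for v in self.counts[r]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class FrequencyMatrix:
    """Counts normalized by alignment depth; every column sums to 1."""

    row_alphabet: tuple[str, ...]
    freqs: np.ndarray  # shape (rows, L), float64 in [0, 1]
    depth: int

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    def row_index(self, residue: str) -> int:
        try:
            return self.row_alphabet.index(residue)
        except ValueError:
            raise ProfileError(f"unknown residue row {residue!r}") from None

    def frequency(self, residue: str, column: int) -> float:
        if not 1 <= column <= self.length:
            raise ProfileError(f"column {column} out of range 1..{self.length}")
        return float(self.freqs[self.row_index(residue), column - 1])

    def to_tsv(self) -> str:
        """TSV export with fixed 6-decimal frequencies."""
        lines = ["residue\t" + "\t".join(str(c) for c in range(1, self.length + 1))]
        for r, sym in enumerate(self.row_alphabet):
            lines.append(sym + "\t" + "\t".join(f"{v:.6f}" for v in self.freqs[r]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-column plurality symbols plus the columns where the maximum tied.

    ``ties[c]`` is a frozenset of the symbols sharing the column maximum
    when at least two do, else empty. The degenerate all-gap column under
    gap_policy="excluded" is flagged with the singleton {'-'}.
    """

    symbols: str
    ties: tuple[frozenset[str], ...]

    def __str__(self) -> str:
        return self.symbols


def build_profile(aln: Alignment) -> ProfileMatrix:
    """Tally residue counts per column, folding ambiguity codes to X.

    The X row is appended only when its total count is nonzero, so clean
    alignments keep exactly 21 rows.
    """
    if aln.depth == 0:
        raise ProfileError("cannot profile an empty alignment")
    raw = np.frombuffer("".join(aln.sequences).encode("ascii"), dtype=np.uint8)
    idx = _LOOKUP[raw].reshape(aln.depth, aln.length).astype(np.int64)
    length = aln.length
    counts = np.zeros((len(ROW_ALPHABET_X), length), dtype=np.int64)
    cols = np.broadcast_to(np.arange(length), idx.shape)
    np.add.at(counts, (idx.ravel(), cols.ravel()), 1)
    if counts[-1].sum() == 0:  # no ambiguity codes: drop the X row
        return ProfileMatrix(ROW_ALPHABET, counts[:-1], aln.depth)
    return ProfileMatrix(ROW_ALPHABET_X, counts, aln.depth)


def normalize(profile: ProfileMatrix) -> FrequencyMatrix:
    """Divide counts by alignment depth."""
    if profile.depth < 1:
        raise ProfileError("cannot normalize a profile of depth 0")
    return FrequencyMatrix(
        profile.row_alphabet, profile.counts / profile.depth, profile.depth
    )


def merge_profiles(a: ProfileMatrix, b: ProfileMatrix) -> ProfileMatrix:
    """Add two tallies over the same columns (counts add, depth adds)."""
    if a.row_alphabet != b.row_alphabet:
        raise ProfileError(
            f"row alphabet mismatch: {a.row_alphabet} vs {b.row_alphabet}"
        )
    if a.length != b.length:
        raise ProfileError(f"length mismatch: {a.length} vs {b.length}")
    return ProfileMatrix(a.row_alphabet, a.counts + b.counts, a.depth + b.depth)


def compute_consensus(
    profile: ProfileMatrix, gap_policy: str = "eligible"
) -> ConsensusSequence:
    """Plurality consensus per column.

    gap_policy="eligible" lets the gap row win a column; "excluded" drops it
    from candidacy (an all-gap column then yields '-' with a flagged tie).
    Ties break toward the earlier row-alphabet symbol (residues
    alphabetically, then '-', then 'X') and are recorded.
    """
    if gap_policy not in ("eligible", "excluded"):
        raise ProfileError(f"unknown gap_policy {gap_policy!r}")
    alphabet = profile.row_alphabet
    eligible = [
        i for i, s in enumerate(alphabet) if gap_policy == "eligible" or s != GAP
    ]
    sub = profile.counts[eligible]
    symbols: list[str] = []
    ties: list[frozenset[str]] = []
    for c in range(profile.length):
        col = sub[:, c]
        best = int(col.max())
        if best == 0:  # all-gap column under gap_policy="excluded"
            symbols.append(GAP)
            ties.append(frozenset({GAP}))
            continue
        winners = [alphabet[eligible[i]] for i in np.flatnonzero(col == best)]
        symbols.append(winners[0])
        ties.append(frozenset(winners) if len(winners) > 1 else frozenset())
    return ConsensusSequence("".join(symbols), tuple(ties))


def fold_residue(residue: str) -> str:
    """Public re-export of symbol folding for cell addressing."""
    return fold_symbol(residue.upper())


def parse_profile_tsv(text: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Parse the TSV emitted by ProfileMatrix/FrequencyMatrix back into arrays."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ProfileError("empty profile TSV")
    symbols: list[str] = []
    rows: list[Sequence[float]] = []
    for line in lines[1:]:
        parts = line.split("\t")
        symbols.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return tuple(symbols), np.asarray(rows)
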