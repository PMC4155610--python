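"""The residue alphabet shared by every module.

A ProfileGrid row alphabet is the 20 canonical amino acids in
alphabetical one-letter order, followed by the gap symbol ``-``.
Ambiguity codes (B, Z, J, U, O, X) are accepted on input and folded to a
single ``X`` row at profile time, so clean alignments keep exactly 21
rows while real-world inputs are not rejected.
"""

from __future__ import annotations

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
X: str = "X"

#: Ambiguity / non-canonical codes folded into the X row when counting.
AMBIGUITY_CODES: frozenset[str] = frozenset("BZJUOX")

#: The 21 fixed rows of a clean ProfileGrid.
ROW_ALPHABET: tuple[str, ...] = tuple(AA20) + (GAP,)

#: Row alphabet extended with the X row (used when ambiguity codes occur).
ROW_ALPHABET_X: tuple[str, ...] = ROW_ALPHABET + (X,)

#: Symbols legal inside a stored Alignment sequence (post-ingest).
SEQUENCE_ALPHABET: frozenset[str] = frozenset(AA20) | AMBIGUITY_CODES | {GAP}


def fold_symbol(symbol: str) -> str:
    """Map a sequence symbol onto its profile row (ambiguity codes -> X)."""
    return X if symbol in AMBIGUITY_CODES else symbol


def fold_sequence(sequence: str) -> str:
    """Fold every ambiguity code in *sequence* to X."""
    return "".join(fold_symbol(s) for s in sequence)
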