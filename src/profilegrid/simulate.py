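"""Deterministic synthetic alignment generator.

Columns are sampled independently from user-specified per-column residue
distributions — sufficient for a paradigm that consumes only column-wise
counts. The generator uses numpy's PCG64 (``default_rng``), which is
bit-reproducible across platforms for a fixed seed, so identical
(specs, n, seed) yield byte-identical FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, GAP, X
from .errors import ProfileGridError
from .msa_io import Alignment, MetadataTable

_SPEC_SYMBOLS = frozenset(AA20) | {GAP, X}


@dataclass(frozen=True)
class ColumnSpec:
    """A residue distribution for one alignment column."""

    distribution: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = 0.0
        seen: set[str] = set()
        for sym, p in self.distribution:
            if sym not in _SPEC_SYMBOLS:
                raise ProfileGridError(f"column spec symbol {sym!r} not allowed")
            if sym in seen:
                raise ProfileGridError(f"duplicate symbol {sym!r} in column spec")
            if p < 0:
                raise ProfileGridError(f"negative probability for {sym!r}")
            seen.add(sym)
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ProfileGridError(f"column spec probabilities sum to {total}, not 1")

    @classmethod
    def of(cls, dist: Mapping[str, float]) -> "ColumnSpec":
        return cls(tuple(dist.items()))

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.distribution)

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.distribution)


def _coerce_specs(specs: Sequence) -> list[ColumnSpec]:
    out = []
    for s in specs:
        out.append(s if isinstance(s, ColumnSpec) else ColumnSpec.of(s))
    return out


def generate_alignment(
    specs: Sequence,
    n: int,
    seed: int,
    id_prefix: str = "seq",
) -> Alignment:
    """Sample ``n`` sequences column-independently from per-column specs.

    Ids are ``seq0001``... (zero-padded to at least 4 digits). The same
    (specs, n, seed) always produce an identical alignment.
    """
    if n < 1:
        raise ProfileGridError("depth n must be >= 1")
    specs = _coerce_specs(specs)
    if not specs:
        raise ProfileGridError("at least one column spec is required")
    rng = np.random.default_rng(seed)
    columns = []
    for spec in specs:
        symbols = np.array(spec.symbols)
        columns.append(rng.choice(symbols, size=n, p=spec.probabilities))
    matrix = np.column_stack(columns)
    pad = max(4, len(str(n)))
    records = tuple(
        (f"{id_prefix}{i + 1:0{pad}d}", "".join(matrix[i])) for i in range(n)
    )
    return Alignment(records)


def make_subpopulations(
    base_specs: Sequence,
    overrides_per_group: Mapping[str, Mapping[int, Mapping[str, float]]],
    n_per_group: int | Mapping[str, int],
    seed: int,
    group_column: str = "group",
) -> tuple[Alignment, MetadataTable]:
    """Concatenate per-group alignments whose specs differ at chosen columns.

    ``overrides_per_group`` maps group name -> {1-based column -> residue
    distribution replacing the base spec there}. Returns the combined
    alignment (ids prefixed with the group name) plus a metadata table
    with a group column, so per-group profiles reflect their overridden
    specs and the groups can be recovered by metadata filtering.
    """
    base = _coerce_specs(base_specs)
    if len(overrides_per_group) < 2:
        raise ProfileGridError("need at least 2 groups")
    sizes: Mapping[str, int]
    if isinstance(n_per_group, int):
        sizes = {g: n_per_group for g in overrides_per_group}
    else:
        sizes = dict(n_per_group)
    records: list[tuple[str, str]] = []
    meta_rows: list[dict] = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(overrides_per_group))
    for child, (group, overrides) in zip(child_seeds, overrides_per_group.items()):
        specs = list(base)
        for col, dist in overrides.items():
            if not 1 <= col <= len(base):
                raise ProfileGridError(
                    f"override column {col} out of range 1..{len(base)}"
                )
            specs[col - 1] = ColumnSpec.of(dist)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub = generate_alignment(specs, sizes[group], sub_seed, id_prefix=f"{group}_seq")
        records.extend(sub.records)
        meta_rows.extend({"id": rid, group_column: group} for rid, _ in sub.records)
    table = MetadataTable(frame=pd.DataFrame(meta_rows), key_column="id")
    return Alignment(tuple(records)), table


def parse_column_specs(path: str | Path) -> list[ColumnSpec]:
    """Read column specs from a text file: one column per line, entries
    like ``A:0.9,N:0.1`` (comma- or whitespace-separated)."""
    specs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        dist: dict[str, float] = {}
        for token in line.replace(",", " ").split():
            if ":" not in token:
                raise ProfileGridError(
                    f"spec line {lineno}: expected SYMBOL:PROB, got {token!r}"
                )
            sym, _, prob = token.partition(":")
            dist[sym.strip().upper()] = float(prob)
        specs.append(ColumnSpec.of(dist))
    if not specs:
        raise ProfileGridError(f"no column specs found in {path}")
    return specs
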