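"""Independent brute-force reference implementations.

Deliberately naive (dict tallies, double loops, linear scans) and kept
free of any profilegrid internals beyond the public alphabet constants,
so they can arbitrate the vectorized implementations.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ROW_ORDER = list(AA20) + ["-", "X"]
AMBIG = set("BZJUOX")


def fold(symbol: str) -> str:
    return "X" if symbol.upper() in AMBIG else symbol.upper()


def naive_profile(records):
    """(symbol, 1-based column) -> count, via an explicit double loop."""
    tally: dict[tuple[str, int], int] = {}
    for _rid, seq in records:
        for col, sym in enumerate(seq, start=1):
            key = (fold(sym), col)
            tally[key] = tally.get(key, 0) + 1
    return tally


def naive_select(records, residue: str, column: int):
    return [(rid, seq) for rid, seq in records if fold(seq[column - 1]) == fold(residue)]


def naive_consensus(records, gap_policy: str = "eligible") -> str:
    tally = naive_profile(records)
    length = len(records[0][1])
    out = []
    for col in range(1, length + 1):
        candidates = [s for s in ROW_ORDER if gap_policy == "eligible" or s != "-"]
        counts = {s: tally.get((s, col), 0) for s in candidates}
        best = max(counts.values())
        if best == 0:
            out.append("-")
            continue
        out.append(next(s for s in candidates if counts[s] == best))
    return "".join(out)


def naive_diff(reference: str, highlight: str):
    return {
        (c, highlight[c - 1].upper())
        for c in range(1, len(reference) + 1)
        if reference[c - 1].upper() != highlight[c - 1].upper()
    }


def random_records(rng, n: int, length: int, gap_fraction: float = 0.15):
    """Random gapped records from a python Random instance (oracle-side PRNG)."""
    symbols = AA20 + "-" * max(1, int(round(gap_fraction * 100 / (100 / 20))))
    records = []
    for i in range(n):
        seq = "".join(rng.choice(symbols) for _ in range(length))
        records.append((f"r{i:04d}", seq))
    return records
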