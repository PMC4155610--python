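"""Row ordering, amino-acid class palettes, and the frequency color ramp.

The ramp is the paradigm's heat-map channel: white below a low cutoff
(default 10%), full color at or above a high cutoff (default 90%), a
monotone interpolation between. Rows can be ordered alphabetically, by
amino-acid class, or by a physico-chemical scale (Kyte–Doolittle
hydropathy, Zamyatnin residue volume, Vihinen flexibility, Pace–Scholtz
helix propensity); the gap row always sits last, with X after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .alphabet import AA20, GAP, ROW_ALPHABET_X, X
from .errors import StyleError

RGB = tuple[int, int, int]

WHITE: RGB = (255, 255, 255)
DARK_BLUE: RGB = (8, 48, 107)  # default high-conservation blue
BLACK: RGB = (0, 0, 0)
PINK: RGB = (255, 105, 180)  # diff-mark border

# Kyte & Doolittle hydropathy index.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Zamyatnin residue volumes (A^3).
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# Vihinen et al. average normalized B-factor flexibility index.
FLEXIBILITY = {
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906, "Q": 1.037,
    "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927, "L": 0.935, "K": 1.102,
    "M": 0.952, "F": 0.915, "P": 1.049, "S": 1.046, "T": 0.997, "W": 0.904,
    "Y": 0.929, "V": 0.931,
}

# Pace & Scholtz helix propensity (delta-delta-G, kcal/mol; Ala = 0, low = helix-favoring).
HELIX_PROPENSITY = {
    "A": 0.0, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26, "Q": 0.39, "E": 0.40,
    "I": 0.41, "W": 0.49, "S": 0.50, "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61,
    "N": 0.65, "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.0, "P": 3.16,
}

_SCALES = {
    "hydropathy": HYDROPATHY,
    "volume": VOLUME,
    "flexibility": FLEXIBILITY,
    "helix_propensity": HELIX_PROPENSITY,
}

CLASS_ORDER = ("hydrophobic", "basic", "nitrogen_containing", "acidic", "other")

DEFAULT_CLASS_MEMBERS = {
    "hydrophobic": frozenset("AVLIMFWC"),
    "basic": frozenset("KRH"),
    "nitrogen_containing": frozenset("NQ"),
    "acidic": frozenset("DE"),
    "other": frozenset("GSTYP"),
}

DEFAULT_CLASS_COLORS: dict[str, RGB] = {
    "hydrophobic": (139, 69, 19),       # brown
    "basic": (0, 0, 255),               # blue
    "nitrogen_containing": (181, 126, 220),  # lavender
    "acidic": (255, 0, 0),              # red
    "other": (0, 128, 0),               # green
    "none": (128, 128, 128),            # gap / X rows: neutral gray
}

SCHEMES = ("alphabetical", "class") + tuple(_SCALES)


@dataclass(frozen=True)
class RowOrder:
    """A named permutation of the 22-symbol row alphabet ('-' then 'X' last)."""

    scheme: str
    permutation: tuple[str, ...]

    def restrict(self, alphabet: tuple[str, ...]) -> tuple[str, ...]:
        """The permutation filtered to the rows a given profile actually has."""
        present = set(alphabet)
        return tuple(s for s in self.permutation if s in present)


@dataclass(frozen=True)
class ClassScheme:
    """Residue -> amino-acid class mapping plus per-class display colors."""

    members: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEMBERS)
    )
    colors: dict[str, RGB] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COLORS)
    )

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for cls in CLASS_ORDER:
            res = self.members.get(cls, frozenset())
            if covered & res:
                raise StyleError(f"residues assigned to multiple classes: {covered & res}")
            covered |= res
        missing = set(AA20) - covered
        if missing:
            raise StyleError(f"residues with no class: {sorted(missing)}")


def classify_residue(residue: str, scheme: Optional[ClassScheme] = None) -> str:
    """The amino-acid class of a residue; '-' and 'X' map to the neutral 'none'."""
    scheme = scheme or ClassScheme()
    residue = residue.upper()
    if residue in (GAP, X):
        return "none"
    for cls in CLASS_ORDER:
        if residue in scheme.members[cls]:
            return cls
    raise StyleError(f"unknown residue {residue!r}")


def order_rows(
    scheme: str, direction: str = "asc", class_scheme: Optional[ClassScheme] = None
) -> RowOrder:
    """Deterministic row permutation for a named ordering scheme.

    Property scales sort by value with alphabetical tie-break; the class
    scheme groups classes in the fixed order hydrophobic, basic,
    nitrogen-containing, acidic, other (alphabetical within a class).
    ``direction="desc"`` reverses the residue part; '-' and 'X' stay last.
    """
    if scheme not in SCHEMES:
        raise StyleError(f"unknown scheme {scheme!r}; valid schemes: {', '.join(SCHEMES)}")
    if direction not in ("asc", "desc"):
        raise StyleError(f"unknown direction {direction!r}")
    if scheme == "alphabetical":
        residues = sorted(AA20)
    elif scheme == "class":
        cs = class_scheme or ClassScheme()
        residues = [
            r for cls in CLASS_ORDER for r in sorted(cs.members[cls])
        ]
    else:
        scale = _SCALES[scheme]
        residues = sorted(AA20, key=lambda r: (scale[r], r))
    if direction == "desc":
        residues = residues[::-1]
    return RowOrder(scheme, tuple(residues) + (GAP, X))


@dataclass(frozen=True)
class ColorRamp:
    """Monotone frequency -> fill mapping with hard clamps at the cutoffs.

    Below ``low_cutoff`` the fill is exactly ``low_color`` (default white);
    at or above ``high_cutoff`` it is exactly ``high_color``. In between,
    continuous mode interpolates channel-wise; binned mode quantizes the
    interpolation fraction into ``bins`` equal steps (bin midpoints).
    """

    low_cutoff: float = 0.10
    high_cutoff: float = 0.90
    low_color: RGB = WHITE
    high_color: RGB = DARK_BLUE
    mode: str = "continuous"
    bins: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_cutoff < self.high_cutoff <= 1.0:
            raise StyleError(
                f"require 0 <= low_cutoff < high_cutoff <= 1, "
                f"got {self.low_cutoff}, {self.high_cutoff}"
            )
        if self.mode not in ("continuous", "binned"):
            raise StyleError(f"unknown ramp mode {self.mode!r}")
        if self.mode == "binned" and self.bins < 1:
            raise StyleError("binned ramp needs at least 1 bin")


def shade(f: float, ramp: Optional[ColorRamp] = None) -> RGB:
    """Fill color for a residue frequency ``f`` in [0, 1]."""
    ramp = ramp or ColorRamp()
    if not 0.0 <= f <= 1.0:
        raise StyleError(f"frequency {f} outside [0, 1]")
    if f < ramp.low_cutoff:
        return ramp.low_color
    if f >= ramp.high_cutoff:
        return ramp.high_color
    t = (f - ramp.low_cutoff) / (ramp.high_cutoff - ramp.low_cutoff)
    if ramp.mode == "binned":
        k = ramp.bins
        t = (min(int(t * k), k - 1) + 0.5) / k
    return tuple(
        int(round(lo + t * (hi - lo)))
        for lo, hi in zip(ramp.low_color, ramp.high_color)
    )


def luminance(color: RGB) -> float:
    """Rec. 601 luma, used to keep cell text legible on dark fills."""
    r, g, b = color
    return 0.299 * r + 0.587 * g + 0.114 * b


def hex_color(color: RGB) -> str:
    return "#{:02X}{:02X}{:02X}".format(*color)


def parse_hex(text: str) -> RGB:
    text = text.strip().lstrip("#")
    if len(text) != 6:
        raise StyleError(f"bad hex color {text!r}")
    try:
        return tuple(int(text[i : i + 2], 16) for i in (0, 2, 4))
    except ValueError:
        raise StyleError(f"bad hex color {text!r}") from None


def _parse_cutoff(text: str) -> float:
    text = text.strip()
    return float(text[:-1]) / 100.0 if text.endswith("%") else float(text)


def load_style_config(path: str | Path) -> dict:
    """Parse a key=value style config into ramp/class-scheme overrides.

    Recognized keys: ``ramp.low``, ``ramp.high`` (hex colors),
    ``ramp.low_cutoff``, ``ramp.high_cutoff`` (fractions or percentages),
    ``ramp.mode``, ``ramp.bins``, ``class.<name>`` (comma-separated
    residues), ``color.<name>`` (hex). Unknown keys are rejected.
    Returns {"ramp": ColorRamp, "class_scheme": ClassScheme}.
    """
    ramp_kw: dict = {}
    members = dict(DEFAULT_CLASS_MEMBERS)
    colors = dict(DEFAULT_CLASS_COLORS)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise StyleError(f"config line {lineno}: expected key=value, got {raw!r}")
        key, _, value = (p.strip() for p in line.partition("="))
        if key == "ramp.low":
            ramp_kw["low_color"] = parse_hex(value)
        elif key == "ramp.high":
            ramp_kw["high_color"] = parse_hex(value)
        elif key == "ramp.low_cutoff":
            ramp_kw["low_cutoff"] = _parse_cutoff(value)
        elif key == "ramp.high_cutoff":
            ramp_kw["high_cutoff"] = _parse_cutoff(value)
        elif key == "ramp.mode":
            ramp_kw["mode"] = value
        elif key == "ramp.bins":
            ramp_kw["bins"] = int(value)
        elif key.startswith("class."):
            cls = key[len("class."):]
            if cls not in CLASS_ORDER:
                raise StyleError(f"config line {lineno}: unknown class {cls!r}")
            members[cls] = frozenset(s.strip().upper() for s in value.split(",") if s.strip())
        elif key.startswith("color."):
            cls = key[len("color."):]
            if cls not in CLASS_ORDER + ("none",):
                raise StyleError(f"config line {lineno}: unknown class {cls!r}")
            colors[cls] = parse_hex(value)
        else:
            raise StyleError(f"config line {lineno}: unknown key {key!r}")
    return {
        "ramp": ColorRamp(**ramp_kw),
        "class_scheme": ClassScheme(members=members, colors=colors),
    }
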