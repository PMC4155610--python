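"""Publication-style ProfileGrid figures: SVG plus a structured sidecar.

Every rendered figure is backed by a flat list of cell records (symbol,
column, count, frequency, fill, marks, geometry) — the *sidecar* — from
which the SVG is assembled by a small deterministic writer. Two renders
of identical inputs are byte-identical, and the sidecar is the headless
test surface for everything the figure shows.

All cell rectangles share one height and all glyphs one font size: the
paradigm's legibility contract (symbols never shrink as columns grow
variable, unlike a sequence logo).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from ._version import __version__
from .errors import ProfileError
from .profile import (
    ConsensusSequence,
    FrequencyMatrix,
    ProfileMatrix,
    normalize,
)
from .query import DiffMarks, CellMask, diff_sequences
from .style import (
    PINK,
    ClassScheme,
    ColorRamp,
    RowOrder,
    classify_residue,
    hex_color,
    luminance,
    order_rows,
    shade,
)

CELL_CONTENT_MODES = ("symbol", "count", "frequency", "empty")
THRESHOLD_MARK_COLOR = (255, 140, 0)  # orange border for threshold highlights


@dataclass(frozen=True)
class GridStyle:
    """Everything that determines a rendered ProfileGrid figure."""

    cell_content: str = "symbol"
    row_order: RowOrder = field(default_factory=lambda: order_rows("alphabetical"))
    ramp: ColorRamp = field(default_factory=ColorRamp)
    class_scheme: Optional[ClassScheme] = None
    diff_marks: Optional[DiffMarks] = None
    threshold_mask: Optional[CellMask] = None
    header_rows: tuple[tuple[str, str], ...] = ()
    cell_size: int = 22
    show_column_ruler: bool = True

    def __post_init__(self) -> None:
        if self.cell_content not in CELL_CONTENT_MODES:
            raise ProfileError(
                f"unknown cell_content {self.cell_content!r}; "
                f"expected one of {CELL_CONTENT_MODES}"
            )
        if self.cell_size < 4:
            raise ProfileError("cell_size must be at least 4 px")


@dataclass(frozen=True)
class Cell:
    """One drawn matrix cell plus its geometry."""

    panel: int
    row_symbol: str
    column: int
    count: int
    frequency: float
    fill: tuple[int, int, int]
    text: str
    diff_mark: bool
    threshold_mark: bool
    x: float
    y: float
    width: float
    height: float
    font_size: float


@dataclass(frozen=True)
class GridDocument:
    """An SVG figure plus the structured table of every drawn cell."""

    svg: str
    cells: tuple[Cell, ...]
    width: float
    height: float

    def sidecar(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "panel": [c.panel for c in self.cells],
                "row_symbol": [c.row_symbol for c in self.cells],
                "column": [c.column for c in self.cells],
                "count": [c.count for c in self.cells],
                "frequency": [c.frequency for c in self.cells],
                "fill_hex": [hex_color(c.fill) for c in self.cells],
                "diff_mark": [c.diff_mark for c in self.cells],
                "threshold_mark": [c.threshold_mark for c in self.cells],
            }
        )
        if frame["panel"].nunique() <= 1:
            frame = frame.drop(columns="panel")
        return frame

    def sidecar_tsv(self) -> str:
        frame = self.sidecar().copy()
        frame["frequency"] = frame["frequency"].map(lambda v: f"{v:.10g}")
        return frame.to_csv(sep="\t", index=False, lineterminator="\n")

    def save_svg(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.svg)

    def save_sidecar(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.sidecar_tsv())


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


class _Svg:
    """Minimal deterministic SVG 1.1 assembler."""

    def __init__(self) -> None:
        self.parts: list[str] = []

    def rect(self, x, y, w, h, fill, stroke=None, stroke_width=None) -> None:
        attrs = (
            f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" '
            f'height="{_fmt(h)}" fill="{fill}"'
        )
        if stroke is not None:
            attrs += f' stroke="{stroke}" stroke-width="{_fmt(stroke_width)}"'
        self.parts.append(attrs + "/>")

    def text(self, x, y, content, size, fill="#000000", anchor="middle", bold=False) -> None:
        weight = ' font-weight="bold"' if bold else ""
        self.parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="monospace" '
            f'font-size="{_fmt(size)}" fill="{fill}" text-anchor="{anchor}"'
            f"{weight}>{_esc(content)}</text>"
        )

    def comment(self, content: str) -> None:
        self.parts.append(f"<!-- {content} -->")

    def document(self, width: float, height: float) -> str:
        body = "\n".join(self.parts)
        return (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(width)}" height="{_fmt(height)}" '
            f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
            f"{body}\n</svg>\n"
        )


def _config_hash(style: GridStyle) -> str:
    return hashlib.sha1(repr(style).encode()).hexdigest()[:12]


def _cell_text(mode: str, symbol: str, count: int, freq: float) -> str:
    """Cell glyph per content mode; zero-count cells are always blank."""
    if count == 0 or mode == "empty":
        return ""
    if mode == "symbol":
        return symbol
    if mode == "count":
        return str(count)
    # frequency mode: percentage, 0 d.p., round half-up
    return str(int(freq * 100 + 0.5))


def _text_fill(fill: tuple[int, int, int]) -> str:
    return "#000000" if luminance(fill) >= 140 else "#FFFFFF"


def _panel_cells(
    profile: ProfileMatrix,
    freqs: FrequencyMatrix,
    style: GridStyle,
    panel: int,
    x0: float,
    y0: float,
) -> list[Cell]:
    cs = float(style.cell_size)
    font = cs * 0.5
    rows = style.row_order.restrict(profile.row_alphabet)
    diff = style.diff_marks or frozenset()
    diff_cells = {(m.residue, m.column) for m in diff}
    mask = style.threshold_mask or frozenset()
    mask_cells = {(a.residue, a.column) for a in mask}
    cells: list[Cell] = []
    for r, sym in enumerate(rows):
        ri = profile.row_index(sym)
        for c in range(1, profile.length + 1):
            count = int(profile.counts[ri, c - 1])
            freq = float(freqs.freqs[ri, c - 1])
            cells.append(
                Cell(
                    panel=panel,
                    row_symbol=sym,
                    column=c,
                    count=count,
                    frequency=freq,
                    fill=shade(freq, style.ramp),
                    text=_cell_text(style.cell_content, sym, count, freq),
                    diff_mark=(sym, c) in diff_cells,
                    threshold_mark=(sym, c) in mask_cells,
                    x=x0 + (c - 1) * cs,
                    y=y0 + r * cs,
                    width=cs,
                    height=cs,
                    font_size=font,
                )
            )
    return cells


def _draw_panel(
    svg: _Svg,
    profile: ProfileMatrix,
    style: GridStyle,
    cells: Sequence[Cell],
    x0: float,
    y0: float,
    caption: Optional[str] = None,
) -> float:
    """Draw one panel (caption, ruler, header rows, grid); return its bottom y."""
    cs = float(style.cell_size)
    font = cs * 0.5
    length = profile.length
    y = y0
    if caption:
        svg.text(x0, y + font, caption, font, anchor="start", bold=True)
        y += cs
    if style.show_column_ruler:
        for c in range(1, length + 1):
            if c == 1 or c % 5 == 0:
                svg.text(x0 + (c - 0.5) * cs, y + font, str(c), font * 0.9)
        y += cs * 0.8
    for label, seq in style.header_rows:
        if len(seq) != length:
            raise ProfileError(
                f"header row {label!r} has length {len(seq)}, expected {length}"
            )
        svg.text(x0 - cs * 0.3, y + cs * 0.7, label, font, anchor="end")
        for c, sym in enumerate(seq, start=1):
            svg.text(x0 + (c - 0.5) * cs, y + cs * 0.7, sym, font, bold=True)
        y += cs
    grid_top = y
    # row labels, colored by amino-acid class when a scheme is supplied
    rows = style.row_order.restrict(profile.row_alphabet)
    for r, sym in enumerate(rows):
        color = "#000000"
        if style.class_scheme is not None:
            cls = classify_residue(sym, style.class_scheme)
            color = hex_color(style.class_scheme.colors[cls])
        svg.text(x0 - cs * 0.5, grid_top + r * cs + cs * 0.7, sym, font, fill=color)
    for cell in cells:
        svg.rect(cell.x, cell.y, cell.width, cell.height, hex_color(cell.fill),
                 stroke="#DDDDDD", stroke_width=0.5)
    # borders drawn after fills so marks sit on top
    for cell in cells:
        if cell.threshold_mark:
            svg.rect(cell.x + 1, cell.y + 1, cell.width - 2, cell.height - 2,
                     "none", stroke=hex_color(THRESHOLD_MARK_COLOR), stroke_width=2)
        if cell.diff_mark:
            svg.rect(cell.x + 1, cell.y + 1, cell.width - 2, cell.height - 2,
                     "none", stroke=hex_color(PINK), stroke_width=2)
        if cell.text:
            svg.text(cell.x + cell.width / 2, cell.y + cell.height * 0.7,
                     cell.text, cell.font_size, fill=_text_fill(cell.fill))
    return grid_top + len(rows) * cs


def render_grid(profile: ProfileMatrix, style: Optional[GridStyle] = None) -> GridDocument:
    """Render one ProfileGrid: shaded cells, optional symbols/counts, marks.

    One cell per (row symbol, column); fill follows the ramp applied to the
    cell frequency; zero-count cells get the low color and no text, making
    unobserved regions of the alignment visible at a glance.
    """
    style = style or GridStyle()
    freqs = normalize(profile)
    if style.diff_marks:
        for mark in style.diff_marks:
            if not 1 <= mark.column <= profile.length:
                raise ProfileError(f"diff mark column {mark.column} out of range")
    cs = float(style.cell_size)
    x0, y_header = cs * 1.6, cs * 0.4
    svg = _Svg()
    svg.comment(f"profilegrid {__version__} config={_config_hash(style)}")
    cells_y = y_header
    if style.show_column_ruler:
        cells_y += cs * 0.8
    cells_y += len(style.header_rows) * cs
    cells = _panel_cells(profile, freqs, style, 1, x0, cells_y)
    bottom = _draw_panel(svg, profile, style, cells, x0, y_header)
    width = x0 + profile.length * cs + cs * 0.4
    height = bottom + cs * 0.4
    return GridDocument(svg.document(width, height), tuple(cells), width, height)


def render_comparison(
    panels: Sequence[tuple[str, ProfileMatrix, ConsensusSequence]],
    style: Optional[GridStyle] = None,
) -> GridDocument:
    """Stacked subpopulation panels with cross-consensus diff borders.

    Each panel shows its own shading with two header rows: its own
    consensus (reference) and another panel's consensus (highlight), with
    pink borders at the highlight cells where the two disagree. With more
    than two panels, panel 1 is the global reference: panels 2..n diff
    against panel 1, and panel 1 diffs against panel 2.
    """
    style = style or GridStyle()
    if len(panels) < 2:
        raise ProfileError("comparison needs at least 2 panels")
    length = panels[0][1].length
    for label, profile, consensus in panels:
        if profile.length != length:
            raise ProfileError(
                f"panel {label!r} length {profile.length} != {length}"
            )
        if len(consensus.symbols) != length:
            raise ProfileError(f"panel {label!r} consensus length mismatch")
    cs = float(style.cell_size)
    x0 = cs * 1.6
    svg = _Svg()
    svg.comment(f"profilegrid {__version__} config={_config_hash(style)}")
    all_cells: list[Cell] = []
    y = cs * 0.4
    for i, (label, profile, consensus) in enumerate(panels, start=1):
        other = panels[1][2] if i == 1 else panels[0][2]
        marks = diff_sequences(consensus.symbols, other.symbols)
        panel_style = GridStyle(
            cell_content=style.cell_content,
            row_order=style.row_order,
            ramp=style.ramp,
            class_scheme=style.class_scheme,
            diff_marks=marks,
            threshold_mask=style.threshold_mask,
            header_rows=(("reference", consensus.symbols),
                         ("highlight", other.symbols)),
            cell_size=style.cell_size,
            show_column_ruler=style.show_column_ruler,
        )
        freqs = normalize(profile)
        cells_y = y + cs  # caption row
        if style.show_column_ruler:
            cells_y += cs * 0.8
        cells_y += 2 * cs  # two header rows
        cells = _panel_cells(profile, freqs, panel_style, i, x0, cells_y)
        bottom = _draw_panel(svg, profile, panel_style, cells, x0, y, caption=label)
        all_cells.extend(cells)
        y = bottom + cs
    width = x0 + length * cs + cs * 0.4
    return GridDocument(svg.document(width, y), tuple(all_cells), width, y)


def render_overview(freqs: FrequencyMatrix, max_pixels: int = 1000) -> GridDocument:
    """Symbol-free shaded matrix with the full alignment width fitted to
    ``max_pixels`` — the single-window overview of a long MSA."""
    if max_pixels < 1:
        raise ProfileError("max_pixels must be positive")
    length = freqs.length
    cs = min(20.0, max_pixels / length)
    ramp = ColorRamp()
    svg = _Svg()
    svg.comment(f"profilegrid {__version__} overview")
    cells: list[Cell] = []
    rows = order_rows("alphabetical").restrict(freqs.row_alphabet)
    for r, sym in enumerate(rows):
        ri = freqs.row_index(sym)
        for c in range(1, length + 1):
            f = float(freqs.freqs[ri, c - 1])
            fill = shade(f, ramp)
            x, y = (c - 1) * cs, r * cs
            svg.rect(x, y, cs, cs, hex_color(fill))
            cells.append(
                Cell(1, sym, c, int(round(f * freqs.depth)), f, fill, "",
                     False, False, x, y, cs, cs, cs * 0.5)
            )
    width, height = length * cs, len(rows) * cs
    return GridDocument(svg.document(width, height), tuple(cells), width, height)


def render_text(profile: ProfileMatrix, mode: str = "count") -> str:
    """The TSV twin of the figure: counts or 6-d.p. frequencies."""
    if mode == "count":
        return profile.to_tsv()
    if mode == "frequency":
        return normalize(profile).to_tsv()
    raise ProfileError(f"unknown text mode {mode!r}")
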