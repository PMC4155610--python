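"""Figure rendering: sidecar consistency, marks, legibility, determinism."""

import numpy as np
import pytest

from profilegrid import (
    GridStyle,
    ProfileError,
    build_profile,
    compute_consensus,
    diff_sequences,
    make_alignment,
    normalize,
    parse_profile_tsv,
    render_comparison,
    render_grid,
    render_overview,
    render_text,
    shade,
)
from profilegrid.style import hex_color


def cell_at(doc, symbol, column, panel=1):
    return next(
        c for c in doc.cells
        if c.row_symbol == symbol and c.column == column and c.panel == panel
    )


class TestRenderGrid:
    def test_symbol_mode_sidecar(self, toy4_profile):
        doc = render_grid(toy4_profile, GridStyle(cell_content="symbol"))
        assert len(doc.cells) == 21 * 3
        a1 = cell_at(doc, "A", 1)
        assert a1.text == "A" and a1.fill == shade(0.75)
        w1 = cell_at(doc, "W", 1)
        assert w1.text == "" and w1.fill == (255, 255, 255)

    def test_count_mode_texts(self, toy4_profile):
        doc = render_grid(toy4_profile, GridStyle(cell_content="count"))
        assert cell_at(doc, "C", 2).text == "3"
        assert cell_at(doc, "-", 2).text == "1"

    def test_frequency_mode_rounds_to_percent(self, toy4_profile):
        doc = render_grid(toy4_profile, GridStyle(cell_content="frequency"))
        assert cell_at(doc, "A", 1).text == "75"
        assert cell_at(doc, "A", 1).frequency == pytest.approx(0.75)

    def test_diff_marks_pass_through(self, toy4_profile):
        marks = diff_sequences("ACD", "ACE")
        doc = render_grid(toy4_profile, GridStyle(diff_marks=marks))
        marked = [c for c in doc.cells if c.diff_mark]
        assert len(marked) == 1
        assert (marked[0].row_symbol, marked[0].column) == ("E", 3)

    def test_sidecar_matches_matrices(self, toy4_profile, toy4_freqs):
        doc = render_grid(toy4_profile)
        for cell in doc.cells:
            assert cell.count == toy4_profile.count(cell.row_symbol, cell.column)
            assert cell.frequency == pytest.approx(
                toy4_freqs.frequency(cell.row_symbol, cell.column))
            assert cell.fill == shade(cell.frequency)

    def test_legibility_uniform_geometry(self, toy4_profile):
        doc = render_grid(toy4_profile)
        assert len({c.height for c in doc.cells}) == 1
        assert len({c.font_size for c in doc.cells}) == 1

    def test_header_row_length_checked(self, toy4_profile):
        style = GridStyle(header_rows=(("ref", "TOOLONG"),))
        with pytest.raises(ProfileError, match="header"):
            render_grid(toy4_profile, style)

    def test_svg_contains_provenance_comment(self, toy4_profile):
        doc = render_grid(toy4_profile)
        assert "<!-- profilegrid" in doc.svg and "config=" in doc.svg

    def test_determinism(self, toy4_profile):
        style = GridStyle(cell_content="count")
        a, b = render_grid(toy4_profile, style), render_grid(toy4_profile, style)
        assert a.svg == b.svg
        assert a.sidecar_tsv() == b.sidecar_tsv()


class TestRenderComparison:
    def panels(self, seq_groups):
        out = []
        for label, seqs in seq_groups:
            p = build_profile(make_alignment(
                [(f"{label}{i}", s) for i, s in enumerate(seqs)]))
            out.append((label, p, compute_consensus(p)))
        return out

    def test_one_diff_per_panel(self):
        doc = render_comparison(self.panels(
            [("neg", ["ACD", "ACD"]), ("pos", ["ACE", "ACE"])]))
        marked = [(c.panel, c.row_symbol, c.column) for c in doc.cells if c.diff_mark]
        assert sorted(marked) == [(1, "E", 3), (2, "D", 3)]

    def test_identical_panels_no_diffs(self):
        doc = render_comparison(self.panels(
            [("a", ["ACD", "ACD"]), ("b", ["ACD", "ACD"])]))
        assert not any(c.diff_mark for c in doc.cells)

    def test_three_panels_diff_against_first(self):
        doc = render_comparison(self.panels(
            [("a", ["ACD"]), ("b", ["ACE"]), ("c", ["GCD"])]))
        per_panel = {}
        for c in doc.cells:
            if c.diff_mark:
                per_panel.setdefault(c.panel, []).append((c.row_symbol, c.column))
        assert per_panel == {1: [("E", 3)], 2: [("D", 3)], 3: [("A", 1)]}

    def test_length_mismatch_rejected(self):
        panels = self.panels([("a", ["ACD"]), ("b", ["AC"])])
        with pytest.raises(ProfileError, match="length"):
            render_comparison(panels)

    def test_single_panel_rejected(self):
        with pytest.raises(ProfileError, match="2 panels"):
            render_comparison(self.panels([("a", ["ACD"])]))


class TestRenderOverview:
    def test_width_bounded_and_all_columns_present(self):
        aln = make_alignment([("s1", "ACDEF" * 100)])
        doc = render_overview(normalize(build_profile(aln)), max_pixels=1000)
        assert doc.width <= 1000
        assert {c.column for c in doc.cells} == set(range(1, 501))

    def test_fills_match_empty_content_grid(self, toy4_profile, toy4_freqs):
        overview = render_overview(toy4_freqs, max_pixels=500)
        grid = render_grid(toy4_profile, GridStyle(cell_content="empty"))
        fills_o = {(c.row_symbol, c.column): c.fill for c in overview.cells}
        fills_g = {(c.row_symbol, c.column): c.fill for c in grid.cells}
        assert fills_o == fills_g
        assert not any(c.text for c in overview.cells)

    def test_single_column(self):
        doc = render_overview(normalize(build_profile(make_alignment([("s", "M")]))))
        assert {c.column for c in doc.cells} == {1}


class TestRenderText:
    def test_count_round_trip(self, toy4_profile):
        symbols, counts = parse_profile_tsv(render_text(toy4_profile, "count"))
        assert symbols == toy4_profile.row_alphabet
        assert np.array_equal(counts, toy4_profile.counts)

    def test_frequency_mode(self, toy4_profile, toy4_freqs):
        symbols, freqs = parse_profile_tsv(render_text(toy4_profile, "frequency"))
        assert np.allclose(freqs, toy4_freqs.freqs, atol=5e-7)

    def test_unknown_mode(self, toy4_profile):
        with pytest.raises(ProfileError):
            render_text(toy4_profile, "logo")
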