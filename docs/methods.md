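# Methods

## The model

A ProfileGrid is a lossless column-wise summary of a protein MSA. Let the
alignment have depth *N* and length *L*. The count matrix has a fixed row
alphabet: the 20 canonical amino acids in alphabetical one-letter order,
then the gap symbol `-`. Each cell holds *k(r, c)*, the number of sequences
whose symbol at column *c* is *r*; because the gap row participates, columns
always sum to *N*, and the frequency matrix *f = k/N* has unit column sums.
Depth enters only through the normalization, so alignments of any size
reduce to the same 21 × *L* surface — the paradigm's answer to the scaling
problem of stacked-sequence and logo displays.

Ambiguity codes (B, Z, J, U, O, X) are accepted on input and folded into a
single `X` row when counting; the `X` row is materialized only when its
total count is nonzero, so clean alignments keep exactly 21 rows. The `.`
character is treated as a gap synonym on ingest and lower case is folded to
upper. These are ingest-time conventions: the stored alignment preserves the
(folded) sequences verbatim, and record order is never re-sorted, since
reference/highlight selection is by id or position.

## Consensus

The consensus is the per-column **plurality** symbol (argmax of counts),
not a strict >50% majority — no threshold parameter exists in this
formulation. Two policies control gap candidacy: `eligible` (default) lets
the gap row win a column, which is informative when a column is mostly
gapped; `excluded` removes it, and a column with no residue observations
then yields `-` flagged with a singleton tie entry. Ties are broken toward
the earlier row-alphabet symbol (residues alphabetically, then `-`, then
`X`) and every tied column is recorded in the result, so the deterministic
choice is always auditable.

## Queries, thresholds, diffs, metadata

`select_cell` scans the alignment for records whose folded symbol at the
cell's column equals the cell's residue; by construction its result depth
equals the matrix count, which is the package's central internal-consistency
invariant (tested exhaustively). A zero-count cell returns an empty result
rather than an error so that the per-column results of all rows always
partition the alignment.

`highlight_by_threshold` applies one of `ge/gt/le/lt` against a frequency
cutoff. Zero-frequency cells are never returned by any operator: absence is
already encoded by the white shade, and marking the (typically vast)
zero region would invert the figure's emphasis.

`diff_sequences` compares two equal-length gapped strings after case
folding; the gap is an ordinary symbol. Each mark stores the 1-based column
and the highlight symbol — the cell that receives the pink border.

Metadata filtering uses a TSV/CSV table keyed by sequence id. Sequences
absent from the table match no predicate (including `not_equals`): filters
fail safe rather than silently admitting unannotated records.

## Color ramp and row orderings

The ramp maps frequency to fill with hard clamps: exactly the low color
(white) below `low_cutoff` (default 0.10) and exactly the high color
(default dark blue `#08306B`) at or above `high_cutoff` (default 0.90).
Between the cutoffs, continuous mode interpolates channel-wise on
*(f − low)/(high − low)*; binned mode quantizes that fraction into *k*
equal bins and uses bin midpoints. Both are monotone non-increasing in
luminance for dark-on-light ramps. A grayscale figure is the same operator
with a black high color — there is no second code path. The exact dark blue
is configurable (`ramp.high` in the style config); no canonical RGB exists
for it, so the default is a conventional dark blue.

Row orderings are deterministic permutations of the 22-symbol alphabet with
`-` and `X` pinned last. Property-based schemes sort by bundled literature
scales — Kyte–Doolittle hydropathy, Zamyatnin residue volumes (Å³), Vihinen
normalized-B-factor flexibility, Pace–Scholtz helix propensity (ΔΔG,
kcal/mol) — with alphabetical tie-breaks. The class ordering groups
hydrophobic {A,V,L,I,M,F,W,C}, basic {K,R,H}, nitrogen-containing {N,Q},
acidic {D,E}, other {G,S,T,Y,P}, in that fixed order. Class membership for
borderline residues (H, C, Y) is genuinely conventional; the defaults above
are a documented choice and every membership and color is overridable via
the `class.<name>` / `color.<name>` config keys. `-` and `X` map to a
reserved neutral class.

## Rendering

Figures are SVG 1.1 assembled by a small deterministic writer; every drawn
cell is also recorded in a structured sidecar (symbol, column, count,
frequency, fill, diff/threshold marks), which is the headless test surface
and is exported as TSV. Two renders of identical inputs are byte-identical;
each SVG embeds a comment with the package version and a hash of the
resolved style for provenance.

All cell rectangles share one height and all glyphs one font size — the
legibility contract that distinguishes the grid from logo-style displays.
Zero-count cells are drawn in the low color with no text in every
cell-content mode: blanking zero counts as well as zero symbols keeps
unobserved regions visually empty.
Frequency-mode cell text is a percentage rounded half-up to 0 decimals; the
sidecar keeps full precision. The column ruler labels column 1 and every
5th column. Diff marks are 2 px pink borders, threshold marks 2 px orange.

Multi-panel comparison stacks one grid per subpopulation, each headed by
its own consensus (reference) and another panel's consensus (highlight)
with diff borders between them. With more than two panels, panel 1 is the
global reference: panels 2..n diff against panel 1, and panel 1 against
panel 2. Overview mode renders the same fills symbol-free with the cell
size scaled so the full width fits a pixel budget.

Output is SVG + sidecar TSV only. Rasterization would have to be a second
drawing path or an external converter, so it is deliberately not part of
the package; any SVG renderer reproduces the figure.

## Synthetic data generator

The generator samples each column independently from a user-specified
residue distribution, using numpy's PCG64 (`default_rng`) so a fixed
(specs, depth, seed) triple is bit-reproducible across platforms.
`make_subpopulations` concatenates per-group alignments whose specs differ
at chosen columns and emits the matching metadata table, emulating the
situations the paradigm is built for: a rare residue hiding in a conserved
column (a ~0.2% planted probability at depth 1000 yields the handful of
hits a cell query must recover exactly) and a column where two
subpopulations favor different residues (the consensus-diff workflow).

What it does **not** emulate: phylogenetic correlation between sequences,
indel structure, or realistic substitution processes. The paradigm consumes
only column-wise counts, so column independence is sufficient for every
contract tested here; passing tests demonstrate the counting, querying and
rendering machinery, not biological realism of the fixtures.

## Problem sizes and numerics

The test suite runs at small scale (alignments up to 500 × 100 for
conservation sweeps, 50 × 50 for brute-force oracle comparisons, depth
1000–2000 for empirical-frequency checks); the acceptance script runs the
full workflow at 1809 × 36 — the scale of the bacterial adenylate-kinase
lid-domain alignments that motivated the design — in about a second.
Frequency column sums are checked to 1e-9; empirical frequencies from the
generator are checked against a ±0.03 band at n = 2000 (≈ 4.5σ for a 0.9
binomial proportion). Counts are exact int64 throughout; the only floating
arithmetic is the single division by depth and the ramp interpolation.

## Known limitations

- No sequence weighting, pseudocounts, or information-content statistics:
  the surface is raw counts and frequencies by design.
- Stockholm/PHYLIP/NEXUS input, alignment construction, and interactive
  viewing are out of scope; inputs are aligned FASTA or Clustal.
- Strict-majority (>50%) consensus is not offered; plurality only.
- The comparison layout's panel geometry is aesthetic and untested; the
  sidecar, not the pixel layout, is the contract.
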