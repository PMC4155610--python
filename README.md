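# profilegrid

ProfileGrid visualizations of protein multiple sequence alignments.

A multiple sequence alignment (MSA) of *N* homologous protein sequences and
*L* columns is reduced to a **residue-frequency matrix**: for every column
*c* and every symbol *r* in a fixed 21-row alphabet (the 20 canonical amino
acids in alphabetical order, plus the gap symbol `-`), the count

&nbsp;&nbsp;&nbsp;&nbsp;*k(r, c)* = number of sequences with symbol *r* at column *c*,
&nbsp;&nbsp;&nbsp;&nbsp;*f(r, c)* = *k(r, c)* / *N*.

The gap row absorbs gaps, so every column of counts sums to *N* and every
column of frequencies to 1. The matrix is rendered as a grid whose cells are
shaded by a monotone color ramp — exactly white below 10% frequency, full
color (dark blue by default) at ≥ 90% — with fixed-height residue symbols or
integer counts in the cells. Unlike a sequence logo, every symbol stays
legible regardless of alignment depth or column variability, gap
conservation is shown explicitly, and unobserved residues are visible as
white cells.

On top of the matrix the package provides:

- **Consensus sequences** — per-column plurality symbol, with explicit tie
  records and a choice of whether the gap row may win a column.
- **Subpopulation comparison** — stacked panels, one per group, each headed
  by its own consensus (reference) and the other group's consensus
  (highlight); columns where they disagree get a pink cell border.
- **Cell queries** — the MSA as a searchable database: retrieve exactly the
  sequences carrying residue *r* at column *c* (the result depth always
  equals *k(r, c)*).
- **Threshold highlighting** — flag cells with frequency above/below a
  user-defined cutoff.
- **Metadata filtering** — subset the alignment by a TSV/CSV annotation
  table keyed by sequence id.
- **Row orderings** — alphabetical, by amino-acid class
  (hydrophobic/basic/nitrogen-containing/acidic/other), or by
  physico-chemical scale (Kyte–Doolittle hydropathy, Zamyatnin volume,
  Vihinen flexibility, Pace–Scholtz helix propensity).
- **A deterministic synthetic-alignment generator** for testing and demos.

Intended users: molecular biologists and bioinformaticians dissecting
conservation patterns in large protein families, and anyone who needs
publication-style conservation figures from aligned FASTA/Clustal input
without a GUI.

## Worked example

With `toy.fasta` containing four aligned records (`s1:ACD`, `s2:ACD`,
`s3:A-E`, `s4:GCD`):

```sh
$ profilegrid build toy.fasta --out toy_counts.tsv
wrote 21x3 count matrix for 4 sequences to toy_counts.tsv

$ head -5 toy_counts.tsv
residue 1       2       3
A       3       0       0
C       0       3       0
D       0       0       3
E       0       0       1
```

Three of the four sequences carry A at column 1, C at column 2, D at
column 3; the counts in every column sum to the depth 4 (the gap in `s3`
is tallied in the `-` row at column 2).

```sh
$ profilegrid consensus toy.fasta
>consensus gap_policy=eligible
ACD

$ profilegrid query toy.fasta E 3 --out hits.fasta
1 sequences match E@3
wrote hits.fasta
```

The plurality consensus is `ACD`, and the cell query at (E, 3) retrieves
exactly the one sequence (`s3`) behind that count — the matrix cell and the
query result always agree.

```sh
$ profilegrid render toy.fasta --out toy.svg --reference s1 --highlight s3
wrote toy.svg and toy.tsv

$ head -3 toy.tsv
row_symbol      column  count   frequency       fill_hex        diff_mark       threshold_mark
A       1       3       0.75    #365787 False   False
A       2       0       0       #FFFFFF False   False
```

The SVG shows the shaded grid with `s1` and `s3` as header rows and pink
diff borders at columns 2 and 3 where they differ; the sidecar TSV records
every drawn cell (count, frequency, fill color, marks) for downstream use.
The cell (A, 1) at frequency 0.75 falls between the 10%/90% cutoffs and is
interpolated to `#365787`; the zero cells are exactly white.

The same operations are available as a library (`profilegrid.build_profile`,
`normalize`, `compute_consensus`, `select_cell`, `render_grid`, ...), and the
CLI is a thin shell over them.

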