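# admixring

Circular stacked-bar plots of ancestry composition for population genetics.

Model-based ancestry inference (ADMIXTURE, structure, frappe) assigns every
individual a vector of K proportions — the fraction of its genome attributed
to each of K ancestral source populations — with the proportions summing to
one. The conventional display is a rectangular plot of stacked bars, which
stops fitting on a page once a study spans hundreds of populations or
thousands of individuals. `admixring` draws the same information on a circle:
each individual is a fixed-length radial bar partitioned into K colored
segments, every population receives the same angular span regardless of its
sample size, and a population of interest can be highlighted as a pie chart
at the center showing its mean ancestry composition.

It is aimed at anyone who has a `.Q` matrix (one row per individual, K
whitespace-separated proportions) and a row-aligned label file (individual ID
in the first column, population label in the last) and wants a
publication-ready figure plus reproducible text outputs.

## The sorting rule

The display order is computed from the data. For a population *p* with mean
ancestry vector *q̄ₚ*, its **representative ancestry** is

> rep(p) = argmax₍ₐ₎ q̄ₚ[a]   (ties to the lowest ancestry index)

Populations are bucketed into K groups by rep(p); groups are placed around
the circle in ascending ancestry-column order; within a group populations are
sorted by q̄ₚ[rep(p)] descending; and individuals within a population are
sorted by their own proportion of the population's representative ancestry,
descending. Each population's angular span is exactly 360°/P, each of its
n individuals gets a wedge of (360°/P)/n, and each bar's K radial segments
have lengths proportional to that individual's proportion vector. Pie slices
for a target population are 360° × its mean proportions.

## Worked example

No external data is needed — the package ships a synthetic generator that
draws each population's center from a flat Dirichlet on the K-simplex and its
individuals from a Dirichlet concentrated around that center:

```bash
python examples/01_sorted_ring.py
```

prints

```
34 individuals, 6 populations, K=4

population   rep. ancestry  mean prop.  members
Pop002                   1       0.495        7
Pop005                   2       0.515        5
Pop004                   2       0.347        5
Pop001                   3       0.482        3
Pop003                   3       0.431        6
Pop006                   4       0.470        8
```

Reading the table: populations appear in final ring order. Pop002's largest
mean ancestry component is column 1 (49.5% of its genome on average), so it
leads the block for ancestry 1; Pop005 and Pop004 both have ancestry 2 as
their representative and are ordered by its mean proportion (0.515 before
0.347); and so on through ancestry 4. `examples/02_layout_and_center_pie.py`
shows the resulting equal 72° spans and the center-pie angles, and
`examples/03_render_figure.py` runs the full pipeline to an SVG figure plus
its companion text outputs.

The same pipeline is available from the shell:

```bash
admixring synth --pops 10 -k 5 --seed 1 -o demo        # writes demo.Q, demo.ind
admixring plot -i demo.ind -q demo.Q -t Pop003 -o fig  # figure + text outputs
```

`admixring plot` writes four files: the figure (`.pdf`/`.png`/`.svg`), a
deterministic plain-text description of every drawn primitive
(`.plotspec.txt`), the color scheme used (`.colors.txt`, reusable as input
via `--colors`), and the ancestry table in final plotting order
(`.sorted.tsv`). Omitting `-t` draws the ring without a center pie;
`--order`, `--exclude`, `--no-lines` and the geometry flags adjust the
display.

## Scope

Ancestry inference itself is out of scope: this package consumes the output
of inference tools, it does not estimate proportions. Multi-K displays
(concentric rings for several values of K) are not implemented.
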