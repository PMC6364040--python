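# Methods

## Inputs and their dialects

The package consumes two row-aligned files. The `.Q` matrix is plain
whitespace-separated text, one row per individual, K ≥ 2 numeric columns, no
header and no IDs — the dialect ADMIXTURE emits. Blank lines are skipped.
The label file follows the `.ind` convention: the first column is the
individual ID, the last column the population label, and any middle columns
(such as the EIGENSTRAT sex column) are ignored; a minimal two-column file
works too. The label-file schema is a documented assumption — the convention
around these files fixes only "ID plus group identifier", so the
first/last-column rule was chosen to accept both common layouts.

Rows must sum to one. Real inference output carries per-entry rounding error
of about 1e-6, so the default acceptance band on |row sum − 1| is 1e-4; an
opt-in `renormalize` flag divides each row by its sum instead, after which
sums are 1 to machine precision. Negative entries and ragged rows are always
errors, reported with 1-based file line numbers. Indices are 0-based
internally; everything human-facing (color-scheme files, log messages) uses
1-based ancestry columns to match how Q-file columns are usually discussed.

Text outputs echo the input tokens verbatim when a row came from a file and
was not renormalized; otherwise values are written with shortest round-trip
float formatting. That makes parse∘serialize the identity on valid files and
keeps the sorted table exact, rather than truncating to a fixed decimal
count.

## Sorting

A population's representative ancestry is the argmax of its mean proportion
vector. The display algorithm buckets populations by representative
ancestry, walks the buckets in ascending ancestry-column index, sorts each
bucket by representative mean proportion descending, and sorts individuals
within a population by the *population's* representative column, descending.

Three tie-break rules make the order a pure function of values and labels:
argmax ties resolve to the lowest ancestry index, equal population
proportions resolve by label lexicographically, and equal individual
proportions keep original file order. Two genuinely open choices were fixed
here: (1) "its representative ancestry" for individual sorting is read as
the population's representative column, not each individual's own argmax —
this keeps a population's bars visually monotone in one color; (2) the K
buckets are arranged by ancestry-column index, the only canonical order the
input provides. A user-supplied order file overrides the automatic sequence
entirely (populations not listed are omitted), and an exclusion list drops
populations before any sorting; both reject unknown or duplicated labels.

## Geometry

The ring allocates exactly 360/P degrees to each of the P displayed
populations, independent of sample size, so the figure's perimeter and
radius never grow with the data. Within a population of n individuals each
wedge is (360/P)/n wide. A bar runs from `inner_radius` 0.45 to
`outer_radius` 1.0 (relative units; labels at 1.04, pie radius 0.40 — all
configurable), and its K radial segments are stacked ancestry 0 innermost
with lengths proportional to the individual's proportion vector, so segment
fractions reproduce the row exactly.

Angles start at 90° (top of the circle) and wind clockwise by default; both
are configurable. Internally angles are kept *unwrapped* along the winding
direction, which keeps widths exact under float arithmetic; label anchors
are normalized into [0, 360). Labels sit at the angular midpoint of each
span, rotated radially; anchors on the left half-circle (90°–270°) are
flipped 180° with the text anchor swapped so they read outward. Separator
lines between populations are zero-width radial strokes and can be disabled
for very large P.

The center pie for a target population uses the population *mean* across its
members — for a single-individual target that reduces to the individual's
own vector. Slice angles are 360° × mean proportion, emitted in
ancestry-index order from the start angle. The highlighted target stays in
the ring by default and is additionally shown as the pie; a flag removes it
from the ring instead.

## Rendering and the PlotSpec

Every figure is generated from a canonical textual PlotSpec listing each
drawn primitive — annular sector, separator line, label, pie slice — with
coordinates rounded to six decimals and hex fill colors, in a fixed order.
The PlotSpec is byte-identical across runs on identical inputs and is the
surface golden-file and determinism tests compare; the figure (PDF, PNG or
SVG via matplotlib, square 10×10-unit canvas, default 300 dpi) is drawn from
the same layout. Zero-proportion segments are skipped rather than drawn with
zero extent, avoiding renderer artifacts; consequently the sector count
equals Σₚ nₚ×K only when all proportions are nonzero. Rendering never
mutates the layout (all geometry types are frozen).

The default palette is deterministic in K: a fixed 12-color curated
categorical list, extended for K > 12 by evenly spaced hue rotation in HSV
space, with a distinctness check. A user scheme file (one `index TAB
#RRGGBB` line per ancestry, 1-based) must carry exactly K entries.

## Synthetic data

The generator emulates the statistical shape of inference output: each
population receives a center drawn from a flat Dirichlet on the K-simplex,
and its individuals are Dirichlet draws with parameter `concentration ×
center`. The default concentration of 30 gives within-population standard
deviations of a few percent — visually similar to real cohort output —
while very large values collapse a population onto its center (per-coordinate
standard deviation ≤ √(0.25/concentration)). After sampling, each row is
renormalized and its largest entry pinned to 1 minus the float sum of the
rest, so written files reparse with row sums within 1e-12. Population sizes
are drawn uniformly from a configurable range, or a pinned total can be
spread as evenly as possible across populations (used for the
survey-scale determinism check: 203 populations, 2345 individuals, K = 8).

What the generator does not emulate: linkage between ancestry components
across individuals, inference noise correlated with sample size, label
errors, or multimodal populations. Tests passing on synthetic data therefore
establish the correctness of sorting, geometry and I/O contracts, not the
behaviour of any inference method.

## Verification sizes and numerical choices

The test suite fuzzes the ordering pipeline against a brute-force reference
(plain loops, written independently of the implementation) on 1000 random
datasets with N ≤ 50, K ≤ 6 and up to 10 populations, and checks
angular-space conservation on 500 random layouts with population sizes up to
30 — sizes at which the brute-force reference is trivially trustworthy while
still exercising every tie-break. Geometry tolerances are 1e-9 on spans and
bar partitions and 1e-6 on the 360° totals; one layout test cross-checks
wedge boundaries against exact rational arithmetic (`fractions.Fraction`).
Determinism is asserted at the byte level on the survey-scale dataset.

## Limitations

Labels can collide for very large P (no dodging beyond the flip rule);
per-individual labels are not drawn; multiple-K concentric rings are not
supported; ancestry columns from different inference runs are not matched.
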