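# Methods

## What the tool computes

`metapaint` is a painting layer over a metabolic network model: it converts
numeric omics tables into per-entity, per-frame SVG presentation attributes
on an automatically laid-out whole-metabolism diagram. The computation is a
pipeline of pure steps — parse → preprocess → resolve → bin → style → emit —
each exposed as a library function and each deterministic given its inputs.

## Network model

A network is three keyed collections (compounds, reactions, pathways) plus
derived indexes: gene → reactions catalyzed, and case-folded
id/name/synonym → compound. Indexes are always the closure of the stored
records (`reindex()` rebuilds them; reconciliation writes pathway membership
back onto reactions, so a reaction in no pathway is discoverable as an
orphan). SBML input maps species → compounds (boundary species retained so
currency metabolites stay paintable), `fbc` gene-product associations →
gene ids, and `groups` whose members are reactions → pathways. SBML carries
no pathway taxonomy, so SBML-derived pathways are categorized "other"; the
flat format carries an explicit `category/sub-category` path whose first
element must be `biosynthesis`, `degradation`, `energy`, or `other`.

Token resolution is case-insensitive exact matching — primary ids first,
then names/synonyms — never fuzzy. A token that could name both a gene and a
compound is disambiguated solely by the dataset's declared data type; the
resolver never guesses. Unmatched tokens are counted and warned about, never
fatal: real exports always contain ids the model lacks.

## Experiment model and file dialect

An experiment holds 1–4 datasets, each typed (`gene`/`protein`/`reaction`
target edges; `compound` targets nodes) and bound to a unique visual channel.
The on-disk dialect is this package's own line-oriented format:
`!NUM-DATASETS`, per-dataset `!DATASET id/label/type/channel/columns/signed`
(+ a trailing file name in the master form), optional `!COLUMNS` time-point
labels, and `>DATASET` sections of `token<TAB>values` rows. Missing cells
(empty, `NA`, `NaN`) stay missing end to end — a missing cell paints the
missing style, it is never coerced to zero. Duplicate tokens are kept as
separate rows (replicates are data); aggregation happens at resolution time.

Frame count = the widest dataset after column selection; narrower datasets
hold their last column through later frames. This is what keeps a
single-time-point metabolomics layer static under an animating five-point
transcriptome.

Preprocessing transforms: log2 fold change versus a reference column (the
reference is dropped, so *n* time points yield *n − 1* columns; missing or
zero references, and nonpositive ratios under log2, produce missing cells
with a warning) and essentiality = 1 − normalized knockout growth yield
(values outside [0, 1] transform anyway, with a warning).

## Value-to-style mapping

Breakpoints are `k + 1` strictly increasing boundaries. Defaults: `k = 5`;
signed data spans `[-M, M]` with `M = max|x|` (all-zero data falls back to
`[-1, 1]`); unsigned data spans `[min(0, min x), max x]`. Bins are half-open
`[b_i, b_{i+1})` with the top boundary folded into the last bin and
out-of-range values clamped into the end bins — clamping rather than
erroring is deliberate, because dragging a breakpoint legitimately pushes
data outside the painted range, and the histogram must still conserve
(`sum(bins) + missing = total`).

Colors are discrete per bin (the legend is drawn as countable regions), not
interpolated per value. Four palettes ship (green-red and blue-red
diverging, white-red and white-blue sequential); scales of any `k` are built
by linear RGB interpolation across a palette's anchors. Thickness is the
linear map of `[b_0, b_k]` onto `[min_px, max_px]` (default 1–10 px),
clamped, with missing → `min_px`; it is monotone nondecreasing by
construction.

Dragging boundary `i` to `v` rescales the left boundaries affinely within
`[b_0, v]` and the right ones within `[v, b_k]`:
`b'_j = b_0 + (b_j − b_0)/(b_i − b_0) · (v − b_0)` on the left, mirrored on
the right. This preserves bin count, the outer range, and strict ordering
for any interior `v`, and matches the intuition that the adjacent extreme
region grows while all others shrink proportionally.

Multiple rows resolving to one entity combine per frame by `max_magnitude`
(largest |value|, first occurrence winning ties; missing ignored, all-missing
stays missing). This default surfaces the strongest signal on multi-gene
reactions; `mean` and `first` are available where a neutral or positional
policy fits better. Popup charts deliberately bypass aggregation and plot
each contributing row separately, because the interesting question at the
single-reaction level is usually *which* isozyme moved.

## Layout

The layout is a deliberate simplification that honors the field's drawing
conventions rather than reproducing any published pathway-layout algorithm:
the contribution here is the painting layer, which only needs a
deterministic, convention-respecting canvas.

* Pathway reactions are ordered by substrate→product chaining (Kahn's
  algorithm, stored order as tie-break, cycles broken by releasing the
  earliest-stored remaining reaction) and placed at strictly increasing `y`
  ("pathways flow downwards"; origin top-left, `y` down, SVG convention).
* The main substrate/product of each reaction becomes a chain node drawn
  once; all other participants — currency metabolites (configurable list:
  ATP/ADP/AMP, NAD(P)(H), water, phosphate, PPi, protons, CO2) and
  co-substrates — become small side nodes, keeping flows legible while
  keeping every participating compound paintable.
* Pathways are shelf-packed (tallest first, deterministic key tie-break,
  column height target 520 units) into side regions: biosynthesis left,
  energy/other center, degradation right; orphan reactions are gridded
  alphabetically in a far-right zone; a membrane polyline frames everything.
* Node shapes: triangle = amino acid, square = carbohydrate, diamond =
  nucleotide, circle otherwise; shading = phosphorylated.
* Zoom tiers 0–3 (membrane/regions → + pathway names → + shapes and edges →
  names replacing shapes, gene labels). Default scale thresholds
  {0.25, 1.0, 3.0} are a configuration choice, exposed on the diagram.

Diagrams serialize to JSON so painting can rerun without re-layout.

## Rendering

Frames are emitted as standalone SVG documents plus a JSON index, not as
SMIL/scripted animation: identical geometry with only presentation
attributes differing is directly assertable and viewer-agnostic. Element ids
are sanitized network ids; duplicate visual occurrences of one reaction get
an `__n` suffix while sharing a `data-ref` attribute that styling and tests
key on. `<title>` children carry the tooltip text. At tier 3 compound shapes
are replaced by name texts whose fill is the node's omics color. Popup
markers embed their exact stored values in `data-value` attributes, so the
plotted numbers round-trip losslessly out of the document.

## Fixture generator

The generator emulates the shape of two real study designs, not their
biology: `abaylyi-like` (three one-column datasets — a signed expression
contrast on edge color, uniform [0, 1] knockout growth yields on edge
thickness awaiting the essentiality transform, signed metabolite scores on
node color) and `synechocystis-like` (lognormal transcript and protein
abundances over five time points labeled 1 h, 3 h, 11.75 h, 13 h, 15 h, plus
a one-column metabolomics score list; a few percent missing cells). Networks
are linear chains with 1–3 genes per reaction, alternating
biosynthesis/degradation categories, plus orphan reactions. Everything runs
off one `random.Random(seed)`, so equal seeds give byte-identical files.

What the fixtures do *not* emulate: branched and cyclic pathway topologies at
realistic frequency, shared intermediates across pathways, correlated
omics layers, heavy-tailed replicate structure, or real identifier messiness
beyond a configurable unmatched-token fraction. Passing tests therefore
demonstrate the mechanics (parsing, binning, layout invariants, style
fidelity, determinism) rather than biological fidelity of any painted
diagram.

## Problem sizes and numerical choices

The test and acceptance runs use toy networks (tens of reactions) for
behavioral checks, generated networks up to 500 reactions for layout
invariants, and one large run — 3 209 reactions, two 3 209-row flux datasets
and two 1 796-row metabolite datasets × 20 columns — to demonstrate
organism-scale painting; these sizes were chosen to exercise every code path
at a scale a single organism's metabolism actually reaches. Float handling:
values are compared and binned as plain doubles; serialized numbers use
repr-shortest decimals (bit-exact numeric text round-trip is not a goal,
value round-trip is). Degenerate inputs are defined, not crashed on:
all-missing columns refuse breakpoint derivation with a clear error, empty
pathways lay out to nothing with a warning, an empty network renders as a
membrane-only document.

## Known limitations

* The layout does not reproduce any published organism chart; region
  placement, shelf packing, and chain glyphs are this package's own design.
* One reaction drawn in several pathways carries one value everywhere; there
  is no per-context painting.
* No statistical normalization is applied — values are painted as given.
* Interactivity (live dragging, mouse-wheel zoom) lives in the viewer of the
  emitted SVG; this package emits documents and recomputes on request.
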