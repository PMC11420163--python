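# metapaint

Paint multi-omics data onto an organism-scale metabolic network diagram.

Systems biologists comparing transcriptomics, proteomics, metabolomics,
reaction-flux or gene-essentiality measurements need to see *where in
metabolism* things change. `metapaint` draws a whole-metabolism chart —
pathways as downward-flowing chains of metabolite nodes joined by reaction
edges, biosynthesis on the left, degradation on the right, pathway-free
reactions in their own zone, all inside a cell-membrane border — and overlays
up to four single-omics datasets on four independent **visual channels**:

| channel          | paints                | typical dataset        |
|------------------|-----------------------|------------------------|
| `edge_color`     | reaction edge color   | transcriptomics        |
| `edge_thickness` | reaction edge width   | proteomics, essentiality |
| `node_color`     | metabolite node fill  | metabolomics           |
| `node_thickness` | metabolite node outline width | a second metabolomics technology |

## The mapping model

Each channel owns a set of **breakpoints** `b_0 < b_1 < … < b_k` partitioning
the data range into `k` bins. Color channels bind one color per bin (default:
5 bins of a green→red diverging scale; for signed data such as log2 fold
changes the range is symmetric, `[-M, M]` with `M = max|x|`, so the neutral
color sits on zero). Thickness channels map `[b_0, b_k]` linearly onto a
stroke-width range (default 1–10 px). Values below `b_0` or above `b_k` clamp
into the extreme bins; a value on an interior boundary falls in the upper bin
(half-open convention `[b_i, b_{i+1})`). An interior boundary can be dragged
to a new position; the boundaries on each side rescale affinely within
`[b_0, new]` and `[new, b_k]`, so dragging `[-4,-2,0,2,4]`'s middle boundary
to 1 gives `[-4, -1.5, 1, 2.5, 4]`. A histogram legend reports how many data
points land in each bin.

Gene/protein rows resolve (case-insensitively, ids before names/synonyms) to
every reaction the gene catalyzes; several rows landing on one entity combine
by largest absolute magnitude by default. Multi-column datasets become
animation frames; narrower datasets hold their last column, so a one-shot
metabolomics layer stays constant while a five-time-point transcriptome
animates. Semantic zoom tiers (0–3) add pathway names, node shapes
(triangle = amino acid, square = carbohydrate, diamond = nucleotide, shading
= phosphorylated) and finally replace shapes with metabolite names colored by
their omics value.

Two preprocessing transforms ship with the tool: **log2 fold change** against
a reference time-point column (five time points → four fold-change columns)
and **essentiality** = 1 − normalized knockout growth yield.

## Worked example

```sh
metapaint synth --preset synechocystis-like --seed 1 --out demo
metapaint transform --omics demo/experiment.tsv --fold-change --reference 1 \
    --dataset tx --dataset prot --out demo/fc.tsv
metapaint validate --network demo/network.tsv --omics demo/fc.tsv
metapaint paint --network demo/network.tsv --omics demo/fc.tsv --tier 3 --out demo/frames
```

The `validate` step prints:

```
network OK: 28 compounds, 20 reactions, 4 pathways, 4 orphans
omics OK: 3 datasets, 4 frames
```

i.e. the generated light-to-dark time-course fixture has 4 pathways plus 4
pathway-free reactions, and after fold-change preprocessing (5 raw time
points at 1 h, 3 h, 11.75 h, 13 h, 15 h, referenced to 1 h) the experiment
animates over 4 frames. `paint` then writes `frame_000.svg` … `frame_003.svg`
(one painted diagram per fold-change time point, geometry identical, only
colors and stroke widths differing), `legend.svg` (the 5-bin histogram for
the first dataset's channel) and `index.json` labeling the frames
`3 h, 11.75 h, 13 h, 15 h`. `metapaint popup rxn0001 …` graphs every
contributing gene's transcript and protein series for that reaction,
pre-aggregation, so isozymes stay distinguishable.

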