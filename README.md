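# hidden-enhancers

Tools for characterising in vivo enhancers that carry **no canonical
chromatin marks** in the tissue where they are active.

Chromatin profiling — H3K27ac ChIP-seq, H3K4me1 ChIP-seq and ATAC-seq open
chromatin — is the standard shortcut for enhancer discovery in developing
tissues. Yet when elements validated in transgenic mouse reporter assays are
intersected with tissue- and stage-matched peak calls, a sizeable minority of
true enhancers show none of the three marks. This package implements the
computational machinery for studying these *hidden* enhancers, aimed at
regulatory genomicists who work with tested-element tables, ENCODE-style peak
calls and transgenic activity calls.

## What it computes

For each validated element `e` with activity in tissue `t`, presence of mark
`m` is defined through bedtools-style intersection with minimum overlap of
1 bp:

```
present(e, t, m)  :=  |{ p in Peaks(t, m, stage) : |e ∩ p| ≥ 1 bp }| ≥ 1
```

and the number of present canonical marks `k(e,t) ∈ {0,1,2,3}` assigns the
categories THREE_MARKS / TWO_MARKS / ONE_MARK / **HIDDEN** (`k = 0`). Around
this classification the package provides:

- **`intervals`** — 0-based half-open interval arithmetic, BED3/BED6/
  narrowPeak/bedGraph and UCSC-chain I/O, and a conservative single-chain
  liftOver with a `minMatch`-style mapped-fraction threshold (default 0.1).
- **`classification`** — per-(element, tissue) mark matrices, the four-way
  category call, sequential mark-filter waterfalls, and validation-rate-by-
  signal-rank curves.
- **`cascade`** — the ordered recovery of hidden enhancers through
  earlier-stage bulk marks (E10.5 H3K27ac/H3K4me1), single-cell chromatin
  accessibility, and cross-species (human) chromatin data, with explicit
  per-stage applicability/availability bookkeeping; plus cCRE catalog overlap
  with negative-set controls.
- **`tiling`** — unbiased ~5 kb overlapping-tile designs across a locus, with
  boundary adjustment that keeps peak-enriched regions whole.
- **`feature_stats`** — mean per-base conservation over elements (zero /
  exclude missing-data policies), two-sample Kolmogorov–Smirnov comparisons,
  length-matched random genomic backgrounds, and repeat-class composition.
- **`synthetic` / `fixtures`** — a seeded generator of complete input bundles
  with planted ground truth, and deterministic fixtures whose pipeline
  outputs reproduce published marginal counts exactly.

There is no command-line interface; the importable API plus the narrative
scripts in `examples/` are the intended surface.

## Worked example

```
python examples/01_classify_retrospective.py
```

prints (abridged):

```
1272 elements, 2051 element-tissue activities

   category  count  fraction  percent
THREE_MARKS   1028  0.501219       50
  TWO_MARKS    461  0.224768       22
   ONE_MARK    277  0.135056       14
     HIDDEN    285  0.138957       14

limb activities: 304
  lacking H3K27ac:                 116
  ... and H3K4me1:                 60
  ... and ATAC (hidden enhancers): 45
```

Half of the validated activities carry all three marks, but 285 of 2051
(14%) carry none — these are hidden enhancers, invisible to any discovery
strategy based on the three canonical marks. The limb waterfall shows the
same filtering one mark at a time: 116 of 304 limb activities lack H3K27ac,
60 of those also lack H3K4me1, and 45 lack all three. The other examples
walk through tiling design, the recovery cascade (172/8/10/118 terminal
counts), cCRE overlap (90% of hidden enhancers vs 82% of in vivo-negative
elements — little specificity), and conservation/repeat comparisons.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the deterministic fixture bundles and recomputes, through the full
pipeline (mark-matrix construction, classification, sequential filtering, the
recovery cascade with chain lift-over, and catalog overlap), the headline
statistics of the analysis: the hidden-category percentage and limb waterfall
of the retrospective cohort, the hidden count of the unbiased tiling cohort,
the per-stage recovery-cascade counts and availability bookkeeping, and the
cCRE overlap percentages for hidden and negative element sets. Results are
written as JSON keyed `t1`…`t12`, each with the computed value and the
problem size it was measured on.

## Layout

```
src/hidden_enhancers/   library modules
examples/               one narrative script per capability
tests/                  pytest suite (unit, property and acceptance tests)
scripts/acceptance.py   headline-statistics recomputation
docs/methods.md         models, conventions, numerical choices, limitations
```
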