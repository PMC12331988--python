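# Methods

This note documents the models and procedures the package implements, the
conventions and numerical choices behind them, what the synthetic data do and
do not emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and intersection semantics

All coordinates are 0-based half-open (BED-native); 1-based inputs must be
converted at parse time. Strand is ignored for elements and peaks — enhancer
activity is treated as strandless — and honoured only in chain arithmetic.

Mark presence is decided by interval intersection with a minimum overlap of
1 bp (configurable): a peak sharing a single base with an element counts, and
half-open adjacency does not. When several datasets exist for the same
(tissue, mark, stage), they are unioned — presence in any dataset counts, and
reported counts are summed across datasets. A required (tissue, mark) pair
with no data at all must be declared unavailable explicitly; silently missing
data would be indistinguishable from a hidden call, which is the failure mode
this analysis exists to expose.

`intersect_elements` filters candidates by sorted start coordinate and then
counts peaks whose shared-base span reaches the floor. The test suite checks
it against an all-pairs double loop and against `bedtools intersect -c`.

## Lift-over

`map_interval` is a conservative dialect of UCSC liftOver: the single chain
whose gapless blocks cover the most query bases is selected (ties by chain
score, then input order); the query maps to the minimal target span
containing all its mapped bases; reverse-strand target coordinates are
flipped back to the forward strand. A query whose covered fraction falls
below `min_match` (default 0.1, matching common practice for regulatory
elements whose boundaries are fuzzy) is UNMAPPED — a value, not an error.
Split and multi-chain mappings are deliberately not stitched; elements that
fail to map are excluded from denominators and reported, never silently
dropped.

## Classification

A matrix row exists for each (element, tissue) pair with a *positive*
activity call, restricted to the six scoreable embryonic tissues (forebrain,
midbrain, hindbrain, craniofacial, limb, heart). An element active in two
tissues contributes two rows and can be hidden in one while marked in the
other; all cohort-level counts are over rows (activities), not elements.
Elements positive only in tissues outside the six contribute no rows.

Categories follow the number of canonical marks present: THREE_MARKS,
TWO_MARKS, ONE_MARK, HIDDEN. Extended marks (H3K27me3, H3K36me3, H3K4me2,
H3K4me3, H3K9ac, H3K9me3, DNase) may be carried in the matrix for annotation
but never influence the category. The canonical stage is E11.5 by default;
stage is a parameter so the same code serves the E10.5 cascade stage.

Integer percents are reported with round-half-away-from-zero, and raw
fractions are always retained. Note one consequence: a category at exactly
13.5% prints as 14 even where an upstream source truncated it to 13; the
counts, not the printed percents, are the exact quantities.

The validation-rate-by-rank analysis ranks tested-element-overlapping peaks
by signal value (descending, coordinate tie-break) and splits them into
equal-count bins; the binning scheme is the simplest rank scheme and is
exposed as a parameter since no canonical choice exists.

## Recovery cascade

Stages run in the fixed order EARLIER_BULK → SINGLE_CELL → CROSS_SPECIES. A
record is evaluated at a stage only while unrecovered, only where the stage
*applies*, and only where data are *available*; the first recovering stage
wins, so terminal states partition the input exactly, and all percentages are
reported against the starting hidden set.

- EARLIER_BULK uses H3K27ac and H3K4me1 only (no earlier-stage ATAC), per the
  biological rationale that residual reporter signal reflects earlier
  enhancer-associated histone acetylation/methylation.
- SINGLE_CELL applies to tissues with single-cell accessibility resources
  (forebrain and hindbrain by default; data-driven, not hardcoded).
- CROSS_SPECIES applies to human-derived elements in tissues with human
  chromatin data (craniofacial, heart, limb), lifting elements onto the human
  assembly first.

Applicability and data availability are tracked separately, and the
">= 2 of 3 complementary data types available" summary counts *data
availability* per data type: earlier-bulk availability, a per-record
single-cell coverage flag, and tissue-level human-data availability
irrespective of element origin. This is a deliberate design choice: the
alternative (counting cross-species availability only where the stage also
applies) cannot reproduce the published availability bookkeeping and
understates how much data was on the table for the unrecovered set. The
`cascade_308` fixture encodes one per-record availability assignment
consistent with all published totals; per-record availability is not itself
published, so that assignment is a labelled reconstruction.

## Tiling design

Tiles are placed greedily left to right at stride
`target_len − min_overlap`. A proposed boundary strictly inside an anchor
peak is moved: extension to the peak end is preferred (maximises intact
capture) when the tile stays within `max_len`; otherwise the tile shrinks to
the peak start when it stays above `min_len`; otherwise the peak is recorded
as split-unavoidable and the boundary stands. The final tile is right-aligned
to the locus end; the stride arithmetic guarantees its overlap bound. A locus
no longer than `max_len` is emitted as a single tile.

Defaults: target 5000 bp; minimum overlap 400 bp (mid-range of "several
hundred"); length bounds 4000–6500 bp, wide enough to admit an observed
~4985 ± 456 bp cloned-element distribution while staying PCR-plausible. All
three are parameters. The designer is deterministic, and `TileSet.validate`
asserts exact coverage, ordering, overlap and length invariants. No claim is
made of reproducing any historical design's exact tile count; the overlap
constant and adjustment rule behind such counts are not published.

## Conservation and repeats

Mean conservation per element is the length-weighted mean of a stepwise
bedGraph track. Uncovered bases score 0 under the default `zero` policy
(unaligned ≈ unconserved); the `exclude` policy drops them from the
denominator and returns NaN for a fully uncovered element. Both policies are
offered because upstream handling of missing bases is generally unstated;
the zero policy is the transparent default.

Group comparisons use the two-sample two-sided Kolmogorov–Smirnov test
(scipy), asymptotic p by default with exact small-sample computation
available. The genomic background is 10,000 (configurable) length-matched
intervals placed uniformly over the genome under a fixed seed, chromosomes
weighted by their number of admissible start positions — standard practice,
fully parameterised, since "genomic background" has no canonical definition.

Repeat composition tallies RepeatMasker-style entries overlapping each
element (≥ 1 bp), grouped into LINE / SINE / DNA / LTR with a catch-all
`other`; subclass labels such as `SINE/Alu` are folded by prefix.

## Synthetic data

The generator emulates: tested-element tables over the six tissues; per
(tissue, mark, stage) peak tracks with a planted hidden fraction; E10.5 bulk,
single-cell and human cross-species recovery resources with configurable
recovery probabilities; a cross-assembly chain (identity plus offset, with
optional unmappable spans); a stepwise conservation track with an uplift
inside active elements; repeat annotations; and a pooled cCRE-style catalog.
Default rates mirror the study's observed conditions: hidden fraction 0.14,
earlier-stage recovery 0.56, single-cell recovery 0.18 (forebrain/hindbrain
only), human-origin fraction 0.76 with cross-species recovery 0.20, catalog
coverage 0.90 (active) vs 0.82 (inactive). Geometry defaults (1.5 kb
elements on a 10 kb grid with 200 bp clearance; 700 ± 120 bp peaks) are
desk-scale choices: small enough to run in milliseconds, large enough that
planted overlaps are unambiguous.

Hidden rows are peak-free *by construction*, not by rejection sampling:
planted peaks sit inside their own element, background peaks are confined to
inter-element gaps with clearance, so the planted label is guaranteed under
the ≥ 1 bp rule. Consequently a green parameter-recovery test establishes
that the pipeline recovers what was planted and that the Bernoulli machinery
is calibrated — it does not establish robustness to peak-caller noise,
boundary ambiguity, overlapping regulatory architecture or read-level
artefacts, none of which the generator emulates. Identical seeds produce
byte-identical bundles.

The four fixtures are deterministic reconstructions pinned to published
marginal counts (cohort sizes, per-tissue positives, category counts,
waterfalls, cascade stage counts, catalog overlap fractions). Marginals that
are not published — per-tissue hidden counts beyond limb and the two printed
tiling tissues, the within-tissue split of two-mark and one-mark patterns,
per-record cascade availability — are distributed deterministically and must
not be read as data. Outputs that depend only on the published marginals are
exact.

## Numerical choices and degenerate inputs

- Parsers reject empty and inverted intervals and name the offending line;
  writer∘reader is the identity on valid records.
- Chain records validate block extents against declared spans on both
  genomes.
- Empty peak collections are legal everywhere (zero counts, 0% overlap);
  empty *element* sets are errors in group-level analyses.
- An empty hidden set runs through the cascade and yields all-zero summaries.
- KS comparison refuses empty groups; background sampling refuses lengths
  exceeding every chromosome.
- Percent reporting: round half away from zero; raw fractions retained.

## Limitations

- The lift-over is single-chain and single-span; elements whose true mapping
  is split across chains are reported unmappable rather than stitched.
- Peak calling, read processing and single-cell clustering are out of scope;
  the package consumes peak BEDs as given.
- The cascade's availability flags describe data-type coverage, not the
  biological interpretability of a recovery (e.g. residual reporter
  perdurance vs. genuine earlier activity is not adjudicated).
- Fixture-level agreement with published totals validates the pipeline's
  arithmetic, not any per-element biological claim.
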