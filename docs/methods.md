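# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `odontoprio`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and interval algebra

All genomic coordinates are 0-based half-open (BED convention) internally.
The only conversion happens at the boundary: GWAS-catalog position columns
are 1-based on disk and shifted at load. Chromosome names are compared by
exact string match — a "chr1" vs "1" mismatch surfaces as zero overlap and
loud downstream validation rather than a silent rename, which in our
experience is the safer failure mode for heterogeneous inputs. Strand is
carried on genes (it orients the basal regulatory domain) but ignored by
all overlap operations: enhancers are strandless.

Merge, subtract, and intersect follow bedtools semantics: merge coalesces
touching intervals (end == next start); subtract trims or splits partially
covered intervals rather than dropping them. The test suite pins these
semantics against a per-base boolean-mask oracle on 10 kb toy chromosomes
(1,000 random fixtures), which also fixes the half-open convention
unambiguously.

## Enhancer extraction and tissue specificity

Strong enhancers are the merged union of segments labelled with the
strong-enhancer states of the 18-state chromatin model — states 8, 9, 10 by
default (configurable; state labels are accepted as bare integers or
ChromHMM dense-BED `N_NAME` strings, with the leading integer
authoritative). Adjacent strong segments coalesce into one element, so
element counts refer to discrete merged regions.

Tissue-specific enhancers default to **whole-element removal**: a target
element sharing at least `min_bp` (default 1) bases with any background
strong element is dropped entirely. This matches counting discrete
enhancers as either unique or not; a base-wise `trim` mode is provided for
sensitivity analysis. Two invariants hold in every mode and are tested:
the specific set is a base-wise subset of the strong set, and adding a
background tissue can only shrink it.

Cross-assembly projection is delegated to a user-supplied precomputed
coordinate map (6-column TSV, non-overlapping on the source side). The
package applies the map — shifting the overlapping portion by the row
offset, largest overlap wins — and reports dropped elements; it performs no
sequence-conservation computation of its own.

## Regulatory domains and proximity

Gene-to-enhancer assignment uses the basal-plus-extension rule with its
documented defaults: basal = 5 kb upstream / 1 kb downstream of the TSS,
extension toward the nearest other gene's basal edge, capped at 1 Mb,
clipped to the chromosome. Implementation details the rule itself leaves
open, fixed here:

* Minus-strand basal domains are the mirror window `[tss − 1 kb, tss + 5 kb)`;
  the ±1 placement of the TSS base inside the half-open window is a
  convention, not derivable from the rule, and is fixed by the tests.
* Genes with identical TSS do not truncate each other (their domains
  overlap freely).
* Extension never shrinks below the basal domain, even when a neighbour's
  basal overlaps it.
* Curated per-gene regulatory domains (a species-resource feature of the
  original association tool) are not modelled.

An enhancer is assigned to **every** gene whose extended domain it overlaps
by ≥ 1 bp; because neighbouring extended domains tile the intergenic space,
multi-assignment is the norm, not the exception.

Variant proximity (default window 500 kbp) is measured from the variant
position to the nearest base of the **gene span**, boundary inclusive; a
`tss` anchor is available because the choice between span and TSS is not
derivable from the stated rule. Interval proximity (validated enhancers,
default 1 Mb) uses the half-open gap between spans, also inclusive. The
synthetic generator plants variants at exactly the window and window + 1 to
pin the boundary on both sides.

Retention filters are literal: GWAS variants pass at p ≤ 5 × 10⁻⁸
(inclusive) and a trait whitelist; DE genes pass at log2 fold change
**strictly greater than** 2 and adjusted p ≤ 0.05 (inclusive). Identical
GWAS rows are deduplicated, but multi-mapping rsIDs (one id, several
positions) are all kept — deduplicating them is not clearly correct and the
conservative choice is to keep the positional evidence.

## Enrichment statistics

`permutation_set_enrichment` draws `n_perm` (default 10,000) uniform random
subsets of the gene universe of the query's size and scores the overlap with
the target set. The empirical p carries the +1 correction,
`(1 + #{null ≥ obs}) / (1 + n_perm)`, so it is never 0 and bottoms out at
1/(n_perm + 1) ≈ 10⁻⁴ at the default depth. Subsets are sampled by
arg-partitioning a matrix of random keys — a genuine subset resampler, not
the equivalent closed-form count sampler — chunked to bound memory. The null
overlap mean must agree with the hypergeometric expectation
|query|·|target|/|universe| (tested within 3 standard errors), and the
under-null rejection rate at α = 0.05 is checked over 200 null fixtures.
The null samples genes uniformly; no expression- or length-matched sampling
is attempted, which is a divergence risk when applying the package to data
whose query sets are biased in such covariates.

`bh_adjust` is standard step-up Benjamini–Hochberg (delegated to
statsmodels, with input validation), applied across the whole
module × category family in `module_enrichment_flags`. A module flag is
true iff fold > 1 **and** BH-adjusted p ≤ α (default 0.05). A category
empty after intersection with the universe yields fold 0/NaN and a false
flag, never an error.

`fisher_2x2` is computed with exact integer hypergeometric weights
(`C(r1,k)·C(r2,c1−k)`), summing the probabilities of all fixed-margin
tables whose point probability does not exceed the observed one
(probability-ordering two-tailed rule). Ties are exact integer comparisons,
not tolerance-based, which is why the implementation agrees with exhaustive
rational-arithmetic enumeration to 1e-12 on every table with total ≤ 60
(tested) and remains exact for large unbalanced tables (Python integers do
not overflow). Two effect sizes are reported: the cross-product odds ratio
(∞ when b·c = 0 with a·d > 0) and the ratio of row proportions
`(a/(a+b)) / (c/(c+d))` — the latter is what a "fold increase in
prevalence" means with the complement group as baseline, and is the number
the package's acceptance test checks at 8.9 for the oligodontia CNV-burden
table.

## The composite score

Eight components, maximum 13: marker (0/1), dental-specific marker (0/1 —
enamel knot, epithelium, mesenchyme, perivascular cells), GWAS proximity
(0/1), TSE bucket (0/1/2/3/4 for 0, 1–2, 3–4, 5–6, 7+ predicted targeting
tissue-specific enhancers), module enrichment (0–3), VISTA proximity (0/1),
tooth-enhancer target (0/1), DEG (0/1). Design choices where the scheme's
prose is ambiguous:

* **Module bonus** defaults to one point per enriched category (max 3);
  this is the only reading under which the three categories are
  individually meaningful. A lump-sum 0/1 option exists.
* **Tie-break** defaults to the predicted TSE count (the quantity the
  ranked table prints), with an STE option; a final lexicographic gene-id
  key makes the ranking fully deterministic.
* **"Tooth-enhancer target"** defaults to the strong (broader) enhancer
  set; configurable to the tissue-specific set.
* Genes absent from the module table are excluded from ranking by default
  (scoring is defined over the co-expression universe); a flag scores them
  with 0 module points instead.

Scoring is a pure function; monotonicity in every component and agreement
with an independent arithmetic oracle are property-tested.

## The synthetic world

The generator plants a 3-chromosome genome (2 × 10 Mb gene grids + one 4 Mb
boundary chromosome), 60 grid genes at 300 kb pitch with alternating
strands, and cycling high / mid / null evidence classes. Scale was chosen
so a full pipeline run with 10,000-permutation enrichment completes in
about a second on one CPU, making 20-seed sweeps cheap.

Two constructions make exact end-to-end truth well-defined:

* **Enhancers live only in basal domains.** Under the extension rule a
  neighbour's domain stops exactly at a gene's basal edge, so an element
  planted inside a basal domain belongs to precisely one gene — per-gene
  counts are exact without re-implementing the extension arithmetic in the
  generator. Planted elements are 120 bp at 250 bp pitch, so they never
  merge into each other. Shared (non-specific) elements reappear — fully or
  half-length — as strong states in a background tissue; background-only
  decoys exercise the subtraction without touching target counts.
* **Module enrichment by containment or exclusion.** Modules meant to be
  flagged are complete subsets of their category (the probability that a
  uniform null draw reaches the observed overlap is below ~10⁻⁴ per
  permutation, so a false negative across 10,000 permutations plus BH is
  negligible); modules meant unflagged have zero overlap (fold 0,
  deterministically false) or an overlap far below expectation (fold < 1).
  This is what makes bit-exact score recovery over a 20-seed sweep a fair
  test despite the stochastic enrichment step.

Truth (evidence, components, totals, ranking, planted tissue-specific
elements) is computed inside the generator from the planted coordinates
with plain arithmetic, before and independent of any pipeline code.

What the world does **not** emulate: nucleotide sequence, linkage
disequilibrium, realistic chromatin-state run-length statistics, covariate
structure (expression level, gene length) in the gene sets, or assembly
differences. Passing the end-to-end tests therefore demonstrates the
correctness of the pipeline's logic and determinism, not the field
performance of the scoring scheme on real data.

## Determinism and provenance

Every stochastic step takes an explicit seed; per-test child seeds are
spawned from a `SeedSequence` and recorded in the results. Re-running the
pipeline with the same config and inputs is bit-identical on all outputs;
the run manifest records the config hash and SHA-256 of every input. The
serialized synthetic world is byte-identical across runs of the same seed.

## Known limitations

* Genome-wide corpus results (tens of thousands of enhancers across
  hundreds of tissues) are out of desk scale; the package is validated on
  planted fixtures and exact oracles instead.
* The permutation null is uniform over the universe (see above).
* Coordinate-map projection assumes locally affine maps (one offset per
  row); split/inverted mappings must be represented as multiple rows.
* The scoring scheme's component weights are fixed by its published
  definition, not fitted; the package intentionally provides no weight
  optimization.
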