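# Methods

## Coordinates and inputs

All internal coordinates are 0-based half-open. Tables written in the
browser-style 1-based fully-closed dialect are converted at read time
(`dialect="ucsc_1_inclusive"`); a flag exists because published cohort tables rarely
state their convention, so both readings can be tried when reproducing
published numbers. Downstream code never re-checks dialects.

The genome is a list of chromosome sizes plus *excluded* intervals (assembly
gaps, alternative haplotypes, random contigs), stored merged per chromosome.
Exclusions constrain both the shuffling null and the variability windows.

## Overlap regions

`coverage_segments` partitions the union of a cohort's CNV intervals into
maximal segments of constant coverage depth via an endpoint sweep; it
reproduces `genomeCoverageBed -bga` semantics exactly (verified against
bedtools during development and against a per-base counting oracle in the
test suite). Depth counts CNV *intervals*: a patient with two tandem CNVs
over a segment contributes 2 to depth but appears once in the segment's
patient set. The cohorts this models carry essentially one CNV per patient,
so the distinction rarely matters, but it mirrors the tool behavior the
analysis is defined by. Σ(depth × length) over segments equals the summed
input length (conservation), asserted as a property test.

A region is *shared* when depth ≥ 2. The overlap summary tabulates region
counts and mean lengths per depth; `mean_overlap` averages depth over all
depth ≥ 1 regions — singleton regions are part of the accounting, since the
per-depth table tabulates them too. A ≥ 2-only variant is available.

## Randomization test

Null model: each observed CNV is relocated independently, preserving its
length, to a start position drawn uniformly over every legal start
genome-wide (the placed interval must fit inside a chromosome and intersect
no excluded interval). Two deliberate properties:

- **Exact sampling, not rejection.** Gap-free stretches are weighted by
  their number of legal starts for the given length, then the start is drawn
  uniformly within the chosen stretch. This is exactly the uniform target
  distribution, makes "unplaceable" a deterministic error, and needs no
  retry bound. Relocation across chromosomes is proportional to legal space;
  shuffled intervals may overlap one another. A same-chromosome-only mode is
  not provided because the cross-chromosome default is the tool behavior the
  analysis mirrors.
- **Reproducibility.** One seed governs a `SeedSequence` whose spawned
  children drive each permutation, so runs are reproducible and trivially
  parallelizable.

For each of R permutations (default 1000), the shuffled list is segmented
and its mean overlap μᵢ recorded. μ̄ and σ are the mean and sample SD
(ddof = 1) of the μᵢ; zᵢ = (μᵢ − μ̄)/σ therefore standardize to mean 0 and
SD 1 by construction (asserted to 1e-9), and the observed list is scored by
the same formula. Significance is the empirical fraction of permutations
with zᵢ ≥ z_obs, floored at 1/R and flagged as an upper bound when no
permutation reaches it; the Shapiro–Wilk p of the zᵢ is reported alongside
(the empirical p is the primary quantity whenever normality is rejected,
and it is reported regardless). σ = 0 is a degenerate-null error rather
than a silent z = ∞.

## Prioritization

Candidates must pass all three filters, and every gene touched by a shared
region keeps its per-filter flags so attrition is reportable:

- **Recurrence**: ≥ `min_patients` (default 2) distinct patients with a CNV
  of the given type overlapping the gene span by ≥ 1 base. Distinct
  *patients*, not raw CNV count, because the criterion expresses "altered in
  more than one individual".
- **Regional gene count**: the gene lies in at least one supporting shared
  region containing ≤ `max_genes_per_region` (default 5) genes. Per-region
  counting with the *any*-region reading is the permissive interpretation;
  "encompassed" genes are any-overlap genes, matching how browser region
  queries behave. Both choices were genuinely open; the alternatives
  (full containment, all-regions) would only shrink candidate sets.
- **Expression**: the gene's maximum nRPK across stages reaches the cutoff.
  nRPK = normalized count / transcript length in kb, computed per
  transcript and aggregated per gene-stage by maximum (the permissive
  reading consistent with a "≥ cutoff at any stage" test). The default
  cutoff is the mean nRPK of expressed records (nRPK > 0) pooled across
  stages — pooling, rather than per-gene averaging first, weights stages
  equally per measurement and is the simpler estimator; the published value
  (59.00 for the mouse-palate table) can be pinned via `nrpk_cutoff`.

Relaxing any threshold can only add candidates (monotonicity, property
tested), and results are invariant to patient relabeling and gene order.

## Enrichment

With N genes retrieved from one CNV type, K panel genes among them, n
candidates and k panel candidates: fold = (k/n)/(K/N), and
p = P(X > k) for X ~ Hypergeometric(N, K, n). The *strict* tail is the
default because it is the convention of R's
`phyper(k, K, N-K, n, lower.tail = FALSE)`, which published enrichment
tables in this literature follow (the printed 7.2 × 10⁻¹⁶ / 8.6 × 10⁻⁶
values are strict-tail values; the inclusive tail gives 3.8 × 10⁻¹⁴ /
3.1 × 10⁻⁴). `tail="ge"` selects the inclusive convention. The
implementation is checked against exhaustive enumeration of all C(N, n)
draws for N ≤ 12, and fold × (K/N) × n = k holds as an algebraic identity.
Symbol matching is case-insensitive with an explicit alias table (e.g.
WHSC2 = NELFA); K = 0 with k = 0 reports fold 0, p = 1.

## Variability

Fixed windows (default 1 Mb; the trailing remainder window per chromosome is
kept) tile each chromosome, and any window intersecting an excluded interval
is removed — any-overlap removal is the stricter of the two possible
readings and avoids partially-gapped windows biasing counts. Catalog
variants are counted per window by any-overlap (a variant spanning two
windows increments both). Zero-count windows are excluded before
standardization because log₁₀ 0 is undefined; their number is logged.
μ is the mean and σ the sample SD (n − 1 denominator, exactly as the
formula prints) of the log₁₀ counts; zᵢ standardizes each retained window.
A region or gene spanning several windows receives the mean of the raw
counts, then log₁₀, then the genome-wide standardization; a region
overlapping only removed windows is explicitly "not assessable" (the
treatment telomeric candidates receive). Catalog rows typed other than
loss/gain (e.g. inversions) are ignored with a logged count. Hypervariable
windows are flagged above a configurable z-quantile (default 0.999) because
the underlying analyses name such regions without defining a numeric
cutoff.

## Phenotypes

The ontology is a child → parent DAG with a single auto-detected root; the
root's direct children are the broad categories. A term maps to *all*
top-level ancestors it reaches (faithful DAG semantics under multiple
inheritance); the root maps to none; unknown terms are reported as unmapped
rather than fatal. The patient × category matrix excludes the cohort's own
selection phenotype (the OFC class labels) by default to avoid tautological
columns. Penetrance summaries contrast OFC-classed cohort carriers of CNVs
over a gene with non-OFC carriers (cohort patients without an OFC class plus
an externally supplied background count).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at a
scale that keeps the full test suite fast: 3 chromosomes × 30 Mb with 5 %
excluded sequence (telomeric + pericentromeric blocks); 50 patients, one CNV
each; planted recurrent 400 kb regions of depths 8 and 4 (deletions) and 5
(duplications) — echoing the deepest published loci — plus one crowded
8-gene region of depth 3; background CNV lengths log-normal with 10 kb
median, placed by the same uniform-over-legal-space rule as the shuffling
null. Background sparsity is part of the generator's contract: with ~30
background CNVs of 10 kb median over ~85 Mb of legal space, the expected
number of chance recurrent expressed genes per run is ~0.005, so planted
candidates are the only candidates by construction. Carrier CNVs jitter
their breakpoints by up to 50 kb around sparse planted regions (background
genes keep a matching safety margin); crowded regions use identical
breakpoints so their shared segment spans all of their genes and the
gene-count filter is what rejects them.

Expression is log-normal (median 30 nRPK, log-SD 1.2) with a 20 %
zero-inflated fraction across five stages; planted candidates and crowded
decoys are set to 3× the provisional cutoff at one stage, low-expression
decoys to 0.05× at every stage, so each decoy class fails exactly one
filter. The catalog draws Poisson counts (50 variants/Mb) per 1 Mb window
with 3 hotspot windows elevated 8-fold. The panel contains 20 background
genes plus 2 planted candidates; the ontology has 8 top-level categories ×
4 leaves. Everything derives from one `numpy` generator seeded by the spec,
and regenerating with the same seed is byte-identical.

What passing on synthetic data does *not* show: real cohorts have correlated
CNV breakpoints (segmental-duplication-mediated hotspots), non-log-normal
size mixtures, shared syndromic CNVs across registries, and annotation/alias
noise; the generator makes no attempt to mimic those, so published
cohort-level numbers are only recomputable from the real inputs (see
`data/README.md`).

## Numerical and degenerate-input choices

- Sample SDs use ddof = 1 throughout (both standardizations print n − 1).
- Empty region lists summarize with an absent (None) mean overlap rather
  than NaN; empty cohorts are errors only where a statistic is undefined.
- Shapiro–Wilk is restricted to 3 ≤ n ≤ 5000; constant vectors are
  degenerate-input errors.
- Ties in the empirical p count as exceedances ("matched or exceeded").
- Problem sizes in the test suite and acceptance script — 10 kb oracle
  chromosomes, R = 200 for calibration sweeps, R = 1000 for the headline
  synthetic test, 100-seed null sweeps — were chosen so the full suite
  exercises every statistical claim at meaningful power while remaining
  quick to run routinely.

## Known limitations

- Depth counts intervals, not patients; cohorts with many multi-CNV
  patients would need the patient-collapsed variant of the summary.
- The ≤ 5-gene filter's any-region reading can admit a gene whose own locus
  is gene-dense if one narrow shared segment isolates it.
- No liftover: all inputs must share one genome build.
- The shuffling null preserves lengths but not GC/repeat context; observed
  z-scores are therefore tests of positional clustering only.
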