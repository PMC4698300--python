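# cnvrecur

Recurrent copy-number-variant (CNV) region discovery and candidate-gene
prioritization for orofacial cleft (OFC) cohorts — and, more generally, for
any patient cohort in which shared deletions/duplications are mined for
dosage-sensitive disease genes.

Clinical registries such as DECIPHER and ECARUCA report patients with large
genomic deletions and duplications alongside their phenotypes. When several
unrelated patients with the same phenotype carry CNVs over the same locus,
the genes in the shared segment become candidate disease genes. This package
implements that analysis as a tested library plus a set of analysis drivers:

1. **Overlap segmentation** — the cohort's CNVs are segmented into maximal
   constant-depth *overlapping regions* (depth = number of covering CNVs,
   `genomeCoverageBed`-style), each annotated with its contributing patients.
2. **Randomization test** — each CNV is relocated, length-preserved, to a
   uniformly drawn legal position in the gap-free genome; repeating this *R*
   times (default 1000) yields null mean-overlap values μᵢ, and the observed
   list is scored as *z* = (μ_obs − μ̄)/σ. Because the permutation z's are
   typically non-normal (Shapiro–Wilk), significance is the empirical
   fraction of permutations matching or exceeding the observed score,
   reported as ≤ 1/R when none does.
3. **Gene prioritization** — genes in shared (depth ≥ 2) regions are
   filtered by recurrence (≥ 2 distinct patients), regional gene count
   (≤ 5 genes in a supporting shared region) and embryonic-palate expression
   (nRPK — normalized counts per kilobase of transcript — at or above the
   mean of expressed genes, pooled over stages E10–E14).
4. **Panel enrichment** — enrichment of a curated disease-gene panel among
   candidates: fold = (k/n)/(K/N) with an upper-tail hypergeometric p-value.
5. **Variability scoring** — 1 Mb windows over the gap-filtered genome are
   scored as *z* = (log₁₀ cᵢ − μ)/σ from a population structural-variant
   catalog (sample SD, n − 1); candidate loci are checked against
   hypervariable regions, and per-gene genic/exonic catalog burden is
   tabulated.
6. **Phenotype mapping** — patient ontology terms are mapped to the
   top-level categories of an HPO-style DAG, and OFC vs non-OFC carrier
   counts summarize per-gene penetrance.

A first-class synthetic-data generator (`cnvrecur.synthetic`) produces every
input — gapped genome, cohort with planted recurrent regions, gene models,
expression, variant catalog with hotspots, panel, mini-ontology — with a
ground-truth manifest, so the whole pipeline is exercisable and testable
without any downloads.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_overlap_regions.py --seed 1
python analysis/03_prioritize_genes.py
```

prints (seed 1):

```
wrote bundle to results/bundle (seed 1)
  patients: 50, CNVs: 50, genes: 217, catalog variants: 5118
  planted deletion depth 8 at chr2:12081285-12481285
  ...
deletion: 29 CNVs, 19 shared regions (max depth 8), z_real = 31.95, empirical p <= 0.001 (Shapiro-Wilk p = 1.2e-25)
duplication: 21 CNVs, 7 shared regions (max depth 5), z_real = 18.29, empirical p <= 0.001 (Shapiro-Wilk p = 1.8e-39)
nRPK cutoff (mean of expressed records): 62.19
deletion: 14 genes in shared regions -> 14 recurrent -> 6 in <=5-gene regions -> 2 candidates
  planted-candidate recall 1.00, off-target none
```

Read: the cohort's deletions share far more sequence than uniformly placed
CNVs of the same sizes would (z ≈ 32, none of 1000 permutations reached it),
and the three filters recover exactly the genes the generator planted as
candidates, while the low-expression and crowded-region decoys are rejected
by exactly the intended filter. `analysis/04–06` continue with panel
enrichment, variability and phenotype summaries; the published deletion
contingency table (5809 genes / 49 panel genes / 45 candidates / 11 hits)
reproduces fold 28.98, p = 7.2 × 10⁻¹⁶ through the same arithmetic.

The same steps are available as a CLI (`cnvrecur run --config cfg.yaml`,
plus `synth`, `randomize`, `intervals`, `enrich` subcommands) or through
`cnvrecur.pipeline.run_pipeline`.

Cohort-level published numbers (249/226 CNV records, 146/109 shared regions,
z = 13.91/11.58, SATB2 deleted in 8 patients) can be recomputed by placing
the patient table and a GRCh37 annotation under `data/` — see
`data/README.md`; the corresponding tests fail with an explanatory message
while those inputs are absent.

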