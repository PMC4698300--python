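# Optional external inputs

This directory is empty by design. The cohort-level checks in
`tests/test_acceptance.py` recompute published patient-cohort results and
need inputs that cannot be redistributed here:

- `published_cohort.tsv` — the 312-patient OFC CNV table (DECIPHER +
  ECARUCA, GRCh37), TSV with header
  `patient_id  cnv_type  chrom  start  end  phenotypes`
  (`cnv_type` ∈ {deletion, duplication}; coordinates 1-based inclusive as
  printed in browser-style tables; `phenotypes` `;`-separated term ids).
- `hg19.chrom.sizes` — two-column UCSC chrom.sizes for GRCh37/hg19.
- `hg19_exclusions.bed` — BED3 of assembly gaps, alternative haplotypes and
  random contigs to exclude from shuffling.
- `grch37_genes.tsv` — gene annotation, either BED12 or
  `symbol  chrom  start  end  gene_type  exon_starts  exon_ends`.

With these present, the affected tests assert the published record counts,
shared-region counts, randomization z-scores and per-gene recurrence; without
them the tests fail with a message naming the missing file.
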