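#!/usr/bin/env python
"""Phenotype-category matrix and per-candidate penetrance summaries.

Maps each patient's ontology terms to the top-level categories of the bundled
mini-ontology, writes the patient x category presence matrix, and contrasts
OFC vs non-OFC carriers for each candidate gene. Writes
phenotype_matrix.tsv and penetrance.tsv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvrecur import (
    PrioritizationConfig,
    load_ontology,
    penetrance_summary,
    phenotype_matrix,
    prioritize,
    read_cnv_cohort,
    read_genome,
)
from cnvrecur.genome import read_annotation
from cnvrecur.prioritization import read_expression


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    genome = read_genome(args.bundle / "genome.chrom.sizes",
                         args.bundle / "exclusions.bed")
    records, patients = read_cnv_cohort(args.bundle / "cohort.tsv", genome)
    ontology = load_ontology(args.bundle / "ontology.tsv")
    annotation = read_annotation(args.bundle / "genes.tsv")
    expression = read_expression(args.bundle / "expression.tsv")

    matrix = phenotype_matrix(patients, ontology)
    matrix.to_csv(args.out / "phenotype_matrix.tsv", sep="\t")
    per_cat = matrix.sum().sort_values(ascending=False)
    print(f"{len(matrix)} patients x {matrix.shape[1]} categories; most frequent: "
          + ", ".join(f"{c} ({n})" for c, n in per_cat.head(3).items()))

    by_symbol = {g.symbol: g for g in annotation}
    rows = []
    for cnv_type in ("deletion", "duplication"):
        out = prioritize(records, annotation, expression,
                         PrioritizationConfig(), cnv_type)
        for cand in (c for c in out if c.is_candidate):
            g = by_symbol[cand.gene]
            n_ofc, n_non, ratio = penetrance_summary(g, (records, patients), 0)
            rows.append({"gene": cand.gene, "cnv_type": cnv_type,
                         "ofc_carriers": n_ofc, "non_ofc_carriers": n_non,
                         "ratio": ratio if ratio is not None else "NA"})
            print(f"  {cand.gene} ({cnv_type}): {n_ofc} OFC vs {n_non} non-OFC carriers")
    pd.DataFrame(rows).to_csv(args.out / "penetrance.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
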