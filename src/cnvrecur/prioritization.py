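"""Candidate-gene prioritization from shared CNV regions.

Three filters select candidates among genes touched by shared (depth >= 2)
overlap regions:

1. recurrence — the gene is deleted/duplicated in >= ``min_patients`` distinct
   patients (any-overlap of the gene span by a CNV of the given type);
2. regional gene count — at least one supporting shared region containing the
   gene holds <= ``max_genes_per_region`` genes;
3. expression — the gene's maximal nRPK (normalized counts per kilobase of
   transcript) across developmental stages reaches ``nrpk_cutoff``.

The default cutoff is recomputed from the supplied expression table as the
mean nRPK of expressed (nRPK > 0) records pooled over stages; it can be
pinned to a published value instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .genome import CNVRecord, GeneModel
from .intervals import coverage_segments, genes_in_interval

logger = logging.getLogger(__name__)

STAGES = ("E10", "E11", "E12", "E13", "E14")


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    transcript_id: str
    stage: str
    normalized_count: float
    length_kb: float

    @property
    def nrpk(self) -> float:
        return self.normalized_count / self.length_kb


@dataclass
class PrioritizationConfig:
    min_patients: int = 2
    max_genes_per_region: int = 5
    nrpk_cutoff: float | None = None  # None -> recompute from the expression table

    def __post_init__(self):
        if self.min_patients <= 0 or self.max_genes_per_region <= 0:
            raise ValidationError("prioritization thresholds must be > 0")
        if self.nrpk_cutoff is not None and self.nrpk_cutoff <= 0:
            raise ValidationError("nrpk_cutoff must be > 0")


@dataclass
class CandidateGene:
    gene: str
    cnv_type: str
    n_patients: int
    min_region_gene_count: int
    max_nrpk: float
    passed_recurrence: bool = False
    passed_gene_count: bool = False
    passed_expression: bool = False

    @property
    def is_candidate(self) -> bool:
        return self.passed_recurrence and self.passed_gene_count and self.passed_expression


def read_expression(source) -> list[ExpressionRecord]:
    """Read the expression TSV: gene, transcript_id, length_kb, stage, normalized_count."""
    df = pd.read_csv(source, sep="\t")
    required = {"gene", "transcript_id", "length_kb", "stage", "normalized_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"expression table missing columns: {sorted(missing)}")
    bad = df[df["length_kb"] <= 0]["gene"].unique().tolist()
    if bad:
        raise ValidationError(f"missing/non-positive transcript length for genes: {bad}")
    return [
        ExpressionRecord(r.gene, r.transcript_id, r.stage, float(r.normalized_count),
                         float(r.length_kb))
        for r in df.itertuples()
    ]


def compute_nrpk(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Gene-level nRPK per stage: maximum over the gene's transcripts."""
    if not records:
        return pd.DataFrame(columns=["gene", "stage", "nrpk"])
    df = pd.DataFrame(
        {"gene": [r.gene for r in records],
         "stage": [r.stage for r in records],
         "nrpk": [r.nrpk for r in records]}
    )
    return df.groupby(["gene", "stage"], as_index=False)["nrpk"].max()


def expression_cutoff(records: Sequence[ExpressionRecord]) -> float:
    """Mean nRPK over expressed (nRPK > 0) records, pooled across stages."""
    values = [r.nrpk for r in records if r.nrpk > 0]
    if not values:
        raise ValidationError("no expressed genes (all nRPK == 0)")
    return sum(values) / len(values)


def gene_patient_counts(
    cnvs: Sequence[CNVRecord], annotation: Sequence[GeneModel], cnv_type: str
) -> dict[str, int]:
    """Distinct patients with >= 1 CNV of ``cnv_type`` overlapping each gene span."""
    carriers: dict[str, set[str]] = {g.symbol: set() for g in annotation}
    typed = [r for r in cnvs if r.cnv_type == cnv_type]
    for g in annotation:
        for r in typed:
            if r.chrom == g.chrom and r.start < g.end and r.end > g.start:
                carriers[g.symbol].add(r.patient_id)
    return {sym: len(p) for sym, p in carriers.items()}


def prioritize(
    cnvs: Sequence[CNVRecord],
    annotation: Sequence[GeneModel],
    expression: Sequence[ExpressionRecord],
    config: PrioritizationConfig,
    cnv_type: str = "deletion",
) -> list[CandidateGene]:
    """Apply the three filters; returns every gene touched by a shared region
    with its per-filter pass flags, so attrition is reportable."""
    typed = [r for r in cnvs if r.cnv_type == cnv_type]
    shared = [reg for reg in coverage_segments(typed) if reg.depth >= 2]

    cutoff = config.nrpk_cutoff if config.nrpk_cutoff is not None else expression_cutoff(expression)
    nrpk = compute_nrpk(expression)
    max_nrpk = nrpk.groupby("gene")["nrpk"].max().to_dict() if len(nrpk) else {}

    # smallest gene count among the shared regions containing each gene
    region_count: dict[str, int] = {}
    for reg in shared:
        genes = genes_in_interval((reg.chrom, reg.start, reg.end), annotation)
        for g in genes:
            n = len(genes)
            region_count[g.symbol] = min(region_count.get(g.symbol, n), n)

    counts = gene_patient_counts(cnvs, annotation, cnv_type)
    out: list[CandidateGene] = []
    for sym in sorted(region_count):
        cand = CandidateGene(
            gene=sym,
            cnv_type=cnv_type,
            n_patients=counts.get(sym, 0),
            min_region_gene_count=region_count[sym],
            max_nrpk=float(max_nrpk.get(sym, 0.0)),
        )
        cand.passed_recurrence = cand.n_patients >= config.min_patients
        cand.passed_gene_count = cand.min_region_gene_count <= config.max_genes_per_region
        cand.passed_expression = cand.max_nrpk >= cutoff
        out.append(cand)

    n_rec = sum(c.passed_recurrence for c in out)
    n_rc = sum(c.passed_recurrence and c.passed_gene_count for c in out)
    n_all = sum(c.is_candidate for c in out)
    logger.info(
        "%s prioritization attrition: %d touched -> %d recurrent -> %d in <=%d-gene regions "
        "-> %d candidates (nRPK cutoff %.2f)",
        cnv_type, len(out), n_rec, n_rc, config.max_genes_per_region, n_all, cutoff,
    )
    return out


def candidates_table(genes: Iterable[CandidateGene]) -> pd.DataFrame:
    rows = [
        {"gene": c.gene, "cnv_type": c.cnv_type, "n_patients": c.n_patients,
         "min_region_gene_count": c.min_region_gene_count, "max_nrpk": c.max_nrpk,
         "passed_recurrence": c.passed_recurrence, "passed_gene_count": c.passed_gene_count,
         "passed_expression": c.passed_expression, "is_candidate": c.is_candidate}
        for c in genes
    ]
    return pd.DataFrame(rows)
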