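"""Synthetic input bundles with controlled ground truth.

The generator emulates the statistical structure the analysis assumes, on a
scaled-down genome: a gapped multi-chromosome genome; a patient cohort in
which a few loci are recurrently deleted/duplicated (planted regions of
configurable depth) on top of sparse, uniformly placed background CNVs;
gene models with exons; heavy-tailed (log-normal) palate expression with a
zero-inflated fraction; a population variant catalog with density hotspots;
a small disease-gene panel overlapping some planted candidates; and a
two-level phenotype mini-ontology.

Planted candidate genes are constructed to pass exactly the three
prioritization filters; near-miss decoys (one filter failed) are planted
alongside: low-expression genes inside sparse planted regions and
well-expressed genes inside a crowded (> 5 genes) planted region.
Everything is deterministic for a fixed seed, and a truth manifest records
what was planted.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .genome import CNVRecord, GeneModel, GenomeBuild, Patient, write_cohort
from .randomization import sample_placements

OFC_CLASS_WEIGHTS = {
    # cohort mix mirroring a cleft-palate-dominated clinical registry
    "CP": 0.63, "CLP": 0.13, "CL": 0.10, "bifid_uvula": 0.10,
    "oral_cleft_unspecified": 0.04,
}


@dataclass
class PlantedRegion:
    """One recurrent locus: depth patients carry a CNV covering it."""

    chrom: str | None = None       # None -> placed by the generator
    start: int | None = None
    length: int = 400_000
    depth: int = 8
    cnv_type: str = "deletion"
    n_genes: int = 3               # genes inside the region
    n_candidates: int = 1          # of which this many are true candidates
    jitter: int = 50_000           # breakpoint jitter of the carrier CNVs
    crowded: bool = False          # > max_genes region: all genes are decoys

    def __post_init__(self):
        if self.crowded:
            # identical breakpoints so the shared segment spans all genes
            self.jitter = 0
            self.n_candidates = 0


@dataclass
class SyntheticSpec:
    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    gap_fraction: float = 0.05
    # cohort
    n_patients: int = 50
    cnv_log_mean: float = math.log(10_000)   # background CNV length, log-normal
    cnv_log_sd: float = 0.8
    planted: list[PlantedRegion] = field(default_factory=lambda: [
        PlantedRegion(depth=8, cnv_type="deletion"),
        PlantedRegion(depth=4, cnv_type="deletion"),
        PlantedRegion(depth=5, cnv_type="duplication"),
        PlantedRegion(depth=3, cnv_type="deletion", n_genes=8, crowded=True),
    ])
    background_duplication_fraction: float = 0.45
    # annotation
    n_background_genes: int = 200
    gene_log_mean: float = math.log(20_000)
    gene_log_sd: float = 0.6
    max_exons: int = 8
    # expression
    expr_log_mean: float = math.log(30.0)    # nRPK scale of expressed genes
    expr_log_sd: float = 1.2
    zero_fraction: float = 0.2
    stages: tuple[str, ...] = ("E10", "E11", "E12", "E13", "E14")
    # catalog
    variants_per_mb: float = 50.0
    n_hotspots: int = 3
    hotspot_fold: float = 8.0
    catalog_window: int = 1_000_000
    # panel
    n_panel_background: int = 20
    n_panel_planted: int = 2
    # ontology
    n_top_level: int = 8
    leaves_per_category: int = 4

    def __post_init__(self):
        for frac in (self.gap_fraction, self.zero_fraction,
                     self.background_duplication_fraction):
            if not (0 <= frac <= 1):
                raise ValidationError("spec fractions must lie in [0, 1]")
        need = sum(p.depth for p in self.planted)
        if self.n_patients < need:
            raise ValidationError(
                f"{self.n_patients} patients cannot carry {need} planted CNVs"
            )


@dataclass
class Bundle:
    """In-memory synthetic inputs plus the ground-truth manifest."""

    genome: GenomeBuild
    records: list[CNVRecord]
    patients: list[Patient]
    annotation: list[GeneModel]
    expression_tsv: str
    catalog: list[tuple[str, int, int, str]]
    panel_tsv: str
    ontology_tsv: str
    truth: dict


# ---------------------------------------------------------------------------


def _make_genome(spec: SyntheticSpec) -> GenomeBuild:
    chroms = tuple(
        (f"chr{i + 1}", spec.chrom_length) for i in range(spec.n_chromosomes)
    )
    excluded = []
    gap_total = int(spec.gap_fraction * spec.chrom_length)
    if gap_total:
        telo = gap_total // 3
        centro = gap_total - 2 * telo
        mid = spec.chrom_length // 2
        for name, length in chroms:
            if telo:
                excluded.append((name, 0, telo))
                excluded.append((name, length - telo, length))
            if centro:
                excluded.append((name, mid - centro // 2, mid - centro // 2 + centro))
    return GenomeBuild("synthetic", chroms, tuple(excluded))


def _place_planted(spec: SyntheticSpec, genome: GenomeBuild,
                   rng: np.random.Generator) -> None:
    """Assign non-overlapping gap-free locations to planted regions lacking one."""
    taken: list[tuple[str, int, int]] = [
        (p.chrom, p.start, p.start + p.length)
        for p in spec.planted if p.chrom is not None
    ]
    for p in spec.planted:
        if p.chrom is not None:
            continue
        pad = p.jitter + 10_000
        for _ in range(1000):
            (chrom, s, e), = sample_placements([p.length + 2 * pad], genome, rng)
            cand = (chrom, s + pad, s + pad + p.length)
            if all(not (cand[0] == c and cand[1] < te and cand[2] > ts)
                   for c, ts, te in taken):
                p.chrom, p.start = cand[0], cand[1]
                taken.append(cand)
                break
        else:
            raise ValidationError("could not place planted regions without overlap")


def _split_exons(start: int, end: int, n: int, rng: np.random.Generator
                 ) -> tuple[tuple[int, int], ...]:
    span = end - start
    if span < 2 * n:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n - 2, replace=False))
    bounds = [0, *cuts.tolist(), span]
    exons = [(start + bounds[i], start + bounds[i + 1])
             for i in range(0, 2 * n, 2)]
    return tuple((s, e) for s, e in exons if e > s)


def _make_genes(spec: SyntheticSpec, genome: GenomeBuild,
                rng: np.random.Generator) -> tuple[list[GeneModel], dict]:
    genes: list[GeneModel] = []
    truth_genes: dict[str, dict] = {}

    # genes inside planted regions, evenly spaced
    for ridx, p in enumerate(spec.planted):
        slot = p.length // p.n_genes
        for gidx in range(p.n_genes):
            g_start = p.start + gidx * slot + slot // 10
            g_len = int(min(slot * 0.6, np.exp(rng.normal(spec.gene_log_mean,
                                                          spec.gene_log_sd))))
            g_len = max(g_len, 1000)
            g_end = min(g_start + g_len, p.start + (gidx + 1) * slot)
            sym = f"PG{ridx}_{gidx}"
            n_ex = int(rng.integers(2, spec.max_exons + 1))
            genes.append(GeneModel(sym, p.chrom, g_start, g_end, "coding",
                                   _split_exons(g_start, g_end, n_ex, rng)))
            if p.crowded:
                role = "decoy_crowded"
            elif gidx < p.n_candidates:
                role = "candidate"
            else:
                role = "decoy_low_expression"
            truth_genes[sym] = {"role": role, "region_index": ridx,
                                "cnv_type": p.cnv_type}

    # background genes outside planted regions (+ margin so shared segments
    # from jittered carrier CNVs never touch them)
    margin = max((p.jitter for p in spec.planted), default=0) + 10_000
    avoid = [(p.chrom, p.start - margin, p.start + p.length + margin)
             for p in spec.planted]
    bg_genome = GenomeBuild(
        "bg", genome.chromosomes,
        tuple(list(genome.excluded)
              + [(c, max(0, s), min(dict(genome.chromosomes)[c], e))
                 for c, s, e in avoid]),
    )
    lengths = np.maximum(
        1000,
        np.exp(rng.normal(spec.gene_log_mean, spec.gene_log_sd,
                          spec.n_background_genes)),
    ).astype(int)
    for i, (chrom, s, e) in enumerate(
        sample_placements(lengths.tolist(), bg_genome, rng)
    ):
        n_ex = int(rng.integers(2, spec.max_exons + 1))
        genes.append(GeneModel(f"BG{i}", chrom, s, e, "coding",
                               _split_exons(s, e, n_ex, rng)))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    # transcript lengths = summed exon length (kb)
    genes = [
        GeneModel(g.symbol, g.chrom, g.start, g.end, g.gene_type, g.exons,
                  ((g.symbol + ".t1",
                    sum(e - s for s, e in g.exons) / 1000.0),))
        for g in genes
    ]
    return genes, truth_genes


def _make_cohort(spec: SyntheticSpec, genome: GenomeBuild,
                 rng: np.random.Generator) -> tuple[list[CNVRecord], list[Patient]]:
    classes = list(OFC_CLASS_WEIGHTS)
    probs = np.array(list(OFC_CLASS_WEIGHTS.values()))
    probs = probs / probs.sum()
    pids = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    records: list[CNVRecord] = []
    cursor = 0
    sizes = genome.sizes
    for p in spec.planted:
        for _ in range(p.depth):
            pid = pids[cursor]
            cursor += 1
            j1 = int(rng.integers(0, p.jitter + 1))
            j2 = int(rng.integers(0, p.jitter + 1))
            s = max(0, p.start - j1)
            e = min(sizes[p.chrom], p.start + p.length + j2)
            records.append(CNVRecord(p.chrom, s, e, pid, p.cnv_type))
    n_bg = spec.n_patients - cursor
    lengths = np.maximum(
        500, np.exp(rng.normal(spec.cnv_log_mean, spec.cnv_log_sd, n_bg))
    ).astype(int)
    placements = sample_placements(lengths.tolist(), genome, rng)
    for (chrom, s, e) in placements:
        pid = pids[cursor]
        cursor += 1
        cnv_type = ("duplication"
                    if rng.random() < spec.background_duplication_fraction
                    else "deletion")
        records.append(CNVRecord(chrom, s, e, pid, cnv_type))
    patients = []
    for pid in pids:
        ofc = classes[int(rng.choice(len(classes), p=probs))]
        terms = {ofc}
        n_extra = int(rng.integers(1, 4))
        for _ in range(n_extra):
            cat = int(rng.integers(spec.n_top_level))
            leaf = int(rng.integers(spec.leaves_per_category))
            terms.add(f"HP:{cat + 1:02d}{leaf + 1:02d}")
        patients.append(Patient(pid, terms, ofc))
    records.sort()
    return records, patients


def _make_expression(spec: SyntheticSpec, genes: Sequence[GeneModel],
                     truth_genes: dict, rng: np.random.Generator
                     ) -> tuple[str, float]:
    rows: list[tuple[str, str, float, str, float]] = []
    nrpk: dict[tuple[str, str], float] = {}
    for g in genes:
        for stage in spec.stages:
            if rng.random() < spec.zero_fraction:
                val = 0.0
            else:
                val = float(np.exp(rng.normal(spec.expr_log_mean, spec.expr_log_sd)))
            nrpk[(g.symbol, stage)] = val
    expressed = [v for v in nrpk.values() if v > 0]
    provisional = float(np.mean(expressed))
    # planted roles: candidates and crowded decoys well above the cutoff at one
    # stage; low-expression decoys strictly below it at every stage
    high_stage = spec.stages[3]
    for sym, info in truth_genes.items():
        if info["role"] in ("candidate", "decoy_crowded"):
            nrpk[(sym, high_stage)] = 3.0 * provisional
        else:
            for stage in spec.stages:
                nrpk[(sym, stage)] = min(nrpk[(sym, stage)], 0.05 * provisional)
    buf = io.StringIO()
    buf.write("gene\ttranscript_id\tlength_kb\tstage\tnormalized_count\n")
    for g in genes:
        tid, kb = g.transcripts[0]
        for stage in spec.stages:
            count = nrpk[(g.symbol, stage)] * kb
            buf.write(f"{g.symbol}\t{tid}\t{kb:.6f}\t{stage}\t{count:.6f}\n")
    return buf.getvalue(), provisional


def _make_catalog(spec: SyntheticSpec, genome: GenomeBuild,
                  rng: np.random.Generator) -> tuple[list, list[dict]]:
    from .intervals import make_windows

    windows = make_windows(genome, spec.catalog_window)
    hot_idx = sorted(
        rng.choice(len(windows), size=min(spec.n_hotspots, len(windows)),
                   replace=False).tolist()
    )
    hotspots = [windows[i] for i in hot_idx]
    lam = spec.variants_per_mb * spec.catalog_window / 1e6
    catalog: list[tuple[str, int, int, str]] = []
    for i, w in enumerate(windows):
        rate = lam * (spec.hotspot_fold if i in hot_idx else 1.0)
        n = int(rng.poisson(rate))
        span = w.end - w.start
        for _ in range(n):
            L = int(rng.integers(1_000, 10_000))
            s = w.start + int(rng.integers(max(1, span - L)))
            vtype = "loss" if rng.random() < 0.5 else "gain"
            catalog.append((w.chrom, s, s + L, vtype))
    truth = [{"chrom": w.chrom, "start": w.start, "end": w.end} for w in hotspots]
    return catalog, truth


def _make_panel(spec: SyntheticSpec, genes: Sequence[GeneModel],
                truth_genes: dict, rng: np.random.Generator
                ) -> tuple[str, list[str]]:
    candidates = [s for s, i in truth_genes.items() if i["role"] == "candidate"]
    planted_hits = candidates[: spec.n_panel_planted]
    background = [g.symbol for g in genes if g.symbol.startswith("BG")]
    extra = rng.choice(len(background),
                       size=min(spec.n_panel_background, len(background)),
                       replace=False)
    members = planted_hits + sorted(background[i] for i in extra)
    cats = ("non_syndromic", "syndromic", "both")
    buf = io.StringIO()
    buf.write("symbol\tcategory\n")
    for m in members:
        buf.write(f"{m}\t{cats[int(rng.integers(3))]}\n")
    return buf.getvalue(), planted_hits


def _make_ontology(spec: SyntheticSpec) -> str:
    lines = ["# child\tparent"]
    for c in range(spec.n_top_level):
        cat = f"HP:{c + 1:02d}00"
        lines.append(f"{cat}\tHP:0000001")
        for l in range(spec.leaves_per_category):
            lines.append(f"HP:{c + 1:02d}{l + 1:02d}\t{cat}")
    return "\n".join(lines) + "\n"


def generate_all(spec: SyntheticSpec) -> Bundle:
    """Generate the full input bundle; deterministic for a fixed seed."""
    import copy

    spec = copy.deepcopy(spec)  # planted-region placement must not leak back
    rng = np.random.default_rng(spec.seed)
    genome = _make_genome(spec)
    _place_planted(spec, genome, rng)
    genes, truth_genes = _make_genes(spec, genome, rng)
    records, patients = _make_cohort(spec, genome, rng)
    expression_tsv, provisional = _make_expression(spec, genes, truth_genes, rng)
    catalog, hotspots = _make_catalog(spec, genome, rng)
    panel_tsv, panel_planted = _make_panel(spec, genes, truth_genes, rng)
    ontology_tsv = _make_ontology(spec)
    truth = {
        "seed": spec.seed,
        "planted_regions": [
            {"chrom": p.chrom, "start": p.start, "end": p.start + p.length,
             "depth": p.depth, "cnv_type": p.cnv_type, "crowded": p.crowded}
            for p in spec.planted
        ],
        "genes": truth_genes,
        "planted_candidates": [s for s, i in truth_genes.items()
                               if i["role"] == "candidate"],
        "panel_planted_candidates": panel_planted,
        "hotspot_windows": hotspots,
        "provisional_nrpk_cutoff": provisional,
    }
    return Bundle(genome, records, patients, genes, expression_tsv,
                  catalog, panel_tsv, ontology_tsv, truth)


def generate_null_cohort(
    genome: GenomeBuild,
    n: int,
    length_distribution: tuple[float, float],
    seed: int,
    cnv_type: str = "deletion",
) -> tuple[list[CNVRecord], list[Patient]]:
    """Cohort with CNVs placed by the same uniform-over-legal-space rule the
    shuffling null uses; one CNV per patient."""
    rng = np.random.default_rng(seed)
    mu, sd = length_distribution
    if n == 0:
        return [], []
    lengths = np.maximum(500, np.exp(rng.normal(mu, sd, n))).astype(int)
    placements = sample_placements(lengths.tolist(), genome, rng)
    records = [
        CNVRecord(chrom, s, e, f"N{i + 1:03d}", cnv_type)
        for i, (chrom, s, e) in enumerate(placements)
    ]
    patients = [Patient(r.patient_id, set(), "none") for r in records]
    return sorted(records), patients


# ---------------------------------------------------------------------------
# file emission (exact formats of the genome I/O module)


def write_bundle(bundle: Bundle, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in {
        "chrom_sizes": "genome.chrom.sizes", "exclusions": "exclusions.bed",
        "cohort": "cohort.tsv", "annotation": "genes.tsv",
        "expression": "expression.tsv", "catalog": "catalog.tsv",
        "panel": "panel.tsv", "ontology": "ontology.tsv",
        "truth": "truth.json",
    }.items()}
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in bundle.genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with open(paths["exclusions"], "w") as fh:
        for chrom, s, e in bundle.genome.excluded:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    with open(paths["cohort"], "w") as fh:
        write_cohort(bundle.records, bundle.patients, fh)
    with open(paths["annotation"], "w") as fh:
        fh.write("symbol\tchrom\tstart\tend\tgene_type\texon_starts\texon_ends\n")
        for g in bundle.annotation:
            xs = ",".join(str(s) for s, _ in g.exons)
            xe = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.gene_type}\t{xs}\t{xe}\n")
    paths["expression"].write_text(bundle.expression_tsv)
    with open(paths["catalog"], "w") as fh:
        fh.write("chrom\tstart\tend\tvariant_type\n")
        for chrom, s, e, vtype in bundle.catalog:
            fh.write(f"{chrom}\t{s}\t{e}\t{vtype}\n")
    paths["panel"].write_text(bundle.panel_tsv)
    paths["ontology"].write_text(bundle.ontology_tsv)
    paths["truth"].write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    return paths
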