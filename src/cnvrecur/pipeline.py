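"""End-to-end orchestration from a YAML config to the report bundle.

One run, per CNV type, produces: the cohort phenotype-class table, the
per-depth shared-region table, the randomization-test JSON, the candidate
table with filter attrition flags, the panel-enrichment table, the
variability per-window/per-gene/per-candidate tables and the patient x
phenotype-category matrix, plus a run log recording the seed and every
threshold in effect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import genome as gio
from . import intervals as iv
from . import phenotypes as ph
from . import prioritization as pr
from . import randomization as rz
from . import variability as vb
from .errors import CnvRecurError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    chrom_sizes: Path
    exclusions: Path
    cohort: Path
    annotation: Path
    expression: Path
    catalog: Path
    panel: Path
    ontology: Path
    outdir: Path
    dialect: str = "bed_0_half_open"
    permutations: int = 1000
    seed: int = 0
    window_size: int = 1_000_000
    min_patients: int = 2
    max_genes_per_region: int = 5
    nrpk_cutoff: float | None = None
    hvr_quantile: float = 0.999
    enrichment_tail: str = "gt"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        paths = {k: Path(v) for k, v in raw.items()
                 if k in ("chrom_sizes", "exclusions", "cohort", "annotation",
                          "expression", "catalog", "panel", "ontology", "outdir")}
        rest = {k: v for k, v in raw.items() if k not in paths}
        cfg = cls(**paths, **rest)
        for name in ("chrom_sizes", "exclusions", "cohort", "annotation",
                     "expression", "catalog", "panel", "ontology"):
            if not getattr(cfg, name).exists():
                raise CnvRecurError(f"config path {name} does not exist: {getattr(cfg, name)}")
        if cfg.permutations < 2:
            raise CnvRecurError("permutations must be >= 2")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; writes the report bundle and returns a summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("load inputs")
        genome = gio.read_genome(config.chrom_sizes, config.exclusions)
        records, patients = gio.read_cnv_cohort(config.cohort, genome, config.dialect)
        annotation = gio.read_annotation(config.annotation)
        expression = pr.read_expression(config.expression)
        panel = enr.read_panel(config.panel)
        ontology = ph.load_ontology(config.ontology)
        catalog_df = pd.read_csv(config.catalog, sep="\t")
        catalog = list(catalog_df.itertuples(index=False, name=None))
    except CnvRecurError as exc:
        _abort(out, "load inputs", exc)
        raise

    # cohort phenotype-class table
    class_counts = pd.Series([p.ofc_class for p in patients]).value_counts()
    class_counts.rename_axis("ofc_class").to_frame("n_patients").to_csv(
        out / "cohort_classes.tsv", sep="\t")
    summary["n_patients"] = len(patients)

    try:
        pcfg = pr.PrioritizationConfig(config.min_patients, config.max_genes_per_region,
                                       config.nrpk_cutoff)
        cutoff = (pcfg.nrpk_cutoff if pcfg.nrpk_cutoff is not None
                  else pr.expression_cutoff(expression))
        summary["nrpk_cutoff"] = cutoff
    except CnvRecurError as exc:
        _abort(out, "expression cutoff", exc)
        raise

    # variability model is shared by both CNV types
    try:
        windows = iv.make_windows(genome, config.window_size)
        counts = iv.count_overlaps(windows, [(c, s, e) for c, s, e, _ in catalog])
        model = vb.window_zscores(counts)
        pd.DataFrame(
            [{"chrom": v.window.chrom, "start": v.window.start, "end": v.window.end,
              "count": v.variant_count, "z": v.z} for v in model.windows]
        ).to_csv(out / "variability_windows.tsv", sep="\t", index=False)
    except CnvRecurError as exc:
        _abort(out, "variability", exc)
        raise

    for cnv_type in gio.CNV_TYPES:
        typed = [r for r in records if r.cnv_type == cnv_type]
        summary[cnv_type] = _run_one_type(
            config, out, cnv_type, typed, records, annotation, expression,
            panel, genome, pcfg, model)

    # phenotype matrix (shared across types)
    matrix = ph.phenotype_matrix(patients, ontology)
    matrix.to_csv(out / "phenotype_matrix.tsv", sep="\t")
    summary["phenotype_categories"] = list(matrix.columns)

    (out / "run_log.json").write_text(json.dumps({
        "seed": config.seed, "permutations": config.permutations,
        "window_size": config.window_size, "min_patients": config.min_patients,
        "max_genes_per_region": config.max_genes_per_region,
        "nrpk_cutoff": cutoff, "hvr_quantile": config.hvr_quantile,
        "enrichment_tail": config.enrichment_tail, "dialect": config.dialect,
    }, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def _run_one_type(config, out, cnv_type, typed, records, annotation, expression,
                  panel, genome, pcfg, model) -> dict:
    res: dict = {}
    try:
        regions = iv.coverage_segments(typed, genome)
        overlap = rz.summarize_overlaps(regions)
        pd.DataFrame(
            [{"depth": d, "n_regions": overlap.count_by_depth[d],
              "mean_length_bp": overlap.mean_length_by_depth[d]}
             for d in overlap.count_by_depth]
        ).to_csv(out / f"overlap_table_{cnv_type}.tsv", sep="\t", index=False)
        res["n_cnvs"] = len(typed)
        res["n_shared_regions"] = overlap.n_shared
        res["mean_overlap"] = overlap.mean_overlap

        if typed:
            rand = rz.randomization_test(typed, genome, config.permutations, config.seed)
            rand_report = {
                "R": rand.R, "mu_bar": rand.mu_bar, "sigma": rand.sigma,
                "z_real": rand.z_real, "empirical_p": rand.empirical_p,
                "p_is_upper_bound": rand.p_is_upper_bound,
                "normality_p": rand.normality_p,
            }
            (out / f"randomization_{cnv_type}.json").write_text(
                json.dumps(rand_report, indent=1))
            pd.DataFrame({"mu_i": rand.mu, "z_i": rand.z}).to_csv(
                out / f"randomization_{cnv_type}_permutations.tsv", sep="\t",
                index=False)
            res["randomization"] = rand_report

        cands = pr.prioritize(records, annotation, expression, pcfg, cnv_type)
        table = pr.candidates_table(cands)
        table.to_csv(out / f"candidates_{cnv_type}.tsv", sep="\t", index=False)
        selected = [c.gene for c in cands if c.is_candidate]
        res["n_candidates"] = len(selected)
        res["candidates"] = selected

        universe = [g.symbol for g in annotation
                    if any(r.chrom == g.chrom and r.start < g.end and r.end > g.start
                           for r in typed)]
        if selected and universe:
            N, K, n, k, hits = enr.panel_intersection(selected, panel, universe)
            e = enr.fold_enrichment(N, K, n, k, tail=config.enrichment_tail)
            pd.DataFrame([{
                "cnv_type": cnv_type, "N": N, "K": K, "n": n, "k": k,
                "fold": round(e.fold, 2), "p": e.p,
                "panel_hits": ";".join(hits),
            }]).to_csv(out / f"enrichment_{cnv_type}.tsv", sep="\t", index=False)
            res["enrichment"] = {"N": N, "K": K, "n": n, "k": k,
                                 "fold": e.fold, "p": e.p, "hits": hits}

        # per-candidate variability and per-gene catalog burden
        gene_by_symbol = {g.symbol: g for g in annotation}
        rows = []
        for sym in selected:
            g = gene_by_symbol[sym]
            z = vb.region_variability((g.chrom, g.start, g.end), model)
            rows.append({"gene": sym, "z": z if z is not None else "NA",
                         "assessable": z is not None})
        pd.DataFrame(rows).to_csv(out / f"candidate_variability_{cnv_type}.tsv",
                                  sep="\t", index=False)
    except CnvRecurError as exc:
        _abort(out, f"{cnv_type} analysis", exc)
        raise
    return res


def _abort(out: Path, stage: str, exc: Exception) -> None:
    report = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
    Path(out).mkdir(parents=True, exist_ok=True)
    (Path(out) / "error.json").write_text(json.dumps(report, indent=1))
    logger.error("stage %r failed: %s", stage, exc)
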