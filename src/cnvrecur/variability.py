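"""Windowed genomic-variability z-scores from a population SV catalog.

The genome is tiled with fixed windows (gap-filtered upstream), each window's
structural-variant count c_i is log10-transformed, and

    mu    = mean of log10(c_i) over retained windows
    sigma = sample SD (n - 1 denominator) of the log10 counts
    z_i   = (log10(c_i) - mu) / sigma

Zero-count windows are excluded from the retained set W (log10(0) undefined);
their number is logged. A shared CNV region or a gene spanning several
windows gets a single score: mean of the raw counts over the overlapped
windows, then log10, then the genome-wide standardization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .genome import GeneModel
from .intervals import Window

logger = logging.getLogger(__name__)

CATALOG_TYPES = {"loss": "deletion", "gain": "duplication"}


@dataclass
class VariabilityWindow:
    window: Window
    variant_count: int
    log_count: float
    z: float


@dataclass
class VariabilityModel:
    """Genome-wide standardization constants plus the retained windows."""

    mu: float
    sigma: float
    windows: list[VariabilityWindow]
    n_zero_dropped: int

    def score_count(self, mean_count: float) -> float:
        return (math.log10(mean_count) - self.mu) / self.sigma


def window_zscores(counts: Mapping[Window, int]) -> VariabilityModel:
    """Standardize log10 variant counts over windows with c_i > 0."""
    retained = [(w, c) for w, c in counts.items() if c > 0]
    n_zero = len(counts) - len(retained)
    if n_zero:
        logger.info("dropped %d zero-count windows before standardization", n_zero)
    if len(retained) < 2:
        raise ValidationError("need >= 2 windows with nonzero counts")
    logs = np.log10([c for _, c in retained])
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0:
        raise DegenerateInputError("all window counts equal; variability sigma = 0")
    vws = [
        VariabilityWindow(w, c, float(l), float((l - mu) / sigma))
        for (w, c), l in zip(retained, logs)
    ]
    vws.sort(key=lambda v: v.window.index)
    return VariabilityModel(mu, sigma, vws, n_zero)


def region_variability(
    region: tuple[str, int, int], model: VariabilityModel
) -> float | None:
    """Single z for a region; None when it overlaps no retained window
    ("not assessable", e.g. telomeric loci whose windows were excluded)."""
    chrom, start, end = region
    hits = [
        v.variant_count
        for v in model.windows
        if v.window.chrom == chrom and v.window.start < end and v.window.end > start
    ]
    if not hits:
        return None
    return model.score_count(float(np.mean(hits)))


@dataclass
class GeneCNVBurden:
    gene: str
    n_genic_del: int
    n_exonic_del: int
    n_genic_dup: int
    n_exonic_dup: int


def gene_cnv_burden(
    gene: GeneModel, catalog: Sequence[tuple[str, int, int, str]]
) -> GeneCNVBurden:
    """Catalog variants overlapping the gene span (genic) / any exon (exonic),
    split by loss/gain; other variant types are ignored with a logged count."""
    genic = {"deletion": 0, "duplication": 0}
    exonic = {"deletion": 0, "duplication": 0}
    ignored = 0
    for chrom, s, e, vtype in catalog:
        kind = CATALOG_TYPES.get(vtype)
        if kind is None:
            ignored += 1
            continue
        if chrom != gene.chrom or s >= gene.end or e <= gene.start:
            continue
        genic[kind] += 1
        if any(s < xe and e > xs for xs, xe in gene.exons):
            exonic[kind] += 1
    if ignored:
        logger.info("gene_cnv_burden(%s): ignored %d catalog rows of unsupported type",
                    gene.symbol, ignored)
    return GeneCNVBurden(gene.symbol, genic["deletion"], exonic["deletion"],
                         genic["duplication"], exonic["duplication"])


def hypervariable_flag(
    model: VariabilityModel, quantile: float = 0.999
) -> dict[Window, bool]:
    """Flag hypervariable windows: z above the given quantile of the z values."""
    if not (0 < quantile < 1):
        raise ValidationError("quantile must be in (0, 1)")
    zs = np.array([v.z for v in model.windows])
    threshold = float(np.quantile(zs, quantile))
    return {v.window: bool(v.z > threshold) for v in model.windows}
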