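"""Overlap summaries and the genome-shuffling permutation test.

The null model relocates each observed CNV, preserving its length, to a
uniformly drawn legal start position anywhere in the gap-free genome,
independently of the other CNVs (shuffled intervals may overlap one another).
For each of the R shuffled lists the coverage profile is segmented and the
mean overlap depth mu_i over all depth >= 1 segments recorded; the observed
list's z-score is

    z = (mu_obs - mean(mu_i)) / sd(mu_i)        (sample SD, n-1)

and significance is the empirical fraction of shuffled lists whose z matches
or exceeds it (reported as an upper bound 1/R when none does, since the
permutation distribution is typically non-normal by Shapiro-Wilk).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .genome import CNVRecord, GenomeBuild
from .intervals import OverlapRegion, coverage_segments


@dataclass
class OverlapSummary:
    """Per-depth region counts and mean lengths (the shared-region table)."""

    count_by_depth: dict[int, int]
    mean_length_by_depth: dict[int, float]
    n_regions: int
    n_shared: int          # regions with depth >= 2
    mean_overlap: float | None  # mean depth over all depth >= 1 regions


def summarize_overlaps(regions: Sequence[OverlapRegion]) -> OverlapSummary:
    count: dict[int, int] = {}
    length_sum: dict[int, int] = {}
    for r in regions:
        count[r.depth] = count.get(r.depth, 0) + 1
        length_sum[r.depth] = length_sum.get(r.depth, 0) + r.length
    n = len(regions)
    mean_len = {d: length_sum[d] / count[d] for d in count}
    n_shared = sum(c for d, c in count.items() if d >= 2)
    mean_overlap = (sum(d * c for d, c in count.items()) / n) if n else None
    return OverlapSummary(dict(sorted(count.items())), mean_len, n, n_shared, mean_overlap)


@dataclass
class RandomizationResult:
    R: int
    mu: np.ndarray           # per-permutation mean overlaps mu_i
    mu_bar: float            # overall mean of the mu_i
    sigma: float             # overall sample SD of the mu_i
    z: np.ndarray            # standardized permutation scores
    z_real: float
    empirical_p: float
    p_is_upper_bound: bool   # True when no permutation reached z_real
    normality_p: float       # Shapiro-Wilk p of the z_i
    seed: int


def sample_placements(
    lengths: Sequence[int],
    genome: GenomeBuild,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place each length uniformly over all legal start positions genome-wide.

    Legality: the placed interval lies within a chromosome and intersects no
    excluded interval. The draw is exact — gap-free stretches are weighted by
    their number of legal starts for the given length, then the start is drawn
    uniformly within the chosen stretch — so placements are mutually
    independent and uniform over the legal space. A length exceeding every
    gap-free stretch is an error.
    """
    stretches = [
        (chrom, s, e)
        for chrom, _ in genome.chromosomes
        for s, e in genome.legal_stretches(chrom)
    ]
    out: list[tuple[str, int, int]] = []
    cache: dict[int, np.ndarray] = {}
    for L in lengths:
        if L not in cache:
            starts = np.array([max(0, (e - s) - L + 1) for _, s, e in stretches], dtype=np.int64)
            cache[L] = np.cumsum(starts)
        cum = cache[L]
        total = int(cum[-1]) if len(cum) else 0
        if total == 0:
            raise ValidationError(f"interval of length {L} fits in no gap-free stretch")
        pick = int(rng.integers(total))
        idx = int(np.searchsorted(cum, pick, side="right"))
        offset = pick - (int(cum[idx - 1]) if idx else 0)
        chrom, s, _ = stretches[idx]
        out.append((chrom, s + offset, s + offset + L))
    return out


def shuffle_intervals(
    intervals: Sequence[CNVRecord],
    genome: GenomeBuild,
    rng: np.random.Generator | int,
) -> list[CNVRecord]:
    """Relocate each interval, preserving its length, via :func:`sample_placements`.

    Shuffled intervals may overlap one another and may change chromosome
    (relocation probability proportional to legal space).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    placed = sample_placements([r.length for r in intervals], genome, rng)
    return [
        CNVRecord(chrom, s, e, r.patient_id, r.cnv_type, r.source)
        for (chrom, s, e), r in zip(placed, intervals)
    ]


def randomization_test(
    intervals: Sequence[CNVRecord],
    genome: GenomeBuild,
    R: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Permutation test of overlap non-randomness (see module docstring)."""
    if R < 2:
        raise ValidationError("R must be >= 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(R)
    mu = np.empty(R)
    for i in range(R):
        shuffled = shuffle_intervals(intervals, genome, np.random.default_rng(children[i]))
        summary = summarize_overlaps(coverage_segments(shuffled))
        mu[i] = summary.mean_overlap if summary.mean_overlap is not None else 0.0
    mu_bar = float(np.mean(mu))
    sigma = float(np.std(mu, ddof=1))
    if sigma == 0:
        raise DegenerateInputError(
            "null distribution is degenerate (sigma = 0); increase R or use a larger genome"
        )
    z = (mu - mu_bar) / sigma
    obs = summarize_overlaps(coverage_segments(intervals)).mean_overlap
    if obs is None:
        raise ValidationError("observed interval list is empty")
    z_real = (obs - mu_bar) / sigma
    exceed = int(np.sum(z >= z_real))
    if exceed == 0:
        empirical_p, upper = 1.0 / R, True
    else:
        empirical_p, upper = exceed / R, False
    normality_p = normality_check(z)
    return RandomizationResult(R, mu, mu_bar, sigma, z, float(z_real),
                               empirical_p, upper, normality_p, seed)


def normality_check(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value; defined for 3 <= n <= 5000 samples."""
    values = np.asarray(values, dtype=float)
    if not (3 <= len(values) <= 5000):
        raise ValidationError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise DegenerateInputError("constant vector has no defined normality p-value")
    return float(stats.shapiro(values).pvalue)
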