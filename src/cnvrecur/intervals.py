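"""Core genomic interval arithmetic.

Depth segmentation follows genomeCoverageBed semantics: the union of the
input intervals is partitioned into maximal segments of constant coverage
depth, where depth counts covering CNV *intervals* (a patient contributing two
intervals over a segment counts twice in depth but once in ``patient_ids``).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .genome import CNVRecord, GeneModel, GenomeBuild


@dataclass
class OverlapRegion:
    """Maximal constant-depth segment of the CNV coverage profile."""

    chrom: str
    start: int
    end: int
    depth: int
    patient_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError("OverlapRegion depth must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    index: int


def coverage_segments(
    intervals: Sequence[CNVRecord], genome: GenomeBuild | None = None
) -> list[OverlapRegion]:
    """Partition the union of intervals into maximal constant-depth segments.

    Depth-0 stretches are not emitted. Each segment is annotated with the
    distinct patient ids of the intervals covering it, so the companion
    :func:`collapse_contributors` is a no-op re-derivation kept for symmetry
    with the two-step tool chain it mirrors.
    """
    if genome is not None:
        sizes = genome.sizes
        for r in intervals:
            if r.chrom not in sizes:
                raise ValidationError(f"interval on unknown chromosome {r.chrom}")
    out: list[OverlapRegion] = []
    by_chrom: dict[str, list[CNVRecord]] = {}
    for r in intervals:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        events: list[tuple[int, int, int]] = []  # (pos, +1/-1, interval idx)
        for i, r in enumerate(by_chrom[chrom]):
            events.append((r.start, +1, i))
            events.append((r.end, -1, i))
        events.sort(key=lambda t: t[0])
        active: set[int] = set()
        prev = None
        j = 0
        while j < len(events):
            pos = events[j][0]
            if prev is not None and active and pos > prev:
                pids = frozenset(by_chrom[chrom][i].patient_id for i in active)
                out.append(OverlapRegion(chrom, prev, pos, len(active), pids))
            while j < len(events) and events[j][0] == pos:
                _, delta, idx = events[j]
                if delta > 0:
                    active.add(idx)
                else:
                    active.discard(idx)
                j += 1
            prev = pos
    return out


def collapse_contributors(
    regions: Sequence[OverlapRegion], intervals: Sequence[CNVRecord]
) -> list[OverlapRegion]:
    """Annotate each region with distinct patient ids of overlapping intervals."""
    out = []
    for reg in regions:
        pids = set()
        for r in intervals:
            if r.chrom == reg.chrom and r.start < reg.end and r.end > reg.start:
                pids.add(r.patient_id)
        if not pids:
            raise ValidationError(
                f"region {reg.chrom}:{reg.start}-{reg.end} matched no interval "
                "(chromosome mismatch with the producing interval list?)"
            )
        out.append(OverlapRegion(reg.chrom, reg.start, reg.end, reg.depth, frozenset(pids)))
    return out


def make_windows(genome: GenomeBuild, window_size: int) -> list[Window]:
    """Tile each chromosome with fixed windows; drop windows touching exclusions.

    The trailing remainder window per chromosome is kept (it is shorter than
    ``window_size``). A window intersecting any excluded interval by >= 1 base
    is removed.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be > 0")
    windows: list[Window] = []
    index = 0
    for chrom, length in genome.chromosomes:
        excl = genome.excluded_on(chrom)
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            if any(s < end and e > start for s, e in excl):
                continue
            windows.append(Window(chrom, start, end, index))
            index += 1
    return windows


def count_overlaps(
    windows: Sequence[Window], features: Iterable[tuple[str, int, int]]
) -> dict[Window, int]:
    """Count features overlapping each window by >= 1 base.

    A feature spanning several windows increments each of them.
    """
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for ws in by_chrom.values():
        ws.sort(key=lambda w: w.start)
    starts = {c: [w.start for w in ws] for c, ws in by_chrom.items()}
    counts = {w: 0 for w in windows}
    for chrom, fs, fe in features:
        ws = by_chrom.get(chrom)
        if not ws:
            continue
        # first window that could overlap: last window starting before fe
        i = bisect_right(starts[chrom], fs) - 1
        i = max(i, 0)
        for w in ws[i:]:
            if w.start >= fe:
                break
            if w.end > fs:
                counts[w] += 1
    return counts


def genes_in_interval(
    interval: tuple[str, int, int], annotation: Sequence[GeneModel]
) -> list[GeneModel]:
    """Genes whose span overlaps the interval by >= 1 base, in genomic order."""
    chrom, start, end = interval
    hits = [g for g in annotation if g.chrom == chrom and g.start < end and g.end > start]
    return sorted(hits, key=lambda g: (g.start, g.end, g.symbol))
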