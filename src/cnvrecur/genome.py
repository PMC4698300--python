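"""Genome definition, cohort and annotation I/O.

All coordinates are normalized to 0-based half-open intervals at read time.
Input tables written in the UCSC browser's 1-based fully-closed style are
converted by passing ``dialect="ucsc_1_inclusive"`` to :func:`read_cnv_cohort`;
everything downstream sees a single convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

CNV_TYPES = ("deletion", "duplication")
DIALECTS = ("bed_0_half_open", "ucsc_1_inclusive")

#: orofacial-cleft classes; a minor cleft combined with a main phenotype is
#: ascribed to the main group (CL, CLP, CP take precedence, in that order of
#: severity grouping used for the cohort summary table).
OFC_CLASSES = (
    "CL",
    "CLP",
    "CP",
    "bifid_uvula",
    "oral_cleft_unspecified",
    "alveolar_ridge_cleft",
    "cleft_lower_lip",
    "facial_cleft",
    "none",
)
_MAIN_OFC = ("CLP", "CL", "CP")


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome sizes plus excluded (unplaceable) intervals.

    Excluded intervals model assembly gaps, alternative haplotypes and random
    contigs; they are stored merged and non-overlapping per chromosome.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    excluded: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names in genome build")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
        for chrom, start, end in self.excluded:
            if chrom not in sizes:
                raise ValidationError(f"excluded interval on unknown chromosome {chrom}")
            if not (0 <= start < end <= sizes[chrom]):
                raise ValidationError(
                    f"excluded interval {chrom}:{start}-{end} outside chromosome bounds"
                )

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def excluded_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.excluded if c == chrom]

    def legal_stretches(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal gap-free stretches of a chromosome (complement of exclusions)."""
        length = self.sizes[chrom]
        out, pos = [], 0
        for s, e in merge_intervals(self.excluded_on(chrom)):
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append((pos, length))
        return out


@dataclass(frozen=True, order=True)
class CNVRecord:
    """One patient's deletion or duplication, 0-based half-open."""

    chrom: str
    start: int
    end: int
    patient_id: str
    cnv_type: str
    source: str = "synthetic"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"CNV {self.chrom}:{self.start}-{self.end} ({self.patient_id}): start >= end"
            )
        if self.cnv_type not in CNV_TYPES:
            raise ValidationError(f"unknown cnv_type {self.cnv_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Patient:
    patient_id: str
    phenotype_terms: set[str] = field(default_factory=set)
    ofc_class: str = "none"

    def __post_init__(self):
        if self.ofc_class not in OFC_CLASSES:
            raise ValidationError(f"unknown OFC class {self.ofc_class!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon structure and per-transcript lengths (kb)."""

    symbol: str
    chrom: str
    start: int
    end: int
    gene_type: str = "coding"
    exons: tuple[tuple[int, int], ...] = ()
    transcripts: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"gene {self.symbol}: exon [{s},{e}) outside span [{self.start},{self.end})"
                )
        for tid, kb in self.transcripts:
            if kb <= 0:
                raise ValidationError(f"gene {self.symbol}: transcript {tid} length <= 0")


# ---------------------------------------------------------------------------
# readers


def _lines(source) -> Iterable[tuple[int, str]]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if line and not line.startswith("#"):
            yield i, line


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent intervals into a sorted disjoint list."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def read_genome(chrom_sizes_source, exclusions_source=None, name: str = "custom") -> GenomeBuild:
    """Read a two-column chrom.sizes file and an optional BED3 exclusions file."""
    chroms: list[tuple[str, int]] = []
    for lineno, line in _lines(chrom_sizes_source):
        parts = line.split()
        if len(parts) < 2:
            raise ParseError("expected 'name length'", lineno)
        try:
            chroms.append((parts[0], int(parts[1])))
        except ValueError:
            raise ParseError(f"non-integer chromosome length {parts[1]!r}", lineno)
    sizes = dict(chroms)

    per_chrom: dict[str, list[tuple[int, int]]] = {}
    if exclusions_source is not None:
        for lineno, line in _lines(exclusions_source):
            parts = line.split()
            if len(parts) < 3:
                raise ParseError("expected BED3 'chrom start end'", lineno)
            chrom = parts[0]
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", lineno)
            if chrom not in sizes:
                raise ValidationError(
                    f"exclusion on chromosome {chrom} absent from chrom.sizes (line {lineno})"
                )
            per_chrom.setdefault(chrom, []).append((s, e))

    excluded = tuple(
        (chrom, s, e)
        for chrom in sizes
        for s, e in merge_intervals(per_chrom.get(chrom, []))
    )
    return GenomeBuild(name=name, chromosomes=tuple(chroms), excluded=excluded)


def read_cnv_cohort(
    table_source,
    genome: GenomeBuild,
    dialect: str = "bed_0_half_open",
) -> tuple[list[CNVRecord], list[Patient]]:
    """Read a cohort TSV: patient_id, cnv_type, chrom, start, end, phenotypes.

    ``phenotypes`` is a ``;``-separated list of ontology term ids and may be
    empty. One :class:`Patient` is emitted per distinct patient id; records are
    returned sorted by (chrom, start, end).
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown coordinate dialect {dialect!r}")
    sizes = genome.sizes
    records: list[CNVRecord] = []
    patients: dict[str, Patient] = {}
    bad_chroms: list[str] = []

    for lineno, line in _lines(table_source):
        parts = line.split("\t")
        if parts[0] == "patient_id":  # header
            continue
        if len(parts) < 5:
            raise ParseError("expected >= 5 tab-separated columns", lineno)
        pid, cnv_type, chrom = parts[0], parts[1], parts[2]
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError:
            raise ParseError("non-integer coordinates", lineno)
        if dialect == "ucsc_1_inclusive":
            start -= 1
        if cnv_type not in CNV_TYPES:
            raise ValidationError(f"unknown cnv_type {cnv_type!r} (line {lineno})")
        if chrom not in sizes:
            bad_chroms.append(f"line {lineno}: {pid} {chrom}:{start}-{end}")
            continue
        if start >= end:
            raise ValidationError(
                f"line {lineno}: start >= end after normalization ({chrom}:{start}-{end})"
            )
        source = parts[6] if len(parts) > 6 else "synthetic"
        records.append(CNVRecord(chrom, start, end, pid, cnv_type, source))
        terms = set()
        if len(parts) > 5 and parts[5]:
            terms = {t for t in parts[5].split(";") if t}
        if pid not in patients:
            patients[pid] = Patient(pid, set())
        patients[pid].phenotype_terms |= terms

    if bad_chroms:
        raise ValidationError(
            "records on chromosomes absent from the genome build:\n" + "\n".join(bad_chroms)
        )
    for p in patients.values():
        p.ofc_class = classify_ofc(p.phenotype_terms)
    records.sort()
    return records, list(patients.values())


#: phenotype term ids the cohort format uses for OFC classes (synthetic and
#: curated tables alike tag patients with these literal class labels).
_OFC_TERM_TO_CLASS = {c: c for c in OFC_CLASSES if c != "none"}


def classify_ofc(terms: set[str]) -> str:
    """Assign the OFC class; combined minor+main phenotypes go to the main group."""
    present = [c for c in _OFC_TERM_TO_CLASS if c in terms]
    for main in _MAIN_OFC:
        if main in present:
            return main
    return present[0] if present else "none"


def read_annotation(source) -> list[GeneModel]:
    """Read genes from BED12 or the tabular format.

    Tabular columns: ``symbol chrom start end gene_type exon_starts exon_ends``
    (exon columns comma-separated; when absent, exons default to the full span
    with a logged warning). Transcript length defaults to summed exon length.
    """
    genes: list[GeneModel] = []
    for lineno, line in _lines(source):
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0] in ("symbol", "track"):
            continue
        if len(parts) == 12 and parts[9].isdigit():
            genes.append(_parse_bed12(parts, lineno))
        else:
            genes.append(_parse_tabular_gene(parts, lineno))
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end))


def _parse_bed12(parts: Sequence[str], lineno: int) -> GeneModel:
    chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
    n_blocks = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
    offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError("blockCount inconsistent with blockSizes/blockStarts", lineno)
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    if exons[-1][1] > end or exons[0][0] != start:
        raise ParseError("block structure inconsistent with span", lineno)
    kb = sum(s for s in sizes) / 1000.0
    return GeneModel(name, chrom, start, end, "coding", exons, ((name + ".t1", kb),))


def _parse_tabular_gene(parts: Sequence[str], lineno: int) -> GeneModel:
    if len(parts) < 4:
        raise ParseError("expected >= 4 columns for tabular gene", lineno)
    symbol, chrom, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
    gene_type = parts[4] if len(parts) > 4 else "coding"
    if len(parts) > 6 and parts[5] and parts[6]:
        starts = [int(x) for x in parts[5].rstrip(",").split(",")]
        ends = [int(x) for x in parts[6].rstrip(",").split(",")]
        exons = tuple(zip(starts, ends))
    else:
        logger.warning("gene %s (line %d): no exon columns, exons default to full span",
                       symbol, lineno)
        exons = ((start, end),)
    kb = sum(e - s for s, e in exons) / 1000.0
    return GeneModel(symbol, chrom, start, end, gene_type, exons,
                     ((symbol + ".t1", kb),))


# ---------------------------------------------------------------------------
# writers (always BED-style 0-based half-open)


def write_cohort(records: Iterable[CNVRecord], patients: Iterable[Patient], out: TextIO) -> None:
    by_id = {p.patient_id: p for p in patients}
    out.write("patient_id\tcnv_type\tchrom\tstart\tend\tphenotypes\tsource\n")
    for r in records:
        terms = ";".join(sorted(by_id[r.patient_id].phenotype_terms)) if r.patient_id in by_id else ""
        out.write(f"{r.patient_id}\t{r.cnv_type}\t{r.chrom}\t{r.start}\t{r.end}\t{terms}\t{r.source}\n")


def write_bed(intervals: Iterable[tuple[str, int, int]], out: TextIO) -> None:
    for chrom, s, e in intervals:
        out.write(f"{chrom}\t{s}\t{e}\n")
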