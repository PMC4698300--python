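"""Phenotype-ontology mapping and penetrance summaries.

Patient phenotype terms are mapped to the top level of an HPO-style ontology
(the direct children of the root act as broad categories). A term under
several top-level categories, via multiple inheritance, contributes to all of
them. Unknown terms are recorded as unmapped rather than fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .genome import CNVRecord, GeneModel, Patient

logger = logging.getLogger(__name__)


@dataclass
class OntologyGraph:
    """DAG of phenotype terms; edges run child -> parent."""

    graph: nx.DiGraph
    root: str
    top_level: frozenset[str]
    labels: dict[str, str]

    def __contains__(self, term: str) -> bool:
        return term in self.graph


def _build(graph: nx.DiGraph, labels: dict[str, str]) -> OntologyGraph:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(f"ontology contains a cycle: {cycle}")
    roots = [n for n in graph if graph.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValidationError(f"ontology must have exactly one root, found {sorted(roots)}")
    root = roots[0]
    top = frozenset(c for c, p in graph.in_edges(root))
    if not top:
        raise ValidationError("root has no children; no top-level categories")
    for n in graph:
        if n != root and not nx.has_path(graph, n, root):
            raise ValidationError(f"term {n} does not reach the root")
    return OntologyGraph(graph, root, top, labels)


def load_ontology(source) -> OntologyGraph:
    """Load an OBO file (id/name/is_a subset) or a two-column child-parent TSV."""
    path = Path(source) if not hasattr(source, "read") else None
    if path is not None and path.suffix == ".obo":
        import obonet

        g = obonet.read_obo(path)
        # obonet edges already run child -> parent for is_a
        dag = nx.DiGraph()
        labels = {}
        for n, data in g.nodes(data=True):
            dag.add_node(n)
            labels[n] = data.get("name", n)
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                dag.add_edge(child, parent)
        return _build(dag, labels)

    dag = nx.DiGraph()
    labels: dict[str, str] = {}
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"ontology TSV needs 'child<TAB>parent': {line!r}")
        child, parent = parts[0], parts[1]
        dag.add_edge(child, parent)
        labels.setdefault(child, child)
        labels.setdefault(parent, parent)
    return _build(dag, labels)


def map_to_top_level(term_id: str, ontology: OntologyGraph) -> set[str]:
    """All top-level ancestors reachable from a term (itself, if top-level)."""
    if term_id not in ontology:
        return set()
    if term_id == ontology.root:
        logger.info("root term maps to no category")
        return set()
    reachable = nx.descendants(ontology.graph, term_id) | {term_id}
    return set(reachable & ontology.top_level)


def phenotype_matrix(
    patients: Sequence[Patient],
    ontology: OntologyGraph,
    exclude_ofc_terms: bool = True,
) -> pd.DataFrame:
    """Patients x top-level-category presence matrix.

    The OFC class labels themselves (the cohort's selection phenotype) are
    excluded by default to avoid tautological columns. Terms absent from the
    ontology are counted and logged as unmapped.
    """
    from .genome import OFC_CLASSES

    cats = sorted(ontology.top_level)
    rows = []
    unmapped = 0
    for p in patients:
        present: set[str] = set()
        for term in p.phenotype_terms:
            if exclude_ofc_terms and term in OFC_CLASSES:
                continue
            if term not in ontology:
                unmapped += 1
                continue
            present |= map_to_top_level(term, ontology)
        rows.append([c in present for c in cats])
    if unmapped:
        logger.info("phenotype_matrix: %d term annotations unmapped", unmapped)
    return pd.DataFrame(rows, index=[p.patient_id for p in patients], columns=cats)


def penetrance_summary(
    gene: GeneModel,
    cohort: tuple[Sequence[CNVRecord], Sequence[Patient]],
    background_carriers: int,
) -> tuple[int, int, float | None]:
    """(OFC carriers, non-OFC carriers, ratio) for CNVs over a gene.

    OFC carriers are cohort patients with an OFC class and >= 1 CNV
    overlapping the gene span; ``background_carriers`` counts individuals with
    CNVs over the gene but no OFC phenotype. The ratio is None when there are
    no background carriers.
    """
    records, patients = cohort
    ofc_ids = {p.patient_id for p in patients if p.ofc_class != "none"}
    carriers = {
        r.patient_id
        for r in records
        if r.chrom == gene.chrom and r.start < gene.end and r.end > gene.start
    }
    n_ofc = len(carriers & ofc_ids)
    n_non = background_carriers + len(carriers - ofc_ids)
    ratio = (n_ofc / n_non) if n_non else None
    return n_ofc, n_non, ratio
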