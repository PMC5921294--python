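"""GAF annotation parsing.

Reads Gene Association Files (GAF 2.0/2.1/2.2) into per-namespace maps from
gene identifier to the set of directly annotated GO terms.  Annotation
propagation up the hierarchy is deliberately NOT done here — it is the job
of the similarity measures, each of which has its own propagation policy.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .ontology import OntologyGraph, namespace_root

logger = logging.getLogger(__name__)

#: GAF aspect column codes -> namespace codes.
ASPECT_CODES = {"P": "BP", "C": "CC", "F": "MF"}

# GAF is 1-based column 2 = DB object ID, 3 = symbol, 4 = qualifier,
# 5 = GO ID, 7 = evidence code, 9 = aspect.
_COL_OBJECT_ID = 1
_COL_SYMBOL = 2
_COL_QUALIFIER = 3
_COL_GO_ID = 4
_COL_EVIDENCE = 6
_COL_ASPECT = 8


class MissingGene:
    """Singleton marker for genes absent from an annotation set."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "MISSING_GENE"

    def __bool__(self) -> bool:
        return False


MISSING_GENE = MissingGene()


@dataclass
class AnnotationSet:
    """Direct gene -> term-set annotations for a single namespace.

    Invariants: every term exists in the companion ontology and carries the
    set's namespace; the namespace root never appears; genes whose surviving
    term set is empty are absent entirely.
    """

    namespace: str
    gene_terms: dict[str, set[str]]
    evidence_policy: str = "IEA+"
    #: direct evidence codes per (gene, term); populated when parsed from GAF.
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_terms)

    def genes(self) -> list[str]:
        return sorted(self.gene_terms)


def parse_gaf(
    path,
    graph: OntologyGraph,
    namespace: str,
    evidence_policy: str = "IEA+",
    id_column: str = "object_id",
) -> AnnotationSet:
    """Parse a GAF file into an :class:`AnnotationSet`.

    Keeps rows of the requested namespace only, resolves ``alt_id``
    accessions, drops NOT-qualified rows and terms unknown to *graph*.
    ``evidence_policy='IEA-'`` additionally drops electronically inferred
    (IEA) annotations.  The namespace root is removed from every gene's set,
    and genes left with nothing are dropped.

    *id_column* selects the gene identifier: ``object_id`` (GAF column 2,
    e.g. SGD or UniProt accessions) or ``symbol`` (column 3).
    """
    if namespace not in ("BP", "CC", "MF"):
        raise ValueError(f"unknown namespace {namespace!r}")
    if evidence_policy not in ("IEA+", "IEA-"):
        raise ValueError(f"unknown evidence policy {evidence_policy!r}")
    id_idx = {"object_id": _COL_OBJECT_ID, "symbol": _COL_SYMBOL}[id_column]
    root = namespace_root(graph, namespace)
    gene_terms: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], str] = {}
    skipped = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("!"):
                continue
            if len(row) < 9:
                skipped += 1
                logger.warning("skipping malformed GAF row %d (%d columns)",
                               lineno, len(row))
                continue
            if ASPECT_CODES.get(row[_COL_ASPECT]) != namespace:
                continue
            qualifier = row[_COL_QUALIFIER]
            if "NOT" in qualifier.split("|"):
                continue
            code = row[_COL_EVIDENCE]
            if evidence_policy == "IEA-" and code == "IEA":
                continue
            try:
                term = graph.resolve(row[_COL_GO_ID])
            except KeyError:
                continue
            if graph.terms[term]["namespace"] != namespace:
                continue
            if term == root:
                continue
            gene = row[id_idx]
            if not gene:
                skipped += 1
                continue
            gene_terms.setdefault(gene, set()).add(term)
            evidence.setdefault((gene, term), code)
    if skipped:
        logger.warning("skipped %d malformed GAF rows in %s", skipped, path)
    return AnnotationSet(
        namespace=namespace,
        gene_terms=gene_terms,
        evidence_policy=evidence_policy,
        evidence=evidence,
    )


def annotation_lookup(ann: AnnotationSet, gene: str):
    """Direct annotation set of *gene*, or :data:`MISSING_GENE`.

    Unknown genes return the missing marker rather than raising so that
    dataset-scale scoring can map them to the −1 sentinel.
    """
    try:
        return set(ann.gene_terms[gene])
    except KeyError:
        return MISSING_GENE


def write_gaf(ann: AnnotationSet, path, db: str = "SYN", taxon: str = "taxon:0") -> None:
    """Write an annotation set as a minimal GAF 2.1 file."""
    inv_aspect = {v: k for k, v in ASPECT_CODES.items()}
    aspect = inv_aspect[ann.namespace]
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(ann.gene_terms):
            for term in sorted(ann.gene_terms[gene]):
                code = ann.evidence.get((gene, term), "IDA")
                row = [
                    db, gene, gene, "", term, "SYN:0001", code, "",
                    aspect, "", "", "protein", taxon, "20160901", db, "", "",
                ]
                fh.write("\t".join(row) + "\n")
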