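"""Gene Ontology DAG handling.

Parses OBO flat files into a light-weight typed DAG restricted to the two
hierarchical relations (``is_a`` and ``part_of``) and answers the one- and
two-step neighborhood queries the vector expansion needs.  Each of the three
GO namespaces (biological process, cellular component, molecular function)
forms its own rooted DAG; all computation downstream is per-namespace.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of")

#: OBO namespace strings -> short codes used throughout the package.
NAMESPACE_CODES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

_TERM_ID_RE = re.compile(r"^GO:\d{7}$")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, missing roots)."""


def is_term_id(s: str) -> bool:
    """True if *s* looks like a GO accession (``GO:`` + 7 digits)."""
    return bool(_TERM_ID_RE.match(s))


@dataclass
class OntologyGraph:
    """Typed DAG of GO terms.

    ``terms`` maps a term accession to ``{"name": ..., "namespace": ...}``
    where namespace is one of ``BP``/``CC``/``MF``.  ``edges`` hold
    (child, parent, relation) triples with relation restricted to ``is_a``
    and ``part_of``; edges always join terms of the same namespace.
    ``alt_ids`` maps secondary accessions to their canonical term.
    """

    terms: dict[str, dict]
    edges: set[tuple[str, str, str]]
    alt_ids: dict[str, str] = field(default_factory=dict)

    # relation -> term -> set of neighbors, built once
    _parents: dict[str, dict[str, set[str]]] = field(init=False, repr=False)
    _children: dict[str, dict[str, set[str]]] = field(init=False, repr=False)
    _roots: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._parents = {r: {} for r in RELATIONS}
        self._children = {r: {} for r in RELATIONS}
        for child, parent, rel in self.edges:
            self._parents[rel].setdefault(child, set()).add(parent)
            self._children[rel].setdefault(parent, set()).add(child)
        self._validate()
        self._roots = {}

    def _validate(self) -> None:
        for child, parent, rel in self.edges:
            if rel not in RELATIONS:
                raise OntologyError(f"unsupported relation {rel!r}")
            for t in (child, parent):
                if t not in self.terms:
                    raise OntologyError(f"edge references unknown term {t}")
            if self.terms[child]["namespace"] != self.terms[parent]["namespace"]:
                raise OntologyError(
                    f"cross-namespace edge {child} -> {parent}"
                )
        for rel in RELATIONS:
            g = nx.DiGraph()
            g.add_nodes_from(self.terms)
            g.add_edges_from(
                (c, p) for c, p, r in self.edges if r == rel
            )
            if not nx.is_directed_acyclic_graph(g):
                member = nx.find_cycle(g)[0][0]
                raise OntologyError(
                    f"cyclic {rel} structure involving {member}"
                )

    # -- lookups -----------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.alt_ids

    def resolve(self, term: str) -> str:
        """Canonical accession for *term*, following ``alt_id`` mappings.

        Raises ``KeyError`` for accessions absent from the ontology.
        """
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(term)

    def namespace_of(self, term: str) -> str:
        return self.terms[self.resolve(term)]["namespace"]

    def namespaces(self) -> set[str]:
        return {info["namespace"] for info in self.terms.values()}

    def parents(self, term: str, relation: str) -> set[str]:
        """Direct parents of *term* via edges of exactly *relation*."""
        return set(self._parents[relation].get(term, ()))

    def children(self, term: str, relation: str) -> set[str]:
        return set(self._children[relation].get(term, ()))

    def parents_any(self, term: str) -> set[str]:
        return self.parents(term, "is_a") | self.parents(term, "part_of")

    def children_any(self, term: str) -> set[str]:
        return self.children(term, "is_a") | self.children(term, "part_of")

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All terms reachable upward via is_a/part_of edges."""
        term = self.resolve(term)
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for p in self.parents_any(t):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        if include_self:
            seen.add(term)
        return seen

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        term = self.resolve(term)
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for c in self.children_any(t):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        if include_self:
            seen.add(term)
        return seen

    def namespace_terms(self, namespace: str) -> set[str]:
        return {
            t for t, info in self.terms.items() if info["namespace"] == namespace
        }


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Only ``is_a`` and ``part_of`` edges are kept; every other relationship
    type (regulates, occurs_in, ...) is discarded, as are obsolete terms and
    any cross-namespace edge.  ``alt_id`` tags are recorded so secondary
    accessions found in annotation files resolve to their canonical term.
    """
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except OSError:
        raise
    terms: dict[str, dict] = {}
    for node, data in multigraph.nodes(data=True):
        ns = data.get("namespace") or multigraph.graph.get("default-namespace", [None])[0]
        if ns is None:
            raise OntologyError(f"term {node} has no namespace")
        terms[node] = {
            "name": data.get("name", ""),
            "namespace": NAMESPACE_CODES.get(ns, ns),
        }
    edges: set[tuple[str, str, str]] = set()
    dropped_rel = 0
    dropped_xns = 0
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in RELATIONS:
            dropped_rel += 1
            continue
        if parent not in terms or child not in terms:
            continue
        if terms[child]["namespace"] != terms[parent]["namespace"]:
            dropped_xns += 1
            continue
        edges.add((child, parent, rel))
    if dropped_rel:
        logger.info("discarded %d edges of unsupported relation types", dropped_rel)
    if dropped_xns:
        logger.info("discarded %d cross-namespace edges", dropped_xns)
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        for alt in data.get("alt_id", []):
            if alt in alt_ids and alt_ids[alt] != node:
                logger.warning(
                    "alt_id %s maps to both %s and %s; keeping the first",
                    alt, alt_ids[alt], node,
                )
                continue
            alt_ids.setdefault(alt, node)
    return OntologyGraph(terms=terms, edges=edges, alt_ids=alt_ids)


def relation_neighbors(
    graph: OntologyGraph,
    term: str,
    relation: str,
    direction: str,
    steps: int,
) -> set[str]:
    """One- or two-step neighborhood of *term* along a single relation.

    ``steps=2`` requires both edges of the path to carry *relation*;
    mixed-relation two-step paths are deliberately not reported here (the
    vector expansion handles them in its part_of stage).  The query term is
    never part of the result.
    """
    if term not in graph.terms:
        raise KeyError(term)
    if relation not in RELATIONS:
        raise ValueError(f"relation must be one of {RELATIONS}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if steps not in (1, 2):
        raise ValueError("steps must be 1 or 2")
    step = graph.parents if direction == "up" else graph.children
    first = step(term, relation)
    if steps == 1:
        return first - {term}
    second: set[str] = set()
    for mid in first:
        second |= step(mid, relation)
    return second - {term}


def namespace_root(graph: OntologyGraph, namespace: str) -> str:
    """The unique parentless term of *namespace*.

    A well-formed GO namespace has exactly one root (e.g. GO:0005575 for
    cellular component); zero or several parentless terms indicate a broken
    or truncated ontology and raise :class:`OntologyError`.
    """
    candidates = [
        t for t in graph.namespace_terms(namespace) if not graph.parents_any(t)
    ]
    if not candidates:
        raise OntologyError(f"namespace {namespace} is empty or rootless")
    if len(candidates) > 1:
        raise OntologyError(
            f"namespace {namespace} has {len(candidates)} parentless terms: "
            f"{sorted(candidates)[:5]}"
        )
    return candidates[0]


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize a graph back to minimal OBO 1.2 text.

    Round-trips through :func:`parse_obo`: re-parsing the output yields an
    identical term and edge set.
    """
    inv_codes = {v: k for k, v in NAMESPACE_CODES.items()}
    up: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in graph.edges:
        up.setdefault(child, []).append((rel, parent))
    alt_by_canonical: dict[str, list[str]] = {}
    for alt, canon in graph.alt_ids.items():
        alt_by_canonical.setdefault(canon, []).append(alt)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(graph.terms):
            info = graph.terms[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {info['name']}\n")
            ns = inv_codes.get(info["namespace"], info["namespace"])
            fh.write(f"namespace: {ns}\n")
            for alt in sorted(alt_by_canonical.get(term, ())):
                fh.write(f"alt_id: {alt}\n")
            for rel, parent in sorted(up.get(term, ())):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
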