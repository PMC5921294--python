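"""Comparison similarity measures.

Implements the classic GO semantic-similarity baselines the hierarchical
model is evaluated against: the flat binary-vector cosine (basic VSM),
IntelliGO's weighted vector model, the set-overlap Jaccard/Dice measures,
the information-content term measures of Resnik, Lin, Jiang and Schlicker
with MAX/AVG/BMA gene-level combination, and SimGIC (IC-weighted Jaccard
over ancestor-closed sets).

Information content is corpus-based: IC(t) = −ln p(t) where p(t) is the
fraction of annotated genes carrying t or any of its descendants
(annotations propagate to ancestors through both is_a and part_of).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

from .annotations import AnnotationSet
from .ontology import OntologyGraph, namespace_root

COMBINE_STRATEGIES = ("MAX", "AVG", "BMA")
TERM_METHODS = ("resnik", "lin", "jiang", "schlicker")


@dataclass
class ICTable:
    """Per-term annotation probabilities and information content (nats).

    p is ancestor-propagated and therefore monotone along the hierarchy
    (p(parent) >= p(child)); the namespace root has p = 1 and IC = 0.
    Terms with no annotated gene below them are absent.
    """

    namespace: str
    ic: dict[str, float]
    p: dict[str, float]
    n_genes: int = 0
    #: genes directly annotated to each term (for inverse annotation frequency)
    direct_counts: dict[str, int] = field(default_factory=dict)


def compute_ic(ann: AnnotationSet, graph: OntologyGraph) -> ICTable:
    """Build an :class:`ICTable` using *ann* as the annotation corpus.

    count(t) = number of genes annotated to t or any descendant (via both
    relations); p(t) = count(t) / count(root).  Uncounted terms are omitted.
    """
    if not ann.gene_terms:
        raise ValueError("empty annotation corpus")
    ns_terms = graph.namespace_terms(ann.namespace)
    # genes reaching each term, accumulated leaf-to-root in topological order
    carriers: dict[str, set[int]] = {t: set() for t in ns_terms}
    for gi, (gene, terms) in enumerate(sorted(ann.gene_terms.items())):
        for t in terms:
            carriers[t].add(gi)
    ts = TopologicalSorter()
    for t in ns_terms:
        ts.add(t)
        for p in graph.parents_any(t):
            ts.add(p, t)  # parent depends on child: children first
    for t in ts.static_order():
        for p in graph.parents_any(t):
            carriers[p] |= carriers[t]
    root = namespace_root(graph, ann.namespace)
    total = len(carriers[root])
    if total == 0:
        raise ValueError("no genes reach the namespace root")
    p_map: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t, genes in carriers.items():
        if genes:
            p = len(genes) / total
            p_map[t] = p
            ic[t] = -math.log(p)
    direct: dict[str, int] = {}
    for terms in ann.gene_terms.values():
        for t in terms:
            direct[t] = direct.get(t, 0) + 1
    return ICTable(namespace=ann.namespace, ic=ic, p=p_map,
                   n_genes=len(ann.gene_terms), direct_counts=direct)


def vsm_similarity(terms1: set[str], terms2: set[str]) -> float:
    """Flat binary-vector cosine: |A ∩ B| / sqrt(|A| |B|)."""
    if not terms1 or not terms2:
        raise ValueError("term sets must be nonempty")
    inter = len(set(terms1) & set(terms2))
    return inter / math.sqrt(len(set(terms1)) * len(set(terms2)))


def set_similarity(terms1: set[str], terms2: set[str], method: str) -> float:
    """Set-overlap similarity: ``jaccard`` |∩|/|∪| or ``dice`` 2|∩|/(|A|+|B|)."""
    if not terms1 or not terms2:
        raise ValueError("term sets must be nonempty")
    a, b = set(terms1), set(terms2)
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "dice":
        return 2 * inter / (len(a) + len(b))
    raise ValueError(f"unknown set method {method!r}")


def _mica(t1: str, t2: str, ic: ICTable, graph: OntologyGraph) -> str | None:
    """Most informative common ancestor (both relations, self included)."""
    common = graph.ancestors(t1) & graph.ancestors(t2)
    common = {t for t in common if t in ic.ic}
    if not common:
        return None
    return max(sorted(common), key=lambda t: ic.ic[t])


def term_similarity(
    t1: str,
    t2: str,
    ic: ICTable,
    graph: OntologyGraph,
    method: str,
) -> float:
    """IC-based similarity between two terms.

    With M the most informative common ancestor: Resnik is IC(M); Lin is
    2 IC(M) / (IC(t1) + IC(t2)) (0 when the denominator vanishes); Jiang's
    distance IC(t1) + IC(t2) − 2 IC(M) is reported as the bounded
    similarity 1 / (1 + distance); Schlicker is Lin relevance-weighted by
    1 − p(M).
    """
    if method not in TERM_METHODS:
        raise ValueError(f"unknown term method {method!r}")
    for t in (t1, t2):
        if t not in ic.ic:
            raise KeyError(f"no IC entry for {t}")
    m = _mica(t1, t2, ic, graph)
    ic_m = ic.ic[m] if m is not None else 0.0
    if method == "resnik":
        return ic_m
    if method == "lin":
        denom = ic.ic[t1] + ic.ic[t2]
        return 2 * ic_m / denom if denom > 0 else 0.0
    if method == "jiang":
        dist = ic.ic[t1] + ic.ic[t2] - 2 * ic_m
        return 1.0 / (1.0 + dist)
    # schlicker
    denom = ic.ic[t1] + ic.ic[t2]
    lin = 2 * ic_m / denom if denom > 0 else 0.0
    p_m = ic.p[m] if m is not None else 1.0
    return lin * (1.0 - p_m)


def combine_pairwise(terms1, terms2, termfn, strategy: str = "MAX") -> float:
    """Combine a cross term-pair score matrix into one gene-pair score.

    MAX and AVG are the maximum and mean of all cross-pair scores; BMA
    averages each term's best match in the other set, in both directions,
    and takes the mean of the two directional averages.
    """
    strategy = strategy.upper()
    if strategy not in COMBINE_STRATEGIES:
        raise ValueError(f"unknown combination strategy {strategy!r}")
    t1 = sorted(set(terms1))
    t2 = sorted(set(terms2))
    if not t1 or not t2:
        raise ValueError("term sets must be nonempty")
    matrix = [[termfn(a, b) for b in t2] for a in t1]
    flat = [s for row in matrix for s in row]
    if strategy == "MAX":
        return max(flat)
    if strategy == "AVG":
        return sum(flat) / len(flat)
    row_best = sum(max(row) for row in matrix) / len(t1)
    col_best = sum(max(matrix[i][j] for i in range(len(t1)))
                   for j in range(len(t2))) / len(t2)
    return 0.5 * (row_best + col_best)


def simgic_similarity(
    terms1: set[str],
    terms2: set[str],
    ic: ICTable,
    graph: OntologyGraph,
) -> float:
    """IC-weighted Jaccard over ancestor-closed annotation sets.

    Each gene's set is extended with every ancestor (both relations); the
    score is the summed IC of the intersection over the summed IC of the
    union.  Because the root's IC is 0, genes whose closures share only the
    root score 0.  Returns 0 when the union carries no IC at all.
    """
    if not terms1 or not terms2:
        raise ValueError("term sets must be nonempty")
    ext1: set[str] = set()
    for t in terms1:
        ext1 |= graph.ancestors(t)
    ext2: set[str] = set()
    for t in terms2:
        ext2 |= graph.ancestors(t)
    union_ic = sum(ic.ic.get(t, 0.0) for t in ext1 | ext2)
    if union_ic == 0.0:
        return 0.0
    inter_ic = sum(ic.ic.get(t, 0.0) for t in ext1 & ext2)
    return inter_ic / union_ic


# --- IntelliGO -------------------------------------------------------------

@dataclass
class IntelliGOConfig:
    """Conventions for the IntelliGO vector measure.

    ``evidence_weights`` maps GAF evidence codes to the per-annotation
    weight w(g, t); codes absent from the map get ``default_weight``.
    """

    evidence_weights: dict[str, float] = field(default_factory=dict)
    default_weight: float = 1.0

    def weight(self, code: str | None) -> float:
        if code is None:
            return self.default_weight
        w = self.evidence_weights.get(code, self.default_weight)
        if w <= 0:
            raise ValueError(f"evidence weight for {code!r} must be > 0")
        return w


class _IntelliGOContext:
    """Cached depths and upward distances for one (graph, namespace)."""

    def __init__(self, graph: OntologyGraph, namespace: str):
        self.graph = graph
        self.root = namespace_root(graph, namespace)
        # depth = minimum edge count from the root, both relations
        self.depth: dict[str, int] = {self.root: 0}
        frontier = [self.root]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for t in frontier:
                for c in graph.children_any(t):
                    if c not in self.depth:
                        self.depth[c] = d
                        nxt.append(c)
            frontier = nxt
        self._updist: dict[str, dict[str, int]] = {}

    def up_distances(self, term: str) -> dict[str, int]:
        """Minimum upward edge distance from *term* to each ancestor."""
        cached = self._updist.get(term)
        if cached is not None:
            return cached
        dist = {term: 0}
        frontier = [term]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for t in frontier:
                for p in self.graph.parents_any(t):
                    if p not in dist:
                        dist[p] = d
                        nxt.append(p)
            frontier = nxt
        self._updist[term] = dist
        return dist

    def edge_product(self, t1: str, t2: str) -> float:
        """e_i · e_j = 2 Depth(LCA) / (MinSPL + 2 Depth(LCA)).

        The LCA is the deepest common ancestor (minimum root distance is
        maximal); among equally deep candidates the one minimizing the
        through-path t1→LCA→t2 wins.  When the only common ancestor is the
        root, Depth = 0 and the product is 0; identical terms give 1.
        """
        if t1 == t2:
            return 1.0
        d1 = self.up_distances(t1)
        d2 = self.up_distances(t2)
        common = set(d1) & set(d2)
        if not common:
            return 0.0
        best = min(
            (-self.depth.get(a, 0), d1[a] + d2[a], a) for a in common
        )
        depth_lca = -best[0]
        minspl = best[1]
        if depth_lca == 0:
            return 0.0
        return 2.0 * depth_lca / (minspl + 2.0 * depth_lca)


def intelligo_similarity(
    gene1: str,
    gene2: str,
    ann: AnnotationSet,
    graph: OntologyGraph,
    cfg: IntelliGOConfig | None = None,
    _context: _IntelliGOContext | None = None,
) -> float:
    """IntelliGO cosine similarity between two annotated genes.

    Each gene is Σ_i α_i e_i with α_i = w(g, t_i) · IFA(t_i), where IFA is
    the inverse annotation frequency ln(G / G_t) over the corpus *ann*,
    and the basis dot products e_i · e_j encode hierarchy closeness via the
    depth of the lowest common ancestor.  The score is the generalized
    cosine g1·g2 / (sqrt(g1·g1) sqrt(g2·g2)).
    """
    if cfg is None:
        cfg = IntelliGOConfig()
    for g in (gene1, gene2):
        if g not in ann.gene_terms:
            raise KeyError(f"gene {g} not annotated")
    ctx = _context or _IntelliGOContext(graph, ann.namespace)
    n_genes = len(ann.gene_terms)
    direct: dict[str, int] = {}
    for terms in ann.gene_terms.values():
        for t in terms:
            direct[t] = direct.get(t, 0) + 1

    def alpha(gene: str, term: str) -> float:
        w = cfg.weight(ann.evidence.get((gene, term)))
        ifa = math.log(n_genes / direct[term]) if direct[term] else 0.0
        return w * ifa

    t1 = sorted(ann.gene_terms[gene1])
    t2 = sorted(ann.gene_terms[gene2])
    a1 = {t: alpha(gene1, t) for t in t1}
    a2 = {t: alpha(gene2, t) for t in t2}

    def dot(ta, wa, tb, wb) -> float:
        return sum(
            wa[x] * wb[y] * ctx.edge_product(x, y) for x in ta for y in tb
        )

    denom = math.sqrt(dot(t1, a1, t1, a1)) * math.sqrt(dot(t2, a2, t2, a2))
    if denom == 0.0:
        return 0.0
    return dot(t1, a1, t2, a2) / denom
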