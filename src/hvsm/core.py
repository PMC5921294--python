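"""The hierarchical vector space model (HVSM).

A gene annotated with GO terms is mapped to a sparse vector over the terms
of one namespace.  Directly annotated terms get weight 1; the vector is then
expanded over the hierarchy in two relation stages (is_a, then part_of),
each stage running four steps in order:

  i.   direct parents of every annotated term,
  ii.  grandparents (two same-direction steps), discounted by ``w_r_g``,
  iii. terms that are a direct child of two or more annotated terms,
  iv.  grandchildren common to two or more annotated terms, discounted.

A fresh (zero) component is set to the product of the applicable
contribution factors; a component already touched is incremented by the
increment factor instead, capped at 1.  Similarity between two expanded
vectors is the cosine, calibrated by a certainty factor ln(S1+S2) where
S_i is the number of directly annotated terms of gene i — pairs backed by
richer annotation earn proportionally more credit, so scores may exceed 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .annotations import MISSING_GENE, AnnotationSet, annotation_lookup
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: Sentinel similarity for pairs with an unresolvable gene.
SENTINEL_MISSING = -1.0
#: Sentinel similarity for pairs whose computation failed internally.
SENTINEL_ERROR = -2.0


@dataclass(frozen=True)
class HVSMParams:
    """The six semantic contribution factors.

    All unitless in [0, 1].  Defaults are the published trade-off values:
    is_a counts more than part_of, parents more than children, and the
    two-step ratio ``w_r_g`` halves every grandparent/grandchild
    contribution.  ``w_incre`` is the increment applied when several
    annotated terms converge on the same component.
    """

    w_is_a: float = 1.0
    w_part_of: float = 0.7
    w_parent: float = 0.5
    w_child: float = 0.2
    w_incre: float = 1.0 / 6.0
    w_r_g: float = 0.5

    def __post_init__(self) -> None:
        for name in ("w_is_a", "w_part_of", "w_parent", "w_child",
                     "w_incre", "w_r_g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.w_is_a > self.w_part_of:
            logger.warning("w_is_a <= w_part_of; is_a normally dominates")
        if not self.w_parent > self.w_child:
            logger.warning("w_parent <= w_child; parents normally dominate")
        if not self.w_r_g < 1:
            logger.warning("w_r_g >= 1; two-step terms normally discounted")

    @classmethod
    def cessm_profile(cls) -> "HVSMParams":
        """Preset used for CESSM-style score export (smaller w_child)."""
        return cls(w_child=0.05)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "HVSMParams":
        known = {"w_is_a", "w_part_of", "w_parent", "w_child",
                 "w_incre", "w_r_g"}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass
class GeneVector:
    """Sparse expanded vector of one gene.

    ``weights`` maps term -> weight in (0, 1]; zero components are simply
    absent.  ``direct_count`` is the number of directly annotated terms
    (the S_i entering the certainty factor); every one of those terms
    carries weight exactly 1.
    """

    gene: str
    namespace: str
    weights: dict[str, float]
    direct_count: int

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


def _bump_new(weights: dict[str, float], term: str, new: float, incre: float) -> None:
    """One expansion update: fresh components get *new*, touched ones +*incre*."""
    cur = weights.get(term, 0.0)
    if cur == 0.0:
        if new > 0.0:
            weights[term] = min(1.0, new)
    else:
        weights[term] = min(1.0, cur + incre)


def _expand_stage(
    weights: dict[str, float],
    direct: list[str],
    graph: OntologyGraph,
    params: HVSMParams,
    relation: str,
    w_rel: float,
    mixed: bool,
) -> None:
    """Run steps i-iv for one relation stage.

    With ``mixed=False`` (the is_a stage) two-step paths must use is_a on
    both edges.  With ``mixed=True`` (the part_of stage) a two-step path
    qualifies when at least one of its edges is part_of — mixed-relation
    paths are charged at the part_of rate.
    """

    def up2(term: str) -> set[str]:
        if not mixed:
            out: set[str] = set()
            for mid in graph.parents(term, relation):
                out |= graph.parents(mid, relation)
            return out - {term}
        out = set()
        for mid in graph.parents(term, "is_a"):
            out |= graph.parents(mid, "part_of")
        for mid in graph.parents(term, "part_of"):
            out |= graph.parents_any(mid)
        return out - {term}

    def down1(term: str) -> set[str]:
        return graph.children(term, relation)

    def down2(term: str) -> set[str]:
        if not mixed:
            out: set[str] = set()
            for mid in graph.children(term, relation):
                out |= graph.children(mid, relation)
            return out - {term}
        out = set()
        for mid in graph.children(term, "is_a"):
            out |= graph.children(mid, "part_of")
        for mid in graph.children(term, "part_of"):
            out |= graph.children_any(mid)
        return out - {term}

    # step i: direct parents, one update per (annotated term, parent) incidence
    for t in direct:
        for p in sorted(graph.parents(t, relation)):
            _bump_new(weights, p,
                      new=params.w_parent * w_rel,
                      incre=params.w_incre * w_rel)
    # step ii: grandparents, discounted by w_r_g
    for t in direct:
        for g in sorted(up2(t)):
            _bump_new(weights, g,
                      new=params.w_r_g * params.w_parent * w_rel,
                      incre=params.w_r_g * params.w_incre * w_rel)
    # step iii: children common to >= 2 annotated terms, one update per child
    child_sources: dict[str, set[str]] = {}
    for t in direct:
        for c in down1(t):
            child_sources.setdefault(c, set()).add(t)
    for c in sorted(child_sources):
        if len(child_sources[c]) >= 2:
            _bump_new(weights, c,
                      new=params.w_child * w_rel,
                      incre=params.w_child * params.w_incre * w_rel)
    # step iv: grandchildren common to >= 2 annotated terms, discounted
    gchild_sources: dict[str, set[str]] = {}
    for t in direct:
        for c in down2(t):
            gchild_sources.setdefault(c, set()).add(t)
    for c in sorted(gchild_sources):
        if len(gchild_sources[c]) >= 2:
            _bump_new(weights, c,
                      new=params.w_r_g * params.w_child * w_rel,
                      incre=params.w_r_g * params.w_child * params.w_incre * w_rel)


def build_vector(
    terms: set[str],
    graph: OntologyGraph,
    params: HVSMParams | None = None,
) -> GeneVector:
    """Expand a set of directly annotated terms into an HVSM vector.

    Stage 1 sets every directly annotated term to 1 (they stay frozen at 1
    throughout: the cap turns every later update on them into a no-op).
    Stage 2 runs steps i-iv along is_a edges, stage 3 repeats them for
    part_of with the part_of contribution factor; within a step, updates
    see the values produced earlier in the same step, and annotated terms
    are visited in sorted accession order for determinism.
    """
    if params is None:
        params = HVSMParams()
    if not terms:
        raise ValueError("cannot build a vector from an empty term set")
    namespaces = set()
    for t in terms:
        if t not in graph.terms:
            raise KeyError(f"term {t} not in ontology")
        namespaces.add(graph.terms[t]["namespace"])
    if len(namespaces) != 1:
        raise ValueError(f"terms span multiple namespaces: {sorted(namespaces)}")
    direct = sorted(terms)
    weights = {t: 1.0 for t in direct}
    _expand_stage(weights, direct, graph, params, "is_a", params.w_is_a,
                  mixed=False)
    _expand_stage(weights, direct, graph, params, "part_of", params.w_part_of,
                  mixed=True)
    return GeneVector(
        gene="",
        namespace=namespaces.pop(),
        weights=weights,
        direct_count=len(direct),
    )


def certainty_factor(s1: int, s2: int) -> float:
    """Calibration factor λ = ln(S1 + S2).

    S_i is the number of terms directly annotated to gene i; the factor is
    strictly increasing in each argument, rewarding well-annotated pairs.
    """
    if s1 < 1 or s2 < 1:
        raise ValueError("both direct-annotation counts must be >= 1")
    return math.log(s1 + s2)


def hvsm_similarity(v1: GeneVector, v2: GeneVector) -> float:
    """Certainty-calibrated cosine of two expanded vectors.

    Computed over the union of nonzero components only, which is exact:
    dimensions at zero in both vectors contribute nothing to either the dot
    product or the norms.  The result may exceed 1 because of the
    calibration factor; downstream ROC analysis is rank-based and unaffected.
    """
    if v1.namespace != v2.namespace:
        raise ValueError(
            f"namespace mismatch: {v1.namespace} vs {v2.namespace}"
        )
    small, big = (v1.weights, v2.weights)
    if len(small) > len(big):
        small, big = big, small
    dot = sum(w * big[t] for t, w in small.items() if t in big)
    lam = certainty_factor(v1.direct_count, v2.direct_count)
    return lam * dot / (v1.norm() * v2.norm())


def pair_similarity(
    gene_a: str,
    gene_b: str,
    ann: AnnotationSet,
    graph: OntologyGraph,
    params: HVSMParams | None = None,
) -> float:
    """HVSM similarity of a gene pair, with dataset-scale sentinel handling.

    A pair with either gene absent from the annotation set scores −1; any
    internal failure during vector construction or comparison scores −2
    (and is logged).  Successful pairs return the calibrated similarity.
    Symmetric in its arguments.
    """
    terms_a = annotation_lookup(ann, gene_a)
    terms_b = annotation_lookup(ann, gene_b)
    if terms_a is MISSING_GENE or terms_b is MISSING_GENE:
        return SENTINEL_MISSING
    try:
        va = build_vector(terms_a, graph, params)
        vb = build_vector(terms_b, graph, params)
        return hvsm_similarity(va, vb)
    except Exception:
        logger.exception("similarity failed for pair (%s, %s)", gene_a, gene_b)
        return SENTINEL_ERROR
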