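"""Seeded synthetic ontologies, annotations and pair benchmarks.

Everything downstream of the parsers is testable without downloads: the
generators build a layered random DAG per namespace (single root, typed
is_a/part_of edges, no part_of in MF), annotate synthetic genes with random
term sets, and assemble balanced positive/negative pair benchmarks in which
positive pairs carry planted annotation relatedness.

The planted signal modes mirror how related proteins look in real
annotation data:

* ``shared-term`` — the two genes share direct terms (full overlap by
  default, tunable via ``share_frac``; plain overlap every measure sees),
* ``sibling-term`` — the genes are annotated to disjoint children of common
  parent terms (related but non-overlapping; flat set/vector measures score
  such pairs 0, hierarchy-aware ones do not),
* ``parent-child`` — one gene holds terms, the other their direct parents,
* ``none`` — positives are random pairs too (null benchmark; any measure's
  ROC area should be near one half).

Identical spec + seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotations import AnnotationSet
from .evaluation import PairDataset
from .ontology import OntologyGraph

SIGNAL_MODES = ("shared-term", "sibling-term", "parent-child", "none")

_NS_LONG = {"BP": "biological_process", "CC": "cellular_component",
            "MF": "molecular_function"}

# substream offsets so the three generators draw independent streams
_STREAM_ONTOLOGY = 1
_STREAM_ANNOTATION = 2
_STREAM_PAIRS = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark.

    Defaults give a desk-scale benchmark: a 200-term single-namespace
    ontology of moderate depth, 100 genes carrying 2-6 direct terms each,
    and a balanced 300+300 pair set.
    """

    seed: int
    n_terms: int = 200
    max_parents: int = 2
    p_part_of: float = 0.2
    n_genes: int = 100
    terms_per_gene: tuple[int, int] = (2, 6)
    signal: str = "shared-term"
    share_frac: float = 1.0
    n_pos: int = 300
    n_neg: int = 300
    namespace: str = "CC"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_part_of <= 1.0:
            raise ValueError("p_part_of must be in [0, 1]")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if min(self.n_terms, self.n_genes, self.n_pos, self.n_neg) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.terms_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("terms_per_gene must be a valid (lo, hi) range")
        if self.signal not in SIGNAL_MODES:
            raise ValueError(f"signal must be one of {SIGNAL_MODES}")
        if not 0.0 < self.share_frac <= 1.0:
            raise ValueError("share_frac must be in (0, 1]")
        if self.namespace not in _NS_LONG:
            raise ValueError("namespace must be BP, CC or MF")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Layered random DAG: single root, every non-root term has >= 1 parent.

    Terms are laid out in layers of geometrically growing size; each term
    draws 1..max_parents parents uniformly from the previous layer, so
    two-step ancestry and shared children occur naturally.  Each edge is
    part_of with probability ``p_part_of`` — forced to 0 for MF, which has
    no part_of relation.
    """
    rng = _rng(spec, _STREAM_ONTOLOGY)
    ns = spec.namespace
    p_po = 0.0 if ns == "MF" else spec.p_part_of
    terms = {
        _term_id(i): {"name": f"synthetic term {i}", "namespace": ns}
        for i in range(spec.n_terms)
    }
    ids = sorted(terms)
    layers = [[ids[0]]]
    i = 1
    while i < spec.n_terms:
        size = min(spec.n_terms - i, max(2, int(len(layers[-1]) * 2.5)))
        layers.append(ids[i:i + size])
        i += size
    edges: set[tuple[str, str, str]] = set()
    for li in range(1, len(layers)):
        prev = layers[li - 1]
        for term in layers[li]:
            k = int(rng.integers(1, min(spec.max_parents, len(prev)) + 1))
            parents = rng.choice(len(prev), size=k, replace=False)
            for pi in parents:
                rel = "part_of" if rng.random() < p_po else "is_a"
                edges.add((term, prev[int(pi)], rel))
    return OntologyGraph(terms=terms, edges=edges)


def generate_annotations(graph: OntologyGraph, spec: FixtureSpec) -> AnnotationSet:
    """Annotate ``n_genes`` synthetic genes with uniform random term sets.

    Term counts are uniform over ``terms_per_gene``; the root is never
    drawn, honoring the root-exclusion invariant of real annotation sets.
    """
    rng = _rng(spec, _STREAM_ANNOTATION)
    ns_terms = sorted(graph.namespace_terms(spec.namespace))
    root = ns_terms[0]
    pool = [t for t in ns_terms if t != root and graph.parents_any(t)]
    if not pool:
        raise ValueError("ontology has no non-root terms to annotate")
    lo, hi = spec.terms_per_gene
    gene_terms: dict[str, set[str]] = {}
    for gi in range(spec.n_genes):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        gene_terms[f"SYNG{gi:04d}"] = {pool[int(j)] for j in idx}
    return AnnotationSet(namespace=spec.namespace, gene_terms=gene_terms)


def _engineer_positive(
    rng: np.random.Generator,
    graph: OntologyGraph,
    spec: FixtureSpec,
    pool: list[str],
    branchy: list[str],
) -> tuple[set[str], set[str]]:
    """Term sets for one planted positive pair, per the spec's signal mode."""
    lo, hi = spec.terms_per_gene
    k = int(rng.integers(lo, hi + 1))
    if spec.signal == "shared-term":
        shared_n = max(1, round(spec.share_frac * k))
        idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        terms_a = {pool[int(j)] for j in idx}
        shared = set(sorted(terms_a)[:shared_n])
        n_extra = min(k - shared_n, len(pool))
        terms_b = set(shared)
        if n_extra > 0:
            extra = rng.choice(len(pool), size=n_extra, replace=False)
            terms_b |= {pool[int(j)] for j in extra}
        return terms_a, terms_b
    if spec.signal == "sibling-term":
        terms_a: set[str] = set()
        terms_b: set[str] = set()
        idx = rng.choice(len(branchy), size=min(k, len(branchy)), replace=False)
        for j in idx:
            kids = sorted(graph.children_any(branchy[int(j)]))
            pair = rng.choice(len(kids), size=2, replace=False)
            terms_a.add(kids[int(pair[0])])
            terms_b.add(kids[int(pair[1])])
        only_a, only_b = terms_a - terms_b, terms_b - terms_a
        if only_a and only_b:
            return only_a, only_b
        return terms_a, terms_b
    if spec.signal == "parent-child":
        idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        terms_a = {pool[int(j)] for j in idx}
        terms_b = set()
        root_like = {t for t in graph.terms if not graph.parents_any(t)}
        for t in terms_a:
            parents = sorted(graph.parents_any(t) - root_like)
            if parents:
                terms_b.add(parents[int(rng.integers(len(parents)))])
        if not terms_b:  # all parents were the root; fall back to overlap
            terms_b = set(sorted(terms_a)[:1])
        return terms_a, terms_b
    raise AssertionError(spec.signal)


def generate_pair_benchmark(
    graph: OntologyGraph,
    ann: AnnotationSet,
    spec: FixtureSpec,
) -> PairDataset:
    """Balanced labeled pair benchmark with planted positive relatedness.

    For the engineered signal modes the positive pairs are fresh gene pairs
    whose annotation sets are constructed to be related; these genes are
    added to *ann* in place (named ``POS####A/B``) so the returned dataset
    is scoreable against the same annotation set.  Negatives are uniform
    random pairs of the pre-existing genes.  ``signal='none'`` draws the
    positives randomly as well.
    """
    rng = _rng(spec, _STREAM_PAIRS)
    base_genes = sorted(ann.gene_terms)
    if len(base_genes) < 2:
        raise ValueError("need at least two annotated genes")
    ns_terms = sorted(graph.namespace_terms(spec.namespace))
    root = ns_terms[0]
    pool = [t for t in ns_terms if t != root and graph.parents_any(t)]
    branchy = [t for t in ns_terms if len(graph.children_any(t)) >= 2
               and graph.parents_any(t)]
    if spec.signal == "sibling-term" and not branchy:
        raise ValueError("ontology has no multi-child non-root terms")
    pairs: list[tuple[str, str, int]] = []
    if spec.signal == "none":
        for _ in range(spec.n_pos):
            i, j = rng.choice(len(base_genes), size=2, replace=False)
            pairs.append((base_genes[int(i)], base_genes[int(j)], 1))
    else:
        for pi in range(spec.n_pos):
            terms_a, terms_b = _engineer_positive(rng, graph, spec, pool,
                                                  branchy)
            ga, gb = f"POS{pi:04d}A", f"POS{pi:04d}B"
            ann.gene_terms[ga] = terms_a
            ann.gene_terms[gb] = terms_b
            pairs.append((ga, gb, 1))
    positive_keys = {frozenset((a, b)) for a, b, _ in pairs}
    tries = 0
    negatives: list[tuple[str, str, int]] = []
    seen: set[frozenset] = set()
    while len(negatives) < spec.n_neg:
        tries += 1
        if tries > 100 * spec.n_neg:
            raise ValueError("cannot draw enough distinct negative pairs")
        i, j = rng.choice(len(base_genes), size=2, replace=False)
        key = frozenset((base_genes[int(i)], base_genes[int(j)]))
        if key in positive_keys or key in seen:
            continue
        seen.add(key)
        negatives.append((base_genes[int(i)], base_genes[int(j)], 0))
    return PairDataset(pairs=pairs + negatives, namespace=spec.namespace)


def generate_benchmark(spec: FixtureSpec):
    """Convenience: ontology + annotations + pair benchmark in one call."""
    graph = generate_ontology(spec)
    ann = generate_annotations(graph, spec)
    ds = generate_pair_benchmark(graph, ann, spec)
    return graph, ann, ds


def write_pairs(ds: PairDataset, path) -> None:
    """Write a pair benchmark as the TSV format the evaluation CLI reads."""
    with open(path, "w") as fh:
        fh.write("# geneA\tgeneB\tlabel\n")
        for a, b, label in ds.pairs:
            if label is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{label}\n")
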