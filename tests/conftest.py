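"""Shared fixtures: tiny hand-built ontologies and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from hvsm.ontology import OntologyGraph


def make_graph(terms, edges, namespace="CC") -> OntologyGraph:
    """Build an OntologyGraph from bare term names and (child, parent, rel)."""
    return OntologyGraph(
        terms={t: {"name": t, "namespace": namespace} for t in terms},
        edges=set(edges),
    )


@pytest.fixture
def graph_builder():
    return make_graph


def random_typed_dag(rng: np.random.Generator, n_terms: int,
                     p_edge: float = 0.35, p_part_of: float = 0.3,
                     namespace: str = "CC") -> OntologyGraph:
    """Random DAG with typed edges; acyclic by index ordering (i -> j>i up)."""
    names = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    edges = set()
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < p_edge:
                rel = "part_of" if rng.random() < p_part_of else "is_a"
                edges.add((names[i], names[j], rel))
    return make_graph(names, edges, namespace=namespace)


@pytest.fixture
def dag_factory():
    return random_typed_dag


def literal_expand(terms, graph: OntologyGraph, p) -> dict[str, float]:
    """Straight-line reference expansion over an explicit full vector.

    Evaluates the four update rules literally, edge list in hand, with no
    sparse representation or adjacency caches: for each relation stage,
    parents then grandparents of every annotated term individually, then
    children and grandchildren shared by at least two annotated terms.
    Two-step paths in the is_a stage must use is_a twice; in the part_of
    stage any two-step path containing a part_of edge qualifies.
    """
    edges = sorted(graph.edges)
    v = {t: 0.0 for t in graph.terms}
    for t in terms:
        v[t] = 1.0

    def set_or_increment(node, fresh, incre):
        if v[node] == 0.0:
            v[node] = min(1.0, fresh)
        elif v[node] < 1.0:
            v[node] = min(1.0, v[node] + incre)

    for stage_rel, w_rel in (("is_a", p.w_is_a), ("part_of", p.w_part_of)):
        def up_paths_ok(r1, r2):
            if stage_rel == "is_a":
                return r1 == "is_a" and r2 == "is_a"
            return r1 == "part_of" or r2 == "part_of"

        # step i: parents
        for t in sorted(terms):
            for (c, par, r) in edges:
                if c == t and r == stage_rel:
                    set_or_increment(par, p.w_parent * w_rel,
                                     p.w_incre * w_rel)
        # step ii: grandparents
        for t in sorted(terms):
            gps = set()
            for (c1, p1, r1) in edges:
                if c1 != t:
                    continue
                for (c2, p2, r2) in edges:
                    if c2 == p1 and up_paths_ok(r1, r2) and p2 != t:
                        gps.add(p2)
            for gp in sorted(gps):
                set_or_increment(gp, p.w_r_g * p.w_parent * w_rel,
                                 p.w_r_g * p.w_incre * w_rel)
        # step iii: children common to >= 2 annotated terms
        owners = {}
        for t in sorted(terms):
            for (c, par, r) in edges:
                if par == t and r == stage_rel:
                    owners.setdefault(c, set()).add(t)
        for c in sorted(owners):
            if len(owners[c]) >= 2:
                set_or_increment(c, p.w_child * w_rel,
                                 p.w_child * p.w_incre * w_rel)
        # step iv: grandchildren common to >= 2 annotated terms
        owners = {}
        for t in sorted(terms):
            for (c1, p1, r1) in edges:
                if p1 != t:
                    continue
                for (c2, p2, r2) in edges:
                    if p2 == c1 and up_paths_ok(r2, r1) and c2 != t:
                        owners.setdefault(c2, set()).add(t)
        for c in sorted(owners):
            if len(owners[c]) >= 2:
                set_or_increment(c, p.w_r_g * p.w_child * w_rel,
                                 p.w_r_g * p.w_child * p.w_incre * w_rel)
    return {t: x for t, x in v.items() if x > 0.0}


@pytest.fixture
def literal_oracle():
    return literal_expand


def rank_auc(scores, labels) -> float:
    """Mann-Whitney oracle: P(random positive outranks random negative).

    Sentinels order below every real score (-1 above -2) exactly as the
    scoring convention declares; ties count one half.
    """
    def key(s):
        return (0, s) if s in (-1.0, -2.0) else (1, s)

    pos = [key(s) for s, l in zip(scores, labels) if l == 1]
    neg = [key(s) for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def rank_auc_oracle():
    return rank_auc
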