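"""Information content, IC-based term measures, set and vector baselines."""

import math

import numpy as np
import pytest

from hvsm.annotations import AnnotationSet
from hvsm.baselines import (
    IntelliGOConfig,
    _IntelliGOContext,
    combine_pairwise,
    compute_ic,
    intelligo_similarity,
    set_similarity,
    simgic_similarity,
    term_similarity,
    vsm_similarity,
)


def ann_of(gene_terms, namespace="CC"):
    return AnnotationSet(namespace=namespace,
                         gene_terms={g: set(t) for g, t in gene_terms.items()})


class TestComputeIC:
    def test_propagation_up_chain(self, graph_builder):
        # root <- a <- b, genes only on b: p(a) = p(b) = 1
        g = graph_builder(["r", "a", "b"],
                          {("a", "r", "is_a"), ("b", "a", "is_a")})
        ic = compute_ic(ann_of({"G1": "b", "G2": "b"}), g)
        assert ic.p["a"] == 1.0 and ic.p["b"] == 1.0
        assert ic.ic["a"] == 0.0

    def test_root_has_zero_ic(self, graph_builder):
        g = graph_builder(["r", "a"], {("a", "r", "is_a")})
        ic = compute_ic(ann_of({"G1": "a"}), g)
        assert ic.p["r"] == 1.0 and ic.ic["r"] == 0.0

    def test_half_corpus_term(self, graph_builder):
        g = graph_builder(["r", "a", "b"],
                          {("a", "r", "is_a"), ("b", "r", "is_a")})
        ic = compute_ic(ann_of({"G1": "a", "G2": "b"}), g)
        assert ic.ic["a"] == pytest.approx(math.log(2))

    def test_uncovered_terms_omitted(self, graph_builder):
        g = graph_builder(["r", "a", "b"],
                          {("a", "r", "is_a"), ("b", "r", "is_a")})
        ic = compute_ic(ann_of({"G1": "a"}), g)
        assert "b" not in ic.ic

    def test_monotone_along_edges(self, dag_factory):
        rng = np.random.default_rng(31)
        for _ in range(10):
            g = dag_factory(rng, 10, p_edge=0.4)
            pool = sorted(g.terms)
            gene_terms = {
                f"G{i}": set(rng.choice(pool, size=2, replace=False))
                for i in range(8)
            }
            # the random DAG has several parentless terms; anchor them to one
            roots = [t for t in pool if not g.parents_any(t)]
            ann = AnnotationSet(namespace="CC", gene_terms=gene_terms)
            if len(roots) > 1:
                continue
            ic = compute_ic(ann, g)
            for child, parent, _ in g.edges:
                if child in ic.p and parent in ic.p:
                    assert ic.p[parent] >= ic.p[child]

    def test_empty_corpus_rejected(self, graph_builder):
        g = graph_builder(["r"], set())
        with pytest.raises(ValueError):
            compute_ic(ann_of({}), g)


class TestVsmAndSets:
    def test_identical_sets(self):
        assert vsm_similarity({"a", "b"}, {"a", "b"}) == 1.0
        assert set_similarity({"a", "b"}, {"a", "b"}, "jaccard") == 1.0
        assert set_similarity({"a", "b"}, {"a", "b"}, "dice") == 1.0

    def test_disjoint_sets(self):
        assert vsm_similarity({"a"}, {"b"}) == 0.0
        assert set_similarity({"a"}, {"b"}, "jaccard") == 0.0
        assert set_similarity({"a"}, {"b"}, "dice") == 0.0

    def test_partial_overlap(self):
        assert vsm_similarity({"a", "b"}, {"b", "c"}) == pytest.approx(0.5)
        assert set_similarity({"a", "b"}, {"b", "c"},
                              "jaccard") == pytest.approx(1 / 3)
        assert set_similarity({"a", "b"}, {"b", "c"},
                              "dice") == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            vsm_similarity(set(), {"a"})


@pytest.fixture
def ic_fixture(graph_builder):
    r"""Five-term DAG with hand-computed ancestor-propagated counts.

         r
        / \
       a   b        genes: G1:{c}, G2:{c,d}, G3:{d}, G4:{b}
        \ / \
         c   d

    counts: c->{G1,G2}, d->{G2,G3}, a->{G1,G2}, b->{G1,G2,G3,G4}, r->all 4.
    """
    g = graph_builder(
        ["r", "a", "b", "c", "d"],
        {("a", "r", "is_a"), ("b", "r", "is_a"),
         ("c", "a", "is_a"), ("c", "b", "is_a"), ("d", "b", "is_a")},
    )
    ann = ann_of({"G1": "c", "G2": "cd", "G3": "d", "G4": "b"})
    return g, ann, compute_ic(ann, g)


class TestTermSimilarity:
    def test_hand_computed_mica_table(self, ic_fixture):
        g, _, ic = ic_fixture
        assert ic.p == pytest.approx(
            {"r": 1.0, "a": 0.5, "b": 1.0, "c": 0.5, "d": 0.5})
        # MICA(c, d): common ancestors {b, r}; b has IC 0 -> resnik 0
        assert term_similarity("c", "d", ic, g, "resnik") == 0.0
        # MICA(c, a) = a with IC ln 2
        assert term_similarity("c", "a", ic, g,
                               "resnik") == pytest.approx(math.log(2))
        lin = term_similarity("c", "a", ic, g, "lin")
        assert lin == pytest.approx(2 * math.log(2) / (2 * math.log(2)))
        jiang = term_similarity("c", "d", ic, g, "jiang")
        assert jiang == pytest.approx(1 / (1 + 2 * math.log(2)))

    def test_self_similarity_identities(self, ic_fixture):
        g, _, ic = ic_fixture
        assert term_similarity("c", "c", ic, g,
                               "resnik") == pytest.approx(math.log(2))
        assert term_similarity("c", "c", ic, g, "lin") == 1.0
        assert term_similarity("c", "c", ic, g, "jiang") == 1.0

    def test_root_only_ancestor_scores_zero(self, ic_fixture):
        g, _, ic = ic_fixture
        # a and d meet only at r (p=1, IC=0)
        assert term_similarity("a", "d", ic, g, "resnik") == 0.0
        assert term_similarity("a", "d", ic, g, "schlicker") == 0.0

    def test_missing_ic_entry_rejected(self, graph_builder):
        g = graph_builder(["r", "a"], {("a", "r", "is_a")})
        ic = compute_ic(ann_of({"G1": "a"}), g)
        with pytest.raises(KeyError):
            term_similarity("a", "zz", ic, g, "lin")

    def test_mica_agrees_with_bruteforce(self, dag_factory):
        rng = np.random.default_rng(17)
        for _ in range(8):
            g = dag_factory(rng, 9, p_edge=0.4)
            pool = sorted(g.terms)
            gene_terms = {f"G{i}": {str(rng.choice(pool))} for i in range(6)}
            ann = AnnotationSet(namespace="CC", gene_terms=gene_terms)
            roots = [t for t in pool if not g.parents_any(t)]
            if len(roots) != 1:
                continue
            ic = compute_ic(ann, g)
            covered = sorted(ic.ic)
            for t1 in covered:
                for t2 in covered:
                    common = g.ancestors(t1) & g.ancestors(t2)
                    expect = max((ic.ic[a] for a in common if a in ic.ic),
                                 default=0.0)
                    got = term_similarity(t1, t2, ic, g, "resnik")
                    assert got == pytest.approx(expect)

    def test_symmetry(self, ic_fixture):
        g, _, ic = ic_fixture
        for method in ("resnik", "lin", "jiang", "schlicker"):
            assert (term_similarity("c", "d", ic, g, method)
                    == term_similarity("d", "c", ic, g, method))


class TestCombinePairwise:
    def test_singletons_collapse_to_termfn(self):
        fn = lambda a, b: 0.7
        for strategy in ("MAX", "AVG", "BMA"):
            assert combine_pairwise({"x"}, {"y"}, fn, strategy) == 0.7

    def test_identity_matrix_combinations(self):
        fn = lambda a, b: 1.0 if a == b else 0.0
        t1, t2 = {"p", "q"}, {"p", "q"}
        assert combine_pairwise(t1, t2, fn, "MAX") == 1.0
        assert combine_pairwise(t1, t2, fn, "AVG") == 0.5
        assert combine_pairwise(t1, t2, fn, "BMA") == 1.0

    def test_strategy_ordering_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n, m = rng.integers(1, 5, size=2)
            mat = rng.random((n, m))
            t1 = [f"a{i}" for i in range(n)]
            t2 = [f"b{j}" for j in range(m)]
            fn = lambda a, b: mat[t1.index(a), t2.index(b)]
            mx = combine_pairwise(t1, t2, fn, "MAX")
            avg = combine_pairwise(t1, t2, fn, "AVG")
            bma = combine_pairwise(t1, t2, fn, "BMA")
            assert mx >= bma >= mat.min() - 1e-12
            assert avg <= mx + 1e-12

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            combine_pairwise({"a"}, {"b"}, lambda a, b: 0, "median")


class TestSimGIC:
    def test_identical_sets_score_one(self, ic_fixture):
        g, _, ic = ic_fixture
        assert simgic_similarity({"c", "d"}, {"c", "d"}, ic, g) == 1.0

    def test_root_only_shared_ancestor_scores_zero(self, ic_fixture):
        g, _, ic = ic_fixture
        assert simgic_similarity({"a"}, {"d"}, ic, g) == 0.0

    def test_equals_jaccard_under_uniform_ic(self, graph_builder):
        # flat star ontology, one gene per leaf: every leaf has IC ln 4 and
        # the root contributes IC 0, so the IC-weighted Jaccard over the
        # ancestor closures reduces to the unweighted set Jaccard
        g = graph_builder(["r", "a", "b", "c", "d"],
                          {(t, "r", "is_a") for t in "abcd"})
        ic = compute_ic(ann_of({"G1": "a", "G2": "b", "G3": "c", "G4": "d"}),
                        g)
        got = simgic_similarity({"a", "b"}, {"b", "c"}, ic, g)
        assert got == pytest.approx(set_similarity({"a", "b"}, {"b", "c"},
                                                   "jaccard"))


class TestIntelliGO:
    @pytest.fixture
    def setting(self, graph_builder):
        g = graph_builder(
            ["r", "a", "b", "c", "d"],
            {("a", "r", "is_a"), ("b", "r", "is_a"),
             ("c", "a", "is_a"), ("d", "a", "is_a")},
        )
        ann = ann_of({"G1": "c", "G2": "d", "G3": "cb", "G4": "b"})
        return g, ann

    def test_same_term_basis_product_is_one(self, setting):
        g, ann = setting
        ctx = _IntelliGOContext(g, "CC")
        assert ctx.edge_product("c", "c") == 1.0

    def test_sibling_basis_product(self, setting):
        g, ann = setting
        ctx = _IntelliGOContext(g, "CC")
        # c, d are siblings under a: Depth(a)=1, MinSPL=2 -> 2/(2+2)
        assert ctx.edge_product("c", "d") == pytest.approx(0.5)

    def test_root_lca_contributes_zero(self, setting):
        g, ann = setting
        ctx = _IntelliGOContext(g, "CC")
        assert ctx.edge_product("c", "b") == 0.0

    def test_identical_genes_score_one(self, setting):
        g, ann = setting
        ann.gene_terms["G5"] = {"c"}
        ann.gene_terms["G6"] = {"c"}
        got = intelligo_similarity("G5", "G6", ann, g)
        assert got == pytest.approx(1.0)

    def test_symmetric(self, setting):
        g, ann = setting
        assert (intelligo_similarity("G1", "G3", ann, g)
                == pytest.approx(intelligo_similarity("G3", "G1", ann, g)))

    def test_bounded(self, setting):
        g, ann = setting
        for a in ("G1", "G2", "G3"):
            for b in ("G1", "G2", "G3", "G4"):
                s = intelligo_similarity(a, b, ann, g)
                assert -1e-12 <= s <= 1 + 1e-12

    def test_unannotated_gene_rejected(self, setting):
        g, ann = setting
        with pytest.raises(KeyError):
            intelligo_similarity("G1", "GHOST", ann, g)

    def test_nonpositive_evidence_weight_rejected(self):
        with pytest.raises(ValueError):
            IntelliGOConfig(evidence_weights={"IEA": 0.0}).weight("IEA")


def test_bounded_measures_stay_in_unit_interval(dag_factory):
    rng = np.random.default_rng(71)
    for _ in range(10):
        g = dag_factory(rng, 10, p_edge=0.4)
        pool = sorted(g.terms)
        if len([t for t in pool if not g.parents_any(t)]) != 1:
            continue
        gene_terms = {f"G{i}": set(rng.choice(pool, size=2, replace=False))
                      for i in range(6)}
        ann = AnnotationSet(namespace="CC", gene_terms=gene_terms)
        ic = compute_ic(ann, g)
        genes = sorted(gene_terms)
        for a in genes[:3]:
            for b in genes[3:]:
                t1, t2 = gene_terms[a], gene_terms[b]
                vals = [
                    vsm_similarity(t1, t2),
                    set_similarity(t1, t2, "jaccard"),
                    set_similarity(t1, t2, "dice"),
                    simgic_similarity(t1, t2, ic, g),
                ]
                if all(t in ic.ic for t in t1 | t2):
                    for m in ("lin", "jiang", "schlicker"):
                        fn = lambda x, y: term_similarity(x, y, ic, g, m)
                        vals.append(combine_pairwise(t1, t2, fn, "BMA"))
                assert all(-1e-12 <= v <= 1 + 1e-12 for v in vals)
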