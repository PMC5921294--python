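# hvsm

Gene Ontology (GO) semantic similarity for gene products, built around a
**hierarchical vector space model**, with the classic comparison measures and
a ROC/AUC harness for protein–protein interaction (PPI) benchmarking.

## The problem

Interacting proteins tend to share function, so the functional similarity of
two gene products — computed from their GO annotations — is a widely used
signal for classifying candidate protein pairs as interacting or not.  The
simplest vector approach treats a gene as a binary vector over all GO terms
and compares genes by cosine.  That flat model ignores the ontology: two
genes annotated to *sibling* terms (say, two kinds of organelle) score
exactly zero, even though they are clearly related.

The hierarchical model fixes this by expanding each gene's vector over the
GO DAG before taking the cosine.  Starting from the directly annotated terms
(weight 1), it adds, with decreasing weights:

* direct parents and grandparents of each annotated term, via `is_a`
  relations and then via `part_of` relations, and
* children and grandchildren shared by at least two annotated terms.

A fresh component is set to the product of the relevant contribution
factors, e.g. `w_parent · w_is_a` for an `is_a` parent; a component that
several annotated terms converge on is incremented by `w_incre`-scaled
amounts instead, capped at 1.  The six factors default to

| `w_is_a` | `w_part_of` | `w_parent` | `w_child` | `w_incre` | `w_r_g` |
|---------|------------|-----------|----------|----------|--------|
| 1       | 0.7        | 0.5       | 0.2      | 1/6      | 0.5    |

The similarity of genes G₁, G₂ with expanded vectors v₁, v₂ and S₁, S₂
directly annotated terms is the **certainty-factor-calibrated cosine**

    S(G₁, G₂) = ln(S₁ + S₂) · (v₁ · v₂) / (‖v₁‖ ‖v₂‖)

The logarithmic factor rewards pairs backed by richer annotation; scores can
therefore exceed 1, which is harmless for rank-based ROC evaluation.

Also included, for comparison on the same data: basic VSM (binary cosine),
IntelliGO, Jaccard/Dice set overlap, the information-content term measures
Resnik / Lin / Jiang / Schlicker with MAX / AVG / BMA combination, and
SimGIC.

## Worked example

A five-term toy cellular-component ontology; gene 1 is annotated to
*vesicle*, gene 2 to *organelle membrane* — disjoint annotations that share
an ancestor (*organelle*):

```python
from hvsm import OntologyGraph, build_vector, hvsm_similarity, vsm_similarity

terms = {
    "GO:0000001": {"name": "cell part", "namespace": "CC"},
    "GO:0000002": {"name": "organelle", "namespace": "CC"},
    "GO:0000003": {"name": "membrane-bounded organelle", "namespace": "CC"},
    "GO:0000004": {"name": "vesicle", "namespace": "CC"},
    "GO:0000005": {"name": "organelle membrane", "namespace": "CC"},
}
edges = {
    ("GO:0000002", "GO:0000001", "is_a"),
    ("GO:0000003", "GO:0000002", "is_a"),
    ("GO:0000004", "GO:0000003", "is_a"),
    ("GO:0000005", "GO:0000002", "part_of"),
}
graph = OntologyGraph(terms=terms, edges=edges)

v1 = build_vector({"GO:0000004"}, graph)   # gene 1: vesicle
v2 = build_vector({"GO:0000005"}, graph)   # gene 2: organelle membrane
print("gene 1 vector:", v1.weights)
print("gene 2 vector:", v2.weights)
print("flat VSM cosine:", vsm_similarity({"GO:0000004"}, {"GO:0000005"}))
print("HVSM similarity:", round(hvsm_similarity(v1, v2), 4))
```

prints

```
gene 1 vector: {'GO:0000004': 1.0, 'GO:0000003': 0.5, 'GO:0000002': 0.25}
gene 2 vector: {'GO:0000005': 1.0, 'GO:0000002': 0.35, 'GO:0000001': 0.175}
flat VSM cosine: 0.0
HVSM similarity: 0.0493
```

Gene 1's vector climbs the `is_a` chain (parent 0.5, grandparent 0.25);
gene 2's climbs through `part_of` (0.7-scaled: 0.35, 0.175).  The flat
cosine is blind to the relationship and returns 0, while the hierarchical
model detects it through the shared *organelle* component: the calibrated
similarity is ln(1+1) · cosine ≈ 0.049.

## Command line

```sh
# synthesize a seeded benchmark (OBO + GAF + labeled pairs)
hvsm simulate --seed 42 --out-dir bench/

# score the pairs with any measure
hvsm compute --obo bench/ontology.obo --gaf bench/annotations.gaf \
     --namespace CC --measure hvsm --pairs bench/pairs.tsv --out scores.tsv

# ROC/AUC against the labels ("partial" drops sentinel-scored pairs)
hvsm eval-roc --scores scores.tsv --pairs bench/pairs.tsv --mode partial
```

`compute` works unchanged on real GO releases (OBO) and GAF 2.x annotation
files.  Pairs with a gene missing from the annotations score the sentinel
−1, pairs whose computation fails score −2; both rank below every real
score in ROC sweeps, or can be dropped with `--mode partial`.

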