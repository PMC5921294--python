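# Methods

## Model

A gene product G annotated with the term set T(G) in one GO namespace is
represented as a sparse vector over that namespace's terms.  Construction
has four stages:

1. **Initialization.** Every directly annotated term gets weight 1.  These
   components are frozen: the cap at 1 makes every later update on them a
   no-op.
2. **`is_a` expansion**, four steps in order:
   i. every direct `is_a` parent of every annotated term — a zero component
      becomes `w_parent·w_is_a`, a nonzero one gains `w_incre·w_is_a`,
      capped at 1;
   ii. every `is_a` grandparent (two `is_a` edges), with both branches
      scaled by the ratio `w_r_g`;
   iii. every term that is a direct `is_a` child of **two or more**
      annotated terms — fresh value `w_child·w_is_a`, increment
      `w_child·w_incre·w_is_a`;
   iv. grandchildren common to two or more annotated terms, both branches
      additionally scaled by `w_r_g`.
3. **`part_of` expansion**: the same four steps with `w_part_of` in place
   of `w_is_a`.
4. **Similarity.** For vectors v₁, v₂ with S₁, S₂ direct terms:
   `ln(S₁+S₂) · (v₁·v₂)/(‖v₁‖‖v₂‖)`.

The expansion reaches exactly two steps in each direction: more distant
ancestors are considered too generic to carry gene-specific signal, and
descendants only matter where at least two annotated terms converge on
them.  The cosine is evaluated over the union of nonzero components, which
is exact — dimensions zero in both vectors contribute nothing to dot
product or norms (a unit test checks the sparse result against an explicit
dense evaluation to 1e-12).

### Parameters

All six contribution factors are unitless in [0, 1]:

| name       | default | meaning |
|------------|---------|---------|
| `w_is_a`   | 1       | relation factor for `is_a` edges |
| `w_part_of`| 0.7     | relation factor for `part_of` edges |
| `w_parent` | 0.5     | fresh-value factor for parents/grandparents |
| `w_child`  | 0.2     | fresh-value factor for common children |
| `w_incre`  | 1/6     | increment when several terms converge on a node |
| `w_r_g`    | 0.5     | extra discount for two-step (grand-) relatives |

The defaults encode the intended ordering `w_is_a > w_part_of`,
`w_parent > w_child`, `w_r_g < 1` (specialization outweighs composition,
ancestors outweigh descendants, distance discounts); constructing
parameters that violate the ordering logs a warning but is allowed, since
sweeping parameter space is a legitimate use.  A `cessm_profile()` preset
lowers `w_child` to 0.05 for CESSM-style score export, where common-child
credit is less appropriate than in PPI ranking.

### Semantics pinned down by this implementation

The staged description leaves a few orderings open; they are fixed here for
determinism and covered by the literal-reference oracle test:

* Steps run i → ii → iii → iv to completion, first for `is_a`, then for
  `part_of`; updates within a step see values written earlier in the same
  step.  Annotated terms are visited in sorted accession order.
* In steps i–ii each (annotated term, relative) incidence triggers one
  update: k annotated terms sharing a parent yield one fresh assignment
  plus k−1 increments.  In steps iii–iv a qualifying common (grand)child
  receives a single update.
* A two-step path mixing relations (`is_a` then `part_of` or vice versa)
  is handled in the `part_of` stage at the `part_of` rate; the `is_a`
  stage requires both edges to be `is_a`.
* The certainty factor counts **directly** annotated terms, before
  expansion.

Degenerate inputs: an empty term set is an error (a gene with no surviving
annotation should be absent from the annotation set, and pair scoring maps
it to the −1 sentinel); terms absent from the ontology are an error at
vector construction, which pair scoring maps to −2.

## Parsing

OBO files are read with `obonet` and reduced to the two hierarchical
relations; other relationship types (`regulates`, `occurs_in`, ...) are
discarded, as are obsolete terms, cross-namespace edges and (at annotation
time) NOT-qualified GAF rows.  `alt_id` accessions resolve to their
canonical term.  Per-relation acyclicity is validated at construction.
GAF rows are filtered by aspect, evidence policy (`IEA+` keeps everything,
`IEA-` drops electronic annotations) and membership in the loaded ontology;
the namespace root is removed from every gene's set because annotation to
the root carries no information (every gene trivially belongs to it).

## Baseline measures

* **Basic VSM**: binary cosine |T₁∩T₂|/√(|T₁||T₂|).
* **Jaccard / Dice**: set-overlap ratios on the direct annotation sets.
* **Information content**: IC(t) = −ln p(t) with p(t) the fraction of
  corpus genes annotated to t or any descendant (propagation through both
  relations); the loaded annotation set is the corpus.
* **Resnik / Lin / Jiang / Schlicker** on term pairs through the most
  informative common ancestor (MICA; ancestors via both relations, a term
  counting as its own ancestor), combined at gene level by MAX (default),
  AVG or best-match-average.  Jiang's distance is mapped to a similarity
  as 1/(1+d) — a bounded, monotone transform; no canonical choice exists.
* **SimGIC**: IC-weighted Jaccard over ancestor-closed sets.
* **IntelliGO**: weighted-basis cosine with basis products
  2·Depth(LCA)/(MinSPL+2·Depth(LCA)).  Depth is the minimum edge distance
  from the namespace root over both relations; the LCA is the deepest
  common ancestor, ties broken by the shorter through-path.  Evidence-code
  weights default to 1 for every code and are configurable.

## ROC evaluation

Pairs are ranked by score; thresholds sweep the distinct values in
descending order with tied scores moving as one block, so a tie produces a
single diagonal segment whose trapezoid credits half of the tied
pos/neg pairs.  The resulting area is identical (to 1e-10 in tests) to the
Mann–Whitney statistic P(score⁺ > score⁻) + ½P(tie), which serves as the
independent oracle.  Sentinel scores rank strictly below every real score,
−1 above −2 (the relative order of the two sentinel classes is a
convention of this package; "partial" mode sidesteps it by dropping
sentinel pairs before the sweep).

The AUC is reported as the full trapezoidal sum Σ(Xₖ−Xₖ₋₁)(Yₖ+Yₖ₋₁)/2 over
the stored step points — the standard composite trapezoidal rule for a
step curve from (0,0) to (1,1).

## Synthetic benchmarks

The fixture generator emulates the structure of a PPI benchmark without
any downloads: a layered random DAG (single root, every non-root term with
1–2 parents drawn from the previous layer, layer sizes growing ~2.5× so
depth is 6–7 at 200 terms; each edge `part_of` with probability 0.2 except
in MF, which has no `part_of` relation), 100 background genes with 2–6
uniform random direct terms, and balanced 300+300 pair sets.  The 1–2
parent range mirrors real GO, where terms average fewer than two parents;
denser DAGs make randomly chosen gene pairs spuriously related, which no
annotation corpus exhibits.

Positive pairs are engineered per signal mode; the engineered genes are
appended to the annotation set so the benchmark is self-contained:

* **shared-term** — the pair shares its direct terms (full overlap by
  default; `share_frac` tunes partial overlap).  Detectable by every
  measure; the flat cosine is near-ceiling here, so this mode checks that
  hierarchy expansion does not *hurt* an easy signal.
* **sibling-term** — the pair is annotated to disjoint children of common
  parents.  Flat set/vector measures score these pairs exactly 0; only
  hierarchy-aware measures separate them from random pairs.  This is the
  headline fixture for what the hierarchical model adds.
* **parent-child** — one gene carries terms, the other their direct
  parents.
* **none** — positives drawn like negatives; any measure's AUC must sit
  near 0.5 (a Monte-Carlo check with tolerance 0.05 at 1000 pairs).

Negatives are uniform random pairs of background genes excluding planted
positives, mirroring the random-pair construction of real negative PPI
sets.  All draws come from per-stage `numpy` Generator streams keyed by
(seed, stage), so identical spec + seed reproduces byte-identical OBO/GAF/
TSV output.

What passing these benchmarks does **not** show: real GO topology (depth
and fan-out distributions, term-count skew), annotation bias (well-studied
genes carry more terms), or evidence-code structure are not emulated, so
desk-scale AUCs say nothing quantitative about AUCs on curated interaction
databases — they verify signal recovery and the qualitative ordering
(hierarchy-aware above flat on sibling-type relatedness).

## Problem sizes

The default test and acceptance runs use 200-term ontologies, 100–800
genes and 600–1000 pairs; exact-agreement oracles run on DAGs of at most
12 terms where literal dense evaluation is tractable.  These sizes give
stable Monte-Carlo estimates at sub-second runtimes; all thresholds in the
test suite (AUC ≥ 0.8 on shared-term signal, hierarchical-minus-flat gap
≥ 0.05 on sibling signal, null AUC within 0.05 of one half) were fixed
alongside the generator defaults.

## Known limitations

* Scores exceed 1 because of the certainty factor; no normalization is
  applied (rank-based evaluation is unaffected, but single scores are not
  directly interpretable as a fraction).
* The IC corpus is the loaded annotation file; corpus choice shifts all
  IC-based baselines.
* IntelliGO's published evidence-weight table is not reproduced; weights
  default to 1.
* Cross-namespace composite scoring (combining BP/CC/MF) is out of scope,
  as is learning the contribution factors from data.
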