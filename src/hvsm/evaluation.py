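"""Scoring labeled gene-pair datasets and ROC/AUC evaluation.

A benchmark is a list of gene pairs labeled 1 (interacting) or 0.  Every
pair receives a similarity score; pairs with an unresolvable gene score the
sentinel −1 and pairs whose computation fails score −2, following the
convention of treating problematic pairs as minimally similar.  The ROC
sweep ranks pairs by score (ties move as one block, sentinels at the
bottom, −1 above −2) and the AUC is the trapezoidal area under the
resulting step curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotations import AnnotationSet
from .baselines import (
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
from .core import (
    SENTINEL_ERROR,
    SENTINEL_MISSING,
    HVSMParams,
    build_vector,
    hvsm_similarity,
)
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

MEASURES = (
    "hvsm", "vsm", "resnik", "lin", "jiang", "schlicker",
    "simgic", "jaccard", "dice", "intelligo",
)

SENTINELS = (SENTINEL_MISSING, SENTINEL_ERROR)


@dataclass
class PairDataset:
    """Labeled (or unlabeled) gene pairs over one namespace."""

    pairs: list[tuple[str, str, int | None]]
    namespace: str = "CC"

    def __post_init__(self) -> None:
        seen: set[frozenset] = set()
        deduped = []
        dropped = 0
        for a, b, label in self.pairs:
            key = frozenset((a, b))
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
            deduped.append((a, b, label))
        if dropped:
            logger.info("dropped %d duplicate unordered pairs", dropped)
        self.pairs = deduped

    def labels(self) -> list[int]:
        return [lab for _, _, lab in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def read_pairs(path, namespace: str = "CC") -> PairDataset:
    """Read a TSV pair file: geneA, geneB, optional 0/1 label; '#' comments."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed pair line: {line!r}")
            label = int(fields[2]) if len(fields) > 2 and fields[2] != "" else None
            if label not in (0, 1, None):
                raise ValueError(f"label must be 0/1, got {fields[2]!r}")
            pairs.append((fields[0], fields[1], label))
    return PairDataset(pairs=pairs, namespace=namespace)


@dataclass
class ROCResult:
    """ROC step points from (0,0) to (1,1) and their trapezoidal area."""

    points: list[tuple[float, float]]
    auc: float
    n_pos: int
    n_neg: int
    n_sentinel: int = 0


class _ScoreContext:
    """Shared per-measure state (IC table, IntelliGO caches), built lazily."""

    def __init__(self, ann: AnnotationSet, graph: OntologyGraph):
        self.ann = ann
        self.graph = graph
        self._ic = None
        self._intelligo_ctx = None

    @property
    def ic(self):
        if self._ic is None:
            self._ic = compute_ic(self.ann, self.graph)
        return self._ic

    @property
    def intelligo_ctx(self):
        if self._intelligo_ctx is None:
            self._intelligo_ctx = _IntelliGOContext(self.graph, self.ann.namespace)
        return self._intelligo_ctx


def _score_pair(
    measure: str,
    gene_a: str,
    gene_b: str,
    ctx: _ScoreContext,
    params: HVSMParams,
    combine: str,
    intelligo_cfg: IntelliGOConfig | None,
) -> float:
    ann, graph = ctx.ann, ctx.graph
    terms_a = ann.gene_terms.get(gene_a)
    terms_b = ann.gene_terms.get(gene_b)
    if not terms_a or not terms_b:
        return SENTINEL_MISSING
    if measure == "hvsm":
        va = build_vector(terms_a, graph, params)
        vb = build_vector(terms_b, graph, params)
        return hvsm_similarity(va, vb)
    if measure == "vsm":
        return vsm_similarity(terms_a, terms_b)
    if measure in ("jaccard", "dice"):
        return set_similarity(terms_a, terms_b, measure)
    if measure == "simgic":
        return simgic_similarity(terms_a, terms_b, ctx.ic, graph)
    if measure == "intelligo":
        return intelligo_similarity(
            gene_a, gene_b, ann, graph, intelligo_cfg,
            _context=ctx.intelligo_ctx,
        )
    if measure in ("resnik", "lin", "jiang", "schlicker"):
        fn = lambda t1, t2: term_similarity(t1, t2, ctx.ic, graph, measure)
        return combine_pairwise(terms_a, terms_b, fn, combine)
    raise ValueError(f"unknown measure {measure!r}")


def score_dataset(
    ds: PairDataset,
    measure: str,
    ann: AnnotationSet,
    graph: OntologyGraph,
    params: HVSMParams | None = None,
    combine: str = "MAX",
    intelligo_cfg: IntelliGOConfig | None = None,
) -> list[tuple[tuple[str, str, int | None], float]]:
    """Score every pair of *ds* with *measure*, preserving input order.

    Missing genes yield the −1 sentinel, internal computation failures −2;
    no exception escapes a single pair.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if params is None:
        params = HVSMParams()
    ctx = _ScoreContext(ann, graph)
    out = []
    n_err = 0
    for pair in ds.pairs:
        a, b, _ = pair
        try:
            score = _score_pair(measure, a, b, ctx, params, combine,
                                intelligo_cfg)
        except Exception:
            logger.exception("scoring failed for pair (%s, %s)", a, b)
            score = SENTINEL_ERROR
            n_err += 1
        out.append((pair, score))
    if n_err:
        logger.warning("%d pairs scored with the error sentinel", n_err)
    return out


def _rank_key(score: float) -> tuple[int, float]:
    # sentinels sort strictly below every real score; -1 above -2
    if score == SENTINEL_MISSING:
        return (0, -1.0)
    if score == SENTINEL_ERROR:
        return (0, -2.0)
    return (1, score)


def roc_auc(scores, labels, drop_sentinels: bool = False) -> ROCResult:
    """ROC step curve and trapezoidal AUC for scored binary labels.

    Thresholds sweep the distinct score values in descending order; tied
    scores move as a single block, producing one diagonal segment whose
    trapezoid credits half the ties — this makes the area identical to the
    rank-statistic (Mann-Whitney) formulation.  Sentinel scores (−1/−2)
    rank below every real score.  ``drop_sentinels=True`` is "partial"
    mode: sentinel pairs are removed before the sweep.
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    items = list(zip(scores, labels))
    n_sentinel = sum(1 for s, _ in items if s in SENTINELS)
    if drop_sentinels:
        items = [(s, l) for s, l in items if s not in SENTINELS]
    for _, lab in items:
        if lab not in (0, 1):
            raise ValueError(f"labels must be 0/1, got {lab!r}")
    n_pos = sum(lab for _, lab in items)
    n_neg = len(items) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    items.sort(key=lambda sl: _rank_key(sl[0]), reverse=True)
    points = [(0.0, 0.0)]
    auc = 0.0
    tp = fp = 0
    i = 0
    while i < len(items):
        j = i
        key = _rank_key(items[i][0])
        while j < len(items) and _rank_key(items[j][0]) == key:
            j += 1
        block = items[i:j]
        tp += sum(lab for _, lab in block)
        fp += len(block) - sum(lab for _, lab in block)
        x, y = fp / n_neg, tp / n_pos
        x0, y0 = points[-1]
        auc += (x - x0) * (y + y0) / 2.0
        points.append((x, y))
        i = j
    return ROCResult(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg,
                     n_sentinel=n_sentinel)


def export_scores(scored, path, fmt: str = "tsv") -> None:
    """Write scored pairs as three-column text: geneA, geneB, score.

    Scores print with six decimal places; sentinel values are retained so
    downstream consumers decide how to treat problematic pairs.  The
    ``cessm`` format is the same layout with identifiers exactly as read
    from the pair file and no header, ready for upload.
    """
    if fmt not in ("tsv", "cessm"):
        raise ValueError(f"unknown export format {fmt!r}")
    with open(path, "w") as fh:
        for (a, b, _), score in scored:
            fh.write(f"{a}\t{b}\t{score:.6f}\n")
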