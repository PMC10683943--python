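"""Official-style scoring for CEM -> GPRO relation extraction.

A predicted or gold relation is identified by the tuple
(PMID, relation type, chemical term id, gene term id).  Scores are
micro-averaged: true/false positives and false negatives are pooled over all
documents and relation types before computing precision, recall and F1.
A CEM-GPRO pair may carry several relation types; each type is evaluated
independently as its own key.

Background documents — unscored documents mixed into a test release to
prevent manual annotation — are handled by dropping every prediction whose
PMID is outside the scored set before comparison.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from .corpus_io import (
    Document,
    EntityMention,
    RELATION_TYPES,
    RelationAnnotation,
    entity_index,
)

logger = logging.getLogger(__name__)


class RelationKey(NamedTuple):
    """Evaluation identity of a relation: field-wise equality."""

    pmid: str
    rel_type: str
    chem_term: str
    gene_term: str


@dataclass
class TypeScores:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationResult:
    """Micro-averaged counts and scores, globally and per relation type."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_type: dict[str, TypeScores] = field(default_factory=dict)


@dataclass
class ErrorProfile:
    """False-negative/-positive breakdowns by type, entity and distance."""

    fn_by_type: dict[str, int]
    fp_by_type: dict[str, int]
    fn_by_entity: dict[str, int]
    fp_by_entity: dict[str, int]
    fn_distance_histogram: dict[int, int]  # bin start offset -> count


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    # zero-denominator convention: scores default to 0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def key_of(rel: RelationAnnotation) -> RelationKey:
    return RelationKey(rel.pmid, rel.rel_type, rel.arg1, rel.arg2)


def normalize_predictions(
    preds: Iterable[RelationAnnotation],
    scored_pmids: Optional[set[str]] = None,
    strict: bool = True,
) -> set[RelationKey]:
    """Collapse duplicates and drop background-document predictions.

    ``scored_pmids=None`` scores every document.  Unknown relation types
    raise in strict mode and are dropped with a warning otherwise.
    """
    keys: set[RelationKey] = set()
    for rel in preds:
        if rel.rel_type not in RELATION_TYPES:
            if strict:
                raise ValueError(f"unknown relation type {rel.rel_type!r}")
            logger.warning("dropping prediction with unknown type %r", rel.rel_type)
            continue
        if scored_pmids is not None and rel.pmid not in scored_pmids:
            continue
        keys.add(key_of(rel))
    return keys


def evaluate(gold: set[RelationKey], pred: set[RelationKey]) -> EvaluationResult:
    """Micro-averaged P/R/F1 of ``pred`` against ``gold``, with per-type rows.

    tp = |gold ∩ pred|, fp = |pred \\ gold|, fn = |gold \\ pred|; the type is
    part of the key, so per-type counts partition the global counts exactly.
    """
    tp = len(gold & pred)
    fp = len(pred - gold)
    fn = len(gold - pred)
    p, r, f1 = _prf(tp, fp, fn)
    per_type: dict[str, TypeScores] = {}
    for t in RELATION_TYPES:
        g = {k for k in gold if k.rel_type == t}
        q = {k for k in pred if k.rel_type == t}
        ttp, tfp, tfn = len(g & q), len(q - g), len(g - q)
        tprec, trec, tf1 = _prf(ttp, tfp, tfn)
        per_type[t] = TypeScores(ttp, tfp, tfn, tprec, trec, tf1)
    return EvaluationResult(tp, fp, fn, p, r, f1, per_type)


def span_distance(a: EntityMention, b: EntityMention) -> int:
    """Character gap between the nearer edges of two spans; 0 if they touch
    or overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def error_profile(
    gold: set[RelationKey],
    pred: set[RelationKey],
    entities: Sequence[EntityMention],
    docs: Sequence[Document] = (),
    bin_width: int = 50,
) -> ErrorProfile:
    """Break down false negatives and false positives for error analysis.

    Counts are keyed by relation type and by the surface forms of both
    participating entities; false negatives are additionally histogrammed by
    the character distance between the chemical and gene spans (bins of
    ``bin_width`` characters, keyed by bin start).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    index = entity_index(entities)

    def resolve(key: RelationKey) -> tuple[EntityMention, EntityMention]:
        try:
            return index[(key.pmid, key.chem_term)], index[(key.pmid, key.gene_term)]
        except KeyError as exc:
            raise ValueError(f"unresolvable term id in {key}: {exc}") from exc

    fn_keys = gold - pred
    fp_keys = pred - gold
    fn_by_type: Counter = Counter(k.rel_type for k in fn_keys)
    fp_by_type: Counter = Counter(k.rel_type for k in fp_keys)
    fn_by_entity: Counter = Counter()
    fp_by_entity: Counter = Counter()
    fn_hist: Counter = Counter()
    for k in fn_keys:
        chem, gene = resolve(k)
        fn_by_entity[chem.text] += 1
        fn_by_entity[gene.text] += 1
        d = span_distance(chem, gene)
        fn_hist[(d // bin_width) * bin_width] += 1
    for k in fp_keys:
        chem, gene = resolve(k)
        fp_by_entity[chem.text] += 1
        fp_by_entity[gene.text] += 1
    return ErrorProfile(
        fn_by_type=dict(fn_by_type),
        fp_by_type=dict(fp_by_type),
        fn_by_entity=dict(fn_by_entity),
        fp_by_entity=dict(fp_by_entity),
        fn_distance_histogram=dict(sorted(fn_hist.items())),
    )
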