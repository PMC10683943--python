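"""Candidate generation for CEM -> GPRO relation classification.

Implements the two stages shared by most relation-extraction pipelines on
this corpus:

* the *max-recall baseline*, which emits every same-sentence chemical/gene
  co-mention under all 13 relation types — by construction it recovers every
  intra-sentence gold relation, at the cost of precision;
* *example generation* in the style of cross-sentence window classifiers: a
  candidate pair produces a training/inference example whenever the two
  mentions and the words before, between and after them fit into a token
  window (default 128 tokens).  The two focus entities are either *marked*
  by inserting reserved open/close tokens around them (e.g.
  ``[unused1] insulin [unused2]``) or *masked* by replacing them with a role
  placeholder.

Sentence splitting is deterministic and rule-based; any boundary that would
fall inside an entity span is suppressed, so no mention ever straddles a
sentence boundary.  The tokenizer is pluggable: any object with a
``tokenize(text) -> list[Token]`` method where tokens carry character
offsets satisfies the contract, so a subword tokenizer can be swapped in
without changing pipeline semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np

from .corpus_io import (
    Document,
    EntityMention,
    RELATION_TYPES,
    RelationAnnotation,
)

# Reserved marker tokens (mirroring unused slots of subword vocabularies).
CHEM_OPEN = "[unused1]"
CHEM_CLOSE = "[unused2]"
GENE_OPEN = "[unused3]"
GENE_CLOSE = "[unused4]"
MARKER_TOKENS = frozenset({CHEM_OPEN, CHEM_CLOSE, GENE_OPEN, GENE_CLOSE})

CHEM_MASK = "[CHEM]"
GENE_MASK = "[GENE]"

#: Dotted abbreviations that never end a sentence.
ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "cf", "vs", "et al", "Fig", "fig", "Figs", "ca", "approx",
     "No", "no", "Dr", "wt", "conc"}
)


class SentenceSpan(NamedTuple):
    """Half-open character span of one sentence in ``full_text``."""

    start: int
    end: int


class Token(NamedTuple):
    """A surface token with half-open character offsets."""

    text: str
    start: int
    end: int


class RegexTokenizer:
    """Deterministic word/punctuation tokenizer with character offsets.

    Splits on word-character runs and single non-space punctuation marks; the
    recorded offsets reconstruct the input exactly (whitespace is the gap
    between consecutive tokens).
    """

    _pattern = re.compile(r"\w+|[^\w\s]")

    def tokenize(self, text: str) -> list[Token]:
        return [
            Token(m.group(), m.start(), m.end())
            for m in self._pattern.finditer(text)
        ]


@dataclass(frozen=True)
class CandidatePair:
    """An ordered chemical/gene mention pair within one document."""

    pmid: str
    chem: EntityMention
    gene: EntityMention
    same_sentence: bool
    token_span_length: int

    def __post_init__(self) -> None:
        if not self.chem.is_chemical:
            raise ValueError(f"chem argument has type {self.chem.etype}")
        if not self.gene.is_gene:
            raise ValueError(f"gene argument has type {self.gene.etype}")


@dataclass(frozen=True)
class Example:
    """A tokenized classification example for one candidate pair."""

    pair: CandidatePair
    tokens: tuple[str, ...]
    label: frozenset[str]


# ---------------------------------------------------------------------------
# Sentence splitting


def split_sentences(
    doc: Document, entities: Sequence[EntityMention] = ()
) -> list[SentenceSpan]:
    """Deterministic sentence spans over ``doc.full_text``.

    Boundaries are placed after terminal punctuation followed by whitespace
    and an uppercase letter, digit or opening bracket, and at the tab that
    joins title and abstract.  A boundary is suppressed when the terminator
    lies inside an entity span (e.g. a dotted unit inside a chemical name)
    or when it closes a known abbreviation.  Text without any terminal
    punctuation yields a single span.
    """
    text = doc.full_text
    spans = [(e.start, e.end) for e in entities if e.pmid == doc.pmid]

    def inside_entity(pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    cuts: set[int] = set()
    for m in re.finditer(r"[.!?]+", text):
        q = m.end()
        if q >= len(text) or not text[q].isspace():
            continue
        rest = text[q:].lstrip()
        if not rest or not (rest[0].isupper() or rest[0].isdigit() or rest[0] in "(["):
            continue
        if inside_entity(m.start()):
            continue
        prev = re.search(r"([A-Za-z][A-Za-z.]*)$", text[: m.start()])
        if prev and prev.group(1) in ABBREVIATIONS:
            continue
        cuts.add(q)
    for m in re.finditer(r"\t", text):
        if not inside_entity(m.start()):
            cuts.add(m.end())

    sentences: list[SentenceSpan] = []
    prev_cut = 0
    for cut in sorted(cuts) + [len(text)]:
        segment = text[prev_cut:cut]
        stripped = segment.strip()
        if stripped:
            start = prev_cut + (len(segment) - len(segment.lstrip()))
            sentences.append(SentenceSpan(start, start + len(stripped)))
        prev_cut = cut
    return sentences


def _sentence_index(
    sentences: Sequence[SentenceSpan], entity: EntityMention
) -> Optional[int]:
    for i, s in enumerate(sentences):
        if s.start <= entity.start < s.end:
            return i
    return None


# ---------------------------------------------------------------------------
# Pair enumeration


def enumerate_pairs(
    doc: Document,
    entities: Sequence[EntityMention],
    scope: Union[str, int] = "sentence",
    tokenizer=None,
) -> list[CandidatePair]:
    """All ordered CEM -> GPRO mention pairs of a document, scope-filtered.

    ``scope="sentence"`` keeps only same-sentence pairs.  An integer scope is
    a token window: a pair is kept when its minimal token span plus the four
    marker tokens fits, cross-sentence pairs included.
    """
    tokenizer = tokenizer or RegexTokenizer()
    doc_entities = [e for e in entities if e.pmid == doc.pmid]
    chems = [e for e in doc_entities if e.is_chemical]
    genes = [e for e in doc_entities if e.is_gene]
    if not chems or not genes:
        return []
    sentences = split_sentences(doc, doc_entities)
    tokens = tokenizer.tokenize(doc.full_text)
    starts = np.array([t.start for t in tokens])
    ends = np.array([t.end for t in tokens])

    pairs: list[CandidatePair] = []
    for chem in chems:
        ci = _sentence_index(sentences, chem)
        for gene in genes:
            lo = min(chem.start, gene.start)
            hi = max(chem.end, gene.end)
            # tokens overlapping [lo, hi)
            span_len = int(np.sum((ends > lo) & (starts < hi)))
            same = ci is not None and ci == _sentence_index(sentences, gene)
            pair = CandidatePair(
                pmid=doc.pmid,
                chem=chem,
                gene=gene,
                same_sentence=same,
                token_span_length=span_len,
            )
            if scope == "sentence":
                if same:
                    pairs.append(pair)
            elif isinstance(scope, int):
                if span_len + 4 <= scope:
                    pairs.append(pair)
            else:
                raise ValueError(f"scope must be 'sentence' or an int, got {scope!r}")
    return pairs


def max_recall_baseline(
    docs: Sequence[Document], entities: Sequence[EntityMention]
) -> list[RelationAnnotation]:
    """Every same-sentence co-mention under all 13 types, deduplicated.

    Recall is 1.0 on any corpus whose gold relations are intra-sentence;
    precision is |gold| / (13 x #pairs) when each pair carries at most one
    gold type.
    """
    out: set[RelationAnnotation] = set()
    for doc in docs:
        for pair in enumerate_pairs(doc, entities, scope="sentence"):
            for rel_type in RELATION_TYPES:
                out.add(
                    RelationAnnotation(
                        pmid=doc.pmid,
                        rel_type=rel_type,
                        arg1=pair.chem.term_id,
                        arg2=pair.gene.term_id,
                    )
                )
    return sorted(out, key=lambda r: (r.pmid, r.arg1, r.arg2, r.rel_type))


# ---------------------------------------------------------------------------
# Example generation


def _focus_range(
    tokens: Sequence[Token], entity: EntityMention
) -> tuple[int, int]:
    """Half-open token index range of tokens overlapping the entity span."""
    idx = [
        i for i, t in enumerate(tokens) if t.end > entity.start and t.start < entity.end
    ]
    if not idx:
        raise ValueError(f"entity {entity.term_id} covered by no token")
    return idx[0], idx[-1] + 1


def generate_examples(
    docs: Sequence[Document],
    entities: Sequence[EntityMention],
    relations: Sequence[RelationAnnotation] = (),
    tokenizer=None,
    window: int = 128,
    style: str = "mark",
    label_mode: str = "multi",
    negative_subsample: Optional[float] = None,
    seed: int = 0,
) -> list[Example]:
    """Generate one classification example per window-fitting candidate pair.

    The minimal token span covering both mentions is padded with the
    remaining budget split evenly before and after (left-biased on odd
    remainders).  ``style="mark"`` inserts the four reserved marker tokens
    around the focus mentions; ``style="mask"`` replaces each focus mention
    with a single role placeholder.  Labels come from the gold relations of
    the pair (multi-label by default; ``label_mode="single"`` keeps the
    lexicographically first type).  ``negative_subsample`` keeps unlabeled
    pairs with the given probability (default: keep all).
    """
    if window < 8:
        raise ValueError(f"window must be >= 8 tokens, got {window}")
    if style not in ("mark", "mask"):
        raise ValueError(f"style must be 'mark' or 'mask', got {style!r}")
    if label_mode not in ("multi", "single"):
        raise ValueError(f"label_mode must be 'multi' or 'single', got {label_mode!r}")
    tokenizer = tokenizer or RegexTokenizer()
    rng = np.random.default_rng(seed)

    labels: dict[tuple[str, str, str], set[str]] = {}
    for r in relations:
        labels.setdefault((r.pmid, r.arg1, r.arg2), set()).add(r.rel_type)

    examples: list[Example] = []
    for doc in docs:
        tokens = tokenizer.tokenize(doc.full_text)
        for pair in enumerate_pairs(doc, entities, scope=window, tokenizer=tokenizer):
            cs, ce = _focus_range(tokens, pair.chem)
            gs, ge = _focus_range(tokens, pair.gene)
            lo, hi = min(cs, gs), max(ce, ge)
            budget = window - 4 - (hi - lo)
            before = (budget + 1) // 2  # left-biased on odd remainders
            after = budget - before
            take_left = min(before, lo)
            take_right = min(after + (before - take_left), len(tokens) - hi)
            take_left = min(take_left + (after + before - take_left - take_right), lo)
            start, end = lo - take_left, hi + take_right
            surfaces = [t.text for t in tokens[start:end]]
            c0, c1 = cs - start, ce - start
            g0, g1 = gs - start, ge - start
            if style == "mark":
                inserts = sorted(
                    [(c1, CHEM_CLOSE), (c0, CHEM_OPEN), (g1, GENE_CLOSE), (g0, GENE_OPEN)],
                    key=lambda x: -x[0],
                )
                for pos, marker in inserts:
                    surfaces.insert(pos, marker)
            else:
                # replace later focus first so earlier indices stay valid
                for (a, b), mask in sorted(
                    [((c0, c1), CHEM_MASK), ((g0, g1), GENE_MASK)],
                    key=lambda x: -x[0][0],
                ):
                    surfaces[a:b] = [mask]
            label = frozenset(
                labels.get((pair.pmid, pair.chem.term_id, pair.gene.term_id), ())
            )
            if label_mode == "single" and label:
                label = frozenset([min(label)])
            if not label and negative_subsample is not None:
                if rng.random() >= negative_subsample:
                    continue
            examples.append(Example(pair=pair, tokens=tuple(surfaces), label=label))
    return examples


def strip_markers(tokens: Iterable[str]) -> tuple[str, ...]:
    """Remove the four reserved marker tokens (inverse of marking)."""
    return tuple(t for t in tokens if t not in MARKER_TOKENS)


# ---------------------------------------------------------------------------
# Pluggable classification


class ReferenceRelationClassifier:
    """Sparse lexical bag-of-tokens multi-label classifier.

    A deliberately lightweight reference model — token counts fed to one
    logistic-regression head per relation type — that makes the candidate ->
    example -> classify -> evaluate pipeline runnable end to end at desk
    scale.  Any object with ``fit(examples)`` and
    ``predict(examples) -> list[frozenset[str]]`` satisfies the classifier
    contract.
    """

    def __init__(self, C: float = 10.0) -> None:
        self.C = C
        self._vectorizer = None
        self._heads: dict[str, object] = {}

    def fit(self, examples: Sequence[Example]) -> "ReferenceRelationClassifier":
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.linear_model import LogisticRegression

        if not examples:
            raise ValueError("cannot fit on an empty example collection")
        self._vectorizer = CountVectorizer(analyzer=lambda toks: toks)
        X = self._vectorizer.fit_transform([list(e.tokens) for e in examples])
        observed = sorted({t for e in examples for t in e.label})
        self._heads = {}
        for rel_type in observed:
            y = np.array([int(rel_type in e.label) for e in examples])
            if y.min() == y.max():
                self._heads[rel_type] = int(y[0])  # constant head
            else:
                clf = LogisticRegression(C=self.C, max_iter=1000)
                clf.fit(X, y)
                self._heads[rel_type] = clf
        return self

    def predict(self, examples: Sequence[Example]) -> list[frozenset[str]]:
        if self._vectorizer is None:
            raise RuntimeError("classifier is not fitted")
        X = self._vectorizer.transform([list(e.tokens) for e in examples])
        votes = [set() for _ in examples]
        for rel_type, head in self._heads.items():
            if isinstance(head, int):
                pred = np.full(len(examples), head)
            else:
                pred = head.predict(X)
            for i, keep in enumerate(pred):
                if keep:
                    votes[i].add(rel_type)
        return [frozenset(v) for v in votes]


def classify_examples(
    examples: Sequence[Example], classifier
) -> list[RelationAnnotation]:
    """Apply a fitted classifier and convert positive predictions to
    relation annotations (one per predicted type; possibly none)."""
    out: list[RelationAnnotation] = []
    for example, types in zip(examples, classifier.predict(examples)):
        for rel_type in sorted(types):
            out.append(
                RelationAnnotation(
                    pmid=example.pair.pmid,
                    rel_type=rel_type,
                    arg1=example.pair.chem.term_id,
                    arg2=example.pair.gene.term_id,
                )
            )
    return out
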