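"""Seeded synthetic corpora and degraded prediction runs.

The generator emits complete DrugProt-dialect corpora — abstracts, offset-
anchored entity mentions and CEM -> GPRO relations — with the structural
features that matter to the downstream machinery:

* surface forms are drawn from synthetic vocabularies (``CHEM-00042``,
  ``GENE-00017``) with Zipf-law frequencies, reproducing the heavy rarity of
  real mention vocabularies;
* relation types are sampled with weights proportional to the published
  per-type totals of the gold corpus, so type imbalance (inhibitor
  dominance, near-absent agonist-activator) is emulated;
* every planted relation's mentions co-occur within one sentence, except a
  configurable fraction placed in adjacent sentences (cross-sentence
  relations);
* unrelated co-mentions ("distractors") are planted so that candidate
  enumeration yields more pairs than gold relations.

Prediction runs are degraded copies of the gold standard: each gold key is
kept independently with probability ``target_recall`` and false keys are
added from a candidate pool so that precision matches ``target_precision``
in expectation.  Each emitted record carries the run's *realized* precision,
mirroring how real silver-standard predictions are tagged with the run's
test-set precision.

Everything is deterministic given the seeds: the same configuration writes
byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .candidates import enumerate_pairs
from .corpus_io import (
    CHEMICAL,
    Document,
    EntityMention,
    GENE_N,
    GENE_Y,
    PathLike,
    PredictionRecord,
    RELATION_TYPES,
    RelationAnnotation,
    TITLE_ABSTRACT_JOINER,
    write_abstracts,
    write_entities,
    write_relations,
)
from .evaluation import RelationKey, key_of


def default_rel_type_weights() -> dict[str, float]:
    """Relation-type weights proportional to the gold corpus per-type totals."""
    with resources.files("drugprotkit.data").joinpath(
        "gold_relation_counts.tsv"
    ).open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh, sep="\t", index_col=0)
    totals = table.sum(axis=1)
    return {t: float(totals[t]) / float(totals.sum()) for t in RELATION_TYPES}


@dataclass
class SynthConfig:
    """Configuration of one synthetic corpus.

    Defaults mirror the gold corpus where a published figure exists: the
    mean of ~4.9 relations per abstract matches its 24 526 relations over
    5000 abstracts, and the type weights follow its per-type totals.
    """

    n_docs: int = 100
    chem_vocab: int = 400
    gene_vocab: int = 400
    zipf_exponent: float = 1.5
    rel_type_weights: dict[str, float] = field(default_factory=default_rel_type_weights)
    relations_per_doc: float = 4.9  # Poisson mean
    distractors_per_doc: float = 1.0  # Poisson mean of unrelated co-mentions
    cross_sentence_fraction: float = 0.1
    gene_y_fraction: float = 0.7  # share of GPRO mentions typed GENE-Y
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.chem_vocab < 1 or self.gene_vocab < 1:
            raise ValueError("vocabulary too small: need at least one surface form")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if not 0.0 <= self.cross_sentence_fraction <= 1.0:
            raise ValueError("cross_sentence_fraction must be in [0, 1]")
        weights = [self.rel_type_weights.get(t, 0.0) for t in RELATION_TYPES]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("rel_type_weights must be non-negative, not all zero")


@dataclass(frozen=True)
class RunSpec:
    """Target operating point of one degraded prediction run."""

    team: str
    run: Union[str, int]
    target_precision: float
    target_recall: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_precision <= 1.0:
            raise ValueError("target_precision must be in (0, 1]")
        if not 0.0 < self.target_recall <= 1.0:
            raise ValueError("target_recall must be in (0, 1]")


@dataclass
class RunOutcome:
    """Realized operating point of a generated run."""

    precision: float
    recall: float
    n_predictions: int


_TEMPLATES: dict[str, str] = {
    "ANTAGONIST": "{chem} acted as a potent antagonist of {gene}.",
    "AGONIST": "{chem} behaved as a selective agonist of {gene}.",
    "AGONIST-ACTIVATOR": "Binding of {chem} agonized and thereby activated {gene}.",
    "AGONIST-INHIBITOR": "{chem} engaged {gene} as an agonist yet blunted its output.",
    "DIRECT-REGULATOR": "{chem} bound directly to {gene} in competition assays.",
    "ACTIVATOR": "{chem} markedly activated {gene} in treated cells.",
    "INHIBITOR": "{chem} potently inhibited {gene} activity.",
    "INDIRECT-DOWNREGULATOR": "Treatment with {chem} lowered {gene} expression levels.",
    "INDIRECT-UPREGULATOR": "Exposure to {chem} raised {gene} expression levels.",
    "PART-OF": "{chem} is a structural component of {gene}.",
    "PRODUCT-OF": "{chem} accumulated as a product of {gene} catalysis.",
    "SUBSTRATE": "{chem} served as a substrate of {gene}.",
    "SUBSTRATE_PRODUCT-OF": "{chem} acted as both substrate and product of {gene}.",
}
_CROSS_FIRST = "{chem} was administered before any measurement."
_CROSS_SECOND = "A marked shift in {gene} activity followed."
_DISTRACTOR = "Levels of {chem} and {gene} were assayed in parallel."


def _fill(template: str, slots: dict[str, str]) -> tuple[str, list[tuple[str, int, int]]]:
    """Substitute {chem}/{gene} slots, returning text and slot offsets."""
    parts: list[str] = []
    placed: list[tuple[str, int, int]] = []
    pos = 0
    length = 0
    for m in re.finditer(r"\{(chem|gene)\}", template):
        parts.append(template[pos : m.start()])
        length += m.start() - pos
        surface = slots[m.group(1)]
        placed.append((m.group(1), length, length + len(surface)))
        parts.append(surface)
        length += len(surface)
        pos = m.end()
    parts.append(template[pos:])
    return "".join(parts), placed


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    weights = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return weights / weights.sum()


def generate_corpus(
    cfg: SynthConfig,
) -> tuple[list[Document], list[EntityMention], list[RelationAnnotation]]:
    """Generate a corpus; deterministic given ``cfg.seed``.

    The emitted collections pass :func:`drugprotkit.corpus_io.validate_corpus`
    and round-trip through the writers unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    chem_probs = _zipf_probs(cfg.chem_vocab, cfg.zipf_exponent)
    gene_probs = _zipf_probs(cfg.gene_vocab, cfg.zipf_exponent)

    docs: list[Document] = []
    entities: list[EntityMention] = []
    relations: list[RelationAnnotation] = []
    type_names = list(RELATION_TYPES)
    type_probs = np.array([cfg.rel_type_weights.get(t, 0.0) for t in type_names])
    type_probs = type_probs / type_probs.sum()

    for i in range(cfg.n_docs):
        pmid = str(10_000_000 + i)
        title = f"Chemical regulation profile {pmid}."
        # each sentence: (text, [(role, local_start, local_end, surface)])
        sentences: list[tuple[str, list]] = []
        # pending relations as (rel_type, mention slot refs)
        doc_mentions: list[dict] = []  # etype, surface, sentence idx, local offsets
        doc_relations: list[tuple[str, int, int]] = []  # type, chem idx, gene idx

        def sample_chem() -> str:
            return f"CHEM-{int(rng.choice(cfg.chem_vocab, p=chem_probs)):05d}"

        def sample_gene() -> str:
            return f"GENE-{int(rng.choice(cfg.gene_vocab, p=gene_probs)):05d}"

        def add_sentence(template: str, slots: dict[str, str]) -> dict[str, int]:
            text, placed = _fill(template, slots)
            idx = len(sentences)
            refs: dict[str, int] = {}
            placements = []
            for role, s, e in placed:
                surface = slots[role]
                etype = (
                    CHEMICAL
                    if role == "chem"
                    else (GENE_Y if rng.random() < cfg.gene_y_fraction else GENE_N)
                )
                refs[role] = len(doc_mentions)
                doc_mentions.append(
                    {"etype": etype, "surface": surface, "sent": idx, "lo": s, "hi": e}
                )
                placements.append(refs[role])
            sentences.append((text, placements))
            return refs

        n_rel = int(rng.poisson(cfg.relations_per_doc))
        for _ in range(n_rel):
            rel_type = type_names[int(rng.choice(len(type_names), p=type_probs))]
            chem, gene = sample_chem(), sample_gene()
            if rng.random() < cfg.cross_sentence_fraction:
                refs1 = add_sentence(_CROSS_FIRST, {"chem": chem})
                refs2 = add_sentence(_CROSS_SECOND, {"gene": gene})
                doc_relations.append((rel_type, refs1["chem"], refs2["gene"]))
            else:
                refs = add_sentence(_TEMPLATES[rel_type], {"chem": chem, "gene": gene})
                doc_relations.append((rel_type, refs["chem"], refs["gene"]))
        for _ in range(int(rng.poisson(cfg.distractors_per_doc))):
            add_sentence(_DISTRACTOR, {"chem": sample_chem(), "gene": sample_gene()})
        if not sentences:
            add_sentence("No interaction data were recorded.", {})

        abstract_parts: list[str] = []
        offset = 0
        sentence_starts: list[int] = []
        for text, _ in sentences:
            sentence_starts.append(offset)
            abstract_parts.append(text)
            offset += len(text) + 1  # single-space joiner
        abstract = " ".join(abstract_parts)
        doc = Document(pmid=pmid, title=title, abstract=abstract)
        docs.append(doc)

        base = len(title) + len(TITLE_ABSTRACT_JOINER)
        # assign term ids in offset order
        for m in doc_mentions:
            m["start"] = base + sentence_starts[m["sent"]] + m["lo"]
            m["end"] = base + sentence_starts[m["sent"]] + m["hi"]
        order = sorted(range(len(doc_mentions)), key=lambda j: doc_mentions[j]["start"])
        term_ids = {j: f"T{rank + 1}" for rank, j in enumerate(order)}
        for j in order:
            m = doc_mentions[j]
            entities.append(
                EntityMention(
                    pmid=pmid,
                    term_id=term_ids[j],
                    etype=m["etype"],
                    start=m["start"],
                    end=m["end"],
                    text=m["surface"],
                )
            )
        seen_rel: set[RelationAnnotation] = set()
        for rel_type, cj, gj in doc_relations:
            rel = RelationAnnotation(
                pmid=pmid, rel_type=rel_type, arg1=term_ids[cj], arg2=term_ids[gj]
            )
            if rel not in seen_rel:  # duplicate surface pairs can recur
                seen_rel.add(rel)
                relations.append(rel)
    return docs, entities, relations


def write_corpus(
    out_dir: PathLike,
    docs: Sequence[Document],
    entities: Sequence[EntityMention],
    relations: Sequence[RelationAnnotation],
) -> dict[str, Path]:
    """Write the three corpus TSVs into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abstracts": out / "abstracts.tsv",
        "entities": out / "entities.tsv",
        "relations": out / "relations.tsv",
    }
    write_abstracts(docs, paths["abstracts"])
    write_entities(entities, paths["entities"])
    write_relations(relations, paths["relations"])
    return paths


def candidate_pool(
    docs: Sequence[Document],
    entities: Sequence[EntityMention],
    scope: Union[str, int] = "sentence",
) -> set[RelationKey]:
    """Enumerated candidate pairs x 13 types, as evaluation keys."""
    pool: set[RelationKey] = set()
    for doc in docs:
        for pair in enumerate_pairs(doc, entities, scope=scope):
            for rel_type in RELATION_TYPES:
                pool.add(
                    RelationKey(doc.pmid, rel_type, pair.chem.term_id, pair.gene.term_id)
                )
    return pool


def generate_runs(
    gold_relations: Sequence[RelationAnnotation],
    pool: set[RelationKey],
    specs: Sequence[RunSpec],
) -> tuple[list[PredictionRecord], dict[tuple[str, Union[str, int]], RunOutcome]]:
    """Degrade the gold standard into prediction runs with target P/R.

    Each gold key is kept independently with probability ``target_recall``;
    ``round(kept * (1 - P) / P)`` false keys are then drawn without
    replacement from ``pool`` minus the gold set.  Every record of a run
    carries the run's realized precision as ``p``.
    """
    gold_keys = {key_of(r) for r in gold_relations}
    if not gold_keys <= pool:
        raise ValueError("candidate pool must be a superset of the gold keys")
    negatives = sorted(pool - gold_keys)
    records: list[PredictionRecord] = []
    outcomes: dict[tuple[str, Union[str, int]], RunOutcome] = {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        kept = [k for k in sorted(gold_keys) if rng.random() < spec.target_recall]
        n_fp = round(len(kept) * (1.0 - spec.target_precision) / spec.target_precision)
        if n_fp > len(negatives):
            raise ValueError(
                f"candidate pool too small: need {n_fp} false keys, "
                f"have {len(negatives)}"
            )
        fp_idx = rng.choice(len(negatives), size=n_fp, replace=False) if n_fp else []
        predicted = kept + [negatives[int(j)] for j in fp_idx]
        realized_p = len(kept) / len(predicted) if predicted else 0.0
        realized_r = len(kept) / len(gold_keys) if gold_keys else 0.0
        outcomes[(spec.team, spec.run)] = RunOutcome(
            precision=realized_p, recall=realized_r, n_predictions=len(predicted)
        )
        for k in predicted:
            records.append(
                PredictionRecord(
                    relation=RelationAnnotation(k.pmid, k.rel_type, k.chem_term, k.gene_term),
                    team=spec.team,
                    run=spec.run,
                    precision=realized_p,
                )
            )
    return records, outcomes
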