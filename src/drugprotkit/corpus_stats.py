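"""Descriptive statistics for entity and relation annotations.

Covers the quantities typically reported for a relation-extraction corpus:
surface-form frequency spectra (rank/frequency "Zipf" points and the fraction
of rare forms), mention length statistics, the overlap between chemical and
gene vocabularies, per-type relation counts by corpus split, multi-label
CEM-GPRO pairs and the frequency spectrum of related surface-form pairs.

Surface-form identity is case-sensitive exact string match throughout; an
optional case-folding switch is provided for the overlap computation only,
since published overlap counts may or may not have folded case.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .corpus_io import (
    EntityMention,
    RELATION_TYPES,
    RelationAnnotation,
    entity_index,
)

#: Role selectors for entity-level statistics.
CEM = "CEM"
GPRO = "GPRO"


@dataclass
class FrequencySpectrum:
    """Occurrence counts of surface forms with rank/frequency points.

    ``fraction_le2`` is the fraction of *distinct* forms occurring at most
    twice — the standard rarity summary for corpus vocabularies.  It is None
    for an empty spectrum.
    """

    counts: dict[str, int]
    fraction_le2: Optional[float]
    zipf_points: list[tuple[int, int]]

    @property
    def n_mentions(self) -> int:
        return sum(self.counts.values())

    @property
    def n_forms(self) -> int:
        return len(self.counts)


@dataclass
class LengthStats:
    """Maximum and median mention length in Unicode code points."""

    max_len: int
    median_len: int


def _role_filter(entities: Iterable[EntityMention], role: str) -> list[EntityMention]:
    if role == CEM:
        return [e for e in entities if e.is_chemical]
    if role == GPRO:
        return [e for e in entities if e.is_gene]
    raise ValueError(f"role must be {CEM!r} or {GPRO!r}, got {role!r}")


def _spectrum_from_counts(counts: Counter) -> FrequencySpectrum:
    if not counts:
        return FrequencySpectrum(counts={}, fraction_le2=None, zipf_points=[])
    # descending frequency; ties broken lexically for determinism
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    zipf_points = [(rank, freq) for rank, (_, freq) in enumerate(ordered, start=1)]
    rare = sum(1 for _, c in counts.items() if c <= 2)
    return FrequencySpectrum(
        counts=dict(ordered),
        fraction_le2=rare / len(counts),
        zipf_points=zipf_points,
    )


def frequency_spectrum(
    entities: Iterable[EntityMention], role: str
) -> FrequencySpectrum:
    """Surface-form frequency spectrum of mentions in the given role."""
    return _spectrum_from_counts(
        Counter(e.text for e in _role_filter(entities, role))
    )


def length_stats(entities: Iterable[EntityMention], role: str) -> LengthStats:
    """Maximum and (lower) median mention length for the given role."""
    lengths = sorted(len(e.text) for e in _role_filter(entities, role))
    if not lengths:
        raise ValueError("length_stats requires at least one entity in the role")
    # lower median: deterministic and integer-valued for even n
    return LengthStats(max_len=lengths[-1], median_len=lengths[(len(lengths) - 1) // 2])


def overlap_mentions(
    cem_entities: Iterable[EntityMention],
    gpro_entities: Iterable[EntityMention],
    casefold: bool = False,
) -> set[str]:
    """Surface forms annotated both as a chemical and as a gene/protein.

    The two arguments may be the same collection; role filtering is applied
    internally.  With ``casefold=True`` forms are compared case-insensitively
    and the lowercase form is returned.
    """
    norm = (lambda s: s.casefold()) if casefold else (lambda s: s)
    cem = {norm(e.text) for e in cem_entities if e.is_chemical}
    gpro = {norm(e.text) for e in gpro_entities if e.is_gene}
    return cem & gpro


def relation_type_counts(
    relations: Sequence[RelationAnnotation],
    split_labels: Mapping[str, str] | Sequence[str],
) -> pd.DataFrame:
    """Per-type relation counts by corpus split, with Total row and column.

    ``split_labels`` maps each PMID to a split name, or is a sequence of
    split labels aligned with ``relations``.  Rows are the 13 relation types
    plus ``Total``; columns are the splits (sorted) plus ``Total``.
    """
    if isinstance(split_labels, Mapping):
        labels = [split_labels[r.pmid] for r in relations]
    else:
        labels = list(split_labels)
        if len(labels) != len(relations):
            raise ValueError("split_labels sequence must align with relations")
    splits = sorted(set(labels))
    table = pd.DataFrame(0, index=list(RELATION_TYPES), columns=splits, dtype=int)
    for rel, label in zip(relations, labels):
        table.loc[rel.rel_type, label] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def multi_label_pairs(
    relations: Iterable[RelationAnnotation],
) -> tuple[list[tuple[tuple[str, str, str], frozenset[str]]], pd.DataFrame]:
    """CEM-GPRO pairs carrying two or more relation types.

    Returns the multi-label pairs — each ``((pmid, arg1, arg2), types)``
    appearing once regardless of arity — and a symmetric type co-occurrence
    count matrix over the 13 relation types (a pair with k >= 2 types
    increments every unordered type pair among its labels).
    """
    types_by_pair: dict[tuple[str, str, str], set[str]] = {}
    for r in relations:
        types_by_pair.setdefault((r.pmid, r.arg1, r.arg2), set()).add(r.rel_type)
    multi = [
        (pair, frozenset(types))
        for pair, types in sorted(types_by_pair.items())
        if len(types) >= 2
    ]
    co = pd.DataFrame(
        0, index=list(RELATION_TYPES), columns=list(RELATION_TYPES), dtype=int
    )
    for _, types in multi:
        ordered = sorted(types)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                co.loc[a, b] += 1
                co.loc[b, a] += 1
    return multi, co


def pair_frequency_spectrum(
    relations: Iterable[RelationAnnotation],
    entities: Iterable[EntityMention],
) -> FrequencySpectrum:
    """Frequency spectrum over (chemical surface, gene surface) related pairs.

    Each relation annotation contributes one occurrence of its surface-form
    pair.  Raises if a relation argument does not resolve to an entity.
    """
    index = entity_index(entities)
    counts: Counter = Counter()
    for r in relations:
        try:
            chem = index[(r.pmid, r.arg1)]
            gene = index[(r.pmid, r.arg2)]
        except KeyError as exc:
            raise ValueError(
                f"relation argument does not resolve to an entity: {exc}"
            ) from exc
        counts[f"{chem.text}\t{gene.text}"] += 1
    return _spectrum_from_counts(counts)
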