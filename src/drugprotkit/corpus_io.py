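"""Readers, writers and validators for the DrugProt standoff dialect.

The corpus is exchanged as three tab-separated files plus one JSON format:

* abstracts TSV — ``PMID \\t title \\t abstract``, one document per line;
* entities TSV — ``PMID \\t T<n> \\t etype \\t start \\t end \\t text``;
* relations TSV — ``PMID \\t rel_type \\t Arg1:T<n> \\t Arg2:T<n>``;
* predictions JSON — an object whose keys are relation TSV rows and whose
  values are arrays of ``{"team": ..., "run": ..., "p": ...}`` records, one
  per system run that predicted the relation (``p`` is that run's
  micro-averaged precision on the gold test set).

Entity offsets are 0-based, half-open character (Unicode code point) indices
into the document's ``full_text``, which is the title and abstract joined by
a single tab character (:data:`TITLE_ABSTRACT_JOINER`).  Files are UTF-8,
newline-terminated, with ``\\n`` line endings; fields are never quoted and
embedded tabs inside a field are illegal.

All readers accept ``strict=False`` to downgrade enum violations and
duplicates to logged warnings, which is the pragmatic mode for large-scale
silver-standard data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

logger = logging.getLogger(__name__)

#: The 13 relation types of the corpus, CEM -> GPRO directed.
RELATION_TYPES: tuple[str, ...] = (
    "ANTAGONIST",
    "AGONIST",
    "AGONIST-ACTIVATOR",
    "AGONIST-INHIBITOR",
    "DIRECT-REGULATOR",
    "ACTIVATOR",
    "INHIBITOR",
    "INDIRECT-DOWNREGULATOR",
    "INDIRECT-UPREGULATOR",
    "PART-OF",
    "PRODUCT-OF",
    "SUBSTRATE",
    "SUBSTRATE_PRODUCT-OF",
)

CHEMICAL = "CHEMICAL"
GENE_Y = "GENE-Y"
GENE_N = "GENE-N"
GENE = "GENE"

#: Valid entity mention types.  GENE is the collapsed large-scale variant.
ENTITY_TYPES: frozenset[str] = frozenset({CHEMICAL, GENE_Y, GENE_N, GENE})
#: Entity types that may fill the gene argument of a relation.
GENE_TYPES: frozenset[str] = frozenset({GENE_Y, GENE_N, GENE})

#: Joiner between title and abstract when deriving ``full_text``.
TITLE_ABSTRACT_JOINER = "\t"

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """Raised on malformed corpus files or constraint violations."""


@dataclass(frozen=True)
class Document:
    """One PubMed record: identifier, title and abstract body."""

    pmid: str
    title: str
    abstract: str

    @property
    def full_text(self) -> str:
        """Title and abstract joined by a tab; the offset reference string."""
        return self.title + TITLE_ABSTRACT_JOINER + self.abstract


@dataclass(frozen=True)
class EntityMention:
    """A typed, offset-anchored chemical (CEM) or gene/protein (GPRO) span.

    ``start``/``end`` index into ``Document.full_text`` (0-based, half-open,
    Unicode code points).
    """

    pmid: str
    term_id: str
    etype: str
    start: int
    end: int
    text: str

    @property
    def is_chemical(self) -> bool:
        return self.etype == CHEMICAL

    @property
    def is_gene(self) -> bool:
        return self.etype in GENE_TYPES


@dataclass(frozen=True)
class RelationAnnotation:
    """A directed CEM -> GPRO relation, arguments given as term ids."""

    pmid: str
    rel_type: str
    arg1: str  # term id of the CHEMICAL argument
    arg2: str  # term id of the GENE-* argument


@dataclass(frozen=True)
class PredictionRecord:
    """One system run's vote for a relation, with its run-level precision."""

    relation: RelationAnnotation
    team: str
    run: Union[str, int]
    precision: float


@dataclass
class ValidationReport:
    """Findings of :func:`validate_corpus`; ``error`` entries mean invalid."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, severity: str, pmid: str, message: str) -> None:
        self.errors.append((severity, pmid, message))

    @property
    def is_valid(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.errors)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.errors:
            return "valid: no findings"
        lines = [f"{sev}\t{pmid}\t{msg}" for sev, pmid, msg in self.errors]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# TSV helpers


def _read_lines(path: PathLike) -> list[str]:
    raw = Path(path).read_text(encoding="utf-8")
    if not raw:
        return []
    return raw.split("\n")[:-1] if raw.endswith("\n") else raw.split("\n")


def _split(line: str, n_fields: int, path: PathLike, lineno: int) -> list[str]:
    fields = line.split("\t")
    if len(fields) != n_fields:
        raise CorpusFormatError(
            f"{path}:{lineno}: expected {n_fields} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def read_abstracts(path: PathLike, strict: bool = True) -> list[Document]:
    """Read an abstracts TSV into :class:`Document` objects, order preserved.

    In strict mode a duplicate PMID raises; lenient mode keeps the first
    occurrence and logs a warning.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_read_lines(path), start=1):
        pmid, title, abstract = _split(line, 3, path, lineno)
        if not pmid:
            raise CorpusFormatError(f"{path}:{lineno}: empty PMID")
        if pmid in seen:
            if strict:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate PMID {pmid}")
            logger.warning("%s:%d: duplicate PMID %s skipped", path, lineno, pmid)
            continue
        seen.add(pmid)
        docs.append(Document(pmid=pmid, title=title, abstract=abstract))
    return docs


def write_abstracts(docs: Iterable[Document], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for d in docs:
            _check_no_tab(d.title, "title", d.pmid)
            _check_no_tab(d.abstract, "abstract", d.pmid)
            fh.write(f"{d.pmid}\t{d.title}\t{d.abstract}\n")


def _check_no_tab(text: str, what: str, pmid: str) -> None:
    if "\t" in text:
        raise CorpusFormatError(f"{pmid}: embedded tab in {what} field")


def read_entities(path: PathLike, strict: bool = True) -> list[EntityMention]:
    """Read an entity TSV (six columns) into :class:`EntityMention` objects."""
    entities: list[EntityMention] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        pmid, term_id, etype, start_s, end_s, text = _split(line, 6, path, lineno)
        if etype not in ENTITY_TYPES:
            if strict:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown entity type {etype!r}"
                )
            logger.warning("%s:%d: unknown entity type %r skipped", path, lineno, etype)
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise CorpusFormatError(
                f"{path}:{lineno}: non-integer offsets {start_s!r}/{end_s!r}"
            ) from exc
        entities.append(
            EntityMention(
                pmid=pmid, term_id=term_id, etype=etype, start=start, end=end, text=text
            )
        )
    return entities


def write_entities(entities: Iterable[EntityMention], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for e in entities:
            _check_no_tab(e.text, "entity text", e.pmid)
            fh.write(f"{e.pmid}\t{e.term_id}\t{e.etype}\t{e.start}\t{e.end}\t{e.text}\n")


def _normalize_arg(raw: str, which: str, path: PathLike, lineno: int) -> str:
    """Accept ``Arg1:T3`` / ``Arg2:T3`` or a bare ``T3``; return the term id."""
    if ":" in raw:
        prefix, _, term = raw.partition(":")
        if prefix not in ("Arg1", "Arg2"):
            raise CorpusFormatError(
                f"{path}:{lineno}: bad argument prefix {prefix!r} in {which}"
            )
        return term
    return raw


def read_relations(path: PathLike, strict: bool = True) -> list[RelationAnnotation]:
    """Read a relation TSV (four columns).

    Exact duplicate rows raise in strict mode; lenient mode deduplicates with
    a warning (set semantics).
    """
    relations: list[RelationAnnotation] = []
    seen: set[RelationAnnotation] = set()
    for lineno, line in enumerate(_read_lines(path), start=1):
        pmid, rel_type, raw1, raw2 = _split(line, 4, path, lineno)
        if rel_type not in RELATION_TYPES:
            if strict:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown relation type {rel_type!r}"
                )
            logger.warning(
                "%s:%d: unknown relation type %r skipped", path, lineno, rel_type
            )
            continue
        rel = RelationAnnotation(
            pmid=pmid,
            rel_type=rel_type,
            arg1=_normalize_arg(raw1, "arg1", path, lineno),
            arg2=_normalize_arg(raw2, "arg2", path, lineno),
        )
        if rel in seen:
            if strict:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate relation row")
            logger.warning("%s:%d: duplicate relation row deduplicated", path, lineno)
            continue
        seen.add(rel)
        relations.append(rel)
    return relations


def write_relations(relations: Iterable[RelationAnnotation], path: PathLike) -> None:
    """Write relations with the canonical ``Arg1:``/``Arg2:`` prefixes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for r in relations:
            fh.write(f"{r.pmid}\t{r.rel_type}\tArg1:{r.arg1}\tArg2:{r.arg2}\n")


# ---------------------------------------------------------------------------
# Prediction JSON


def relation_to_key_string(rel: RelationAnnotation) -> str:
    return f"{rel.pmid}\t{rel.rel_type}\tArg1:{rel.arg1}\tArg2:{rel.arg2}"


def _relation_from_key_string(key: str) -> RelationAnnotation:
    fields = key.split("\t")
    if len(fields) != 4:
        raise CorpusFormatError(f"malformed prediction key {key!r}")
    pmid, rel_type, raw1, raw2 = fields
    if rel_type not in RELATION_TYPES:
        raise CorpusFormatError(f"unknown relation type in prediction key {key!r}")
    return RelationAnnotation(
        pmid=pmid,
        rel_type=rel_type,
        arg1=_normalize_arg(raw1, "arg1", "<json>", 0),
        arg2=_normalize_arg(raw2, "arg2", "<json>", 0),
    )


def read_predictions_json(path: PathLike) -> list[PredictionRecord]:
    """Read a prediction JSON file into :class:`PredictionRecord` objects.

    Keys are relation TSV rows; values are arrays of
    ``{"team", "run", "p"}`` objects.  Run identifiers may be strings or
    integers.  An empty array yields no records and a warning.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict):
        raise CorpusFormatError(f"{path}: top-level JSON value must be an object")
    records: list[PredictionRecord] = []
    for key, votes in payload.items():
        rel = _relation_from_key_string(key)
        if not votes:
            logger.warning("%s: empty prediction array for key %r", path, key)
            continue
        for vote in votes:
            try:
                team, run, p = vote["team"], vote["run"], float(vote["p"])
            except (KeyError, TypeError) as exc:
                raise CorpusFormatError(
                    f"{path}: malformed prediction entry under key {key!r}"
                ) from exc
            if not 0.0 <= p <= 1.0:
                raise CorpusFormatError(
                    f"{path}: precision {p} outside [0, 1] under key {key!r}"
                )
            records.append(PredictionRecord(relation=rel, team=team, run=run, precision=p))
    return records


def write_predictions_json(records: Iterable[PredictionRecord], path: PathLike) -> None:
    """Inverse of :func:`read_predictions_json` (insertion order preserved)."""
    payload: dict[str, list[dict]] = {}
    for rec in records:
        if not 0.0 <= rec.precision <= 1.0:
            raise CorpusFormatError(f"precision {rec.precision} outside [0, 1]")
        key = relation_to_key_string(rec.relation)
        payload.setdefault(key, []).append(
            {"team": rec.team, "run": rec.run, "p": rec.precision}
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Validation and normalisation


def validate_corpus(
    docs: Sequence[Document],
    entities: Sequence[EntityMention],
    relations: Sequence[RelationAnnotation] = (),
) -> ValidationReport:
    """Cross-check documents, entity offsets and relation arguments.

    Checks performed:

    * PMID uniqueness among documents; (pmid, term_id) uniqueness among
      entities;
    * offset bounds ``0 <= start < end <= len(full_text)``;
    * ``full_text[start:end] == text`` for every entity;
    * every relation argument resolves to an entity of that document;
    * arg1 is a CHEMICAL and arg2 a GENE-* mention (CEM -> GPRO direction);
    * relation types belong to the 13-type inventory.
    """
    report = ValidationReport()
    doc_by_pmid: dict[str, Document] = {}
    for d in docs:
        if d.pmid in doc_by_pmid:
            report.add("error", d.pmid, "duplicate PMID among documents")
        doc_by_pmid[d.pmid] = d

    ent_index: dict[tuple[str, str], EntityMention] = {}
    for e in entities:
        key = (e.pmid, e.term_id)
        if key in ent_index:
            report.add("error", e.pmid, f"duplicate term id {e.term_id}")
            continue
        ent_index[key] = e
        doc = doc_by_pmid.get(e.pmid)
        if doc is None:
            report.add("error", e.pmid, f"entity {e.term_id} references unknown PMID")
            continue
        text = doc.full_text
        if not (0 <= e.start < e.end <= len(text)):
            report.add(
                "error",
                e.pmid,
                f"entity {e.term_id} offsets [{e.start}, {e.end}) out of bounds "
                f"for text of length {len(text)}",
            )
            continue
        if text[e.start : e.end] != e.text:
            report.add(
                "error",
                e.pmid,
                f"entity {e.term_id} span mismatch: text field {e.text!r} vs "
                f"document slice {text[e.start:e.end]!r}",
            )

    for r in relations:
        if r.rel_type not in RELATION_TYPES:
            report.add("error", r.pmid, f"unknown relation type {r.rel_type!r}")
        chem = ent_index.get((r.pmid, r.arg1))
        gene = ent_index.get((r.pmid, r.arg2))
        if chem is None:
            report.add("error", r.pmid, f"arg1 {r.arg1} does not resolve to an entity")
        elif not chem.is_chemical:
            report.add(
                "error", r.pmid, f"arg1 {r.arg1} has type {chem.etype}, not CHEMICAL"
            )
        if gene is None:
            report.add("error", r.pmid, f"arg2 {r.arg2} does not resolve to an entity")
        elif not gene.is_gene:
            report.add(
                "error", r.pmid, f"arg2 {r.arg2} has type {gene.etype}, not GENE-*"
            )
    return report


def collapse_gene_types(entities: Iterable[EntityMention]) -> list[EntityMention]:
    """Map GENE-Y/GENE-N to plain GENE; CHEMICAL untouched.  Idempotent."""
    out = []
    for e in entities:
        if e.etype in (GENE_Y, GENE_N):
            out.append(
                EntityMention(
                    pmid=e.pmid,
                    term_id=e.term_id,
                    etype=GENE,
                    start=e.start,
                    end=e.end,
                    text=e.text,
                )
            )
        else:
            out.append(e)
    return out


def entity_index(
    entities: Iterable[EntityMention],
) -> dict[tuple[str, str], EntityMention]:
    """Index entities by (pmid, term_id) for argument resolution."""
    return {(e.pmid, e.term_id): e for e in entities}
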