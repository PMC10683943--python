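"""Sentence splitting, pair enumeration, baselines and example generation."""

import pytest

from drugprotkit.candidates import (
    CHEM_CLOSE,
    CHEM_MASK,
    CHEM_OPEN,
    GENE_MASK,
    MARKER_TOKENS,
    ReferenceRelationClassifier,
    RegexTokenizer,
    classify_examples,
    enumerate_pairs,
    generate_examples,
    max_recall_baseline,
    split_sentences,
    strip_markers,
)
from drugprotkit.corpus_io import (
    Document,
    EntityMention,
    RELATION_TYPES,
    RelationAnnotation,
)
from drugprotkit.evaluation import evaluate, normalize_predictions
from drugprotkit.synth import SynthConfig, generate_corpus


def doc_with(abstract, title="T"):
    return Document("1", title, abstract)


def ent(term, etype, start, end, text, pmid="1"):
    return EntityMention(pmid, term, etype, start, end, text)


def locate(doc, term, etype, text, pmid="1"):
    """Entity anchored at the first occurrence of ``text`` in full_text."""
    start = doc.full_text.index(text)
    return EntityMention(pmid, term, etype, start, start + len(text), text)


class TestSplitSentences:
    def test_two_simple_sentences(self):
        doc = doc_with("A fact. Another fact.")
        spans = split_sentences(doc)
        # title span plus two abstract sentences
        texts = [doc.full_text[s:e] for s, e in spans]
        assert texts == ["T", "A fact.", "Another fact."]

    def test_no_terminal_punctuation_is_one_span(self):
        doc = Document("1", "", "no punctuation at all")
        spans = split_sentences(doc)
        assert len(spans) == 1
        s, e = spans[0]
        assert doc.full_text[s:e] == "no punctuation at all"

    def test_boundary_inside_entity_is_repaired(self):
        # dot inside the dosage entity, followed by an uppercase token
        doc = Document("1", "", "Aspirin (1 mg. Kg-1) works. Next sentence.")
        entity = locate(doc, "T1", "CHEMICAL", "1 mg. Kg-1")
        assert doc.full_text[entity.start : entity.end] == "1 mg. Kg-1"
        without_repair = split_sentences(doc)
        with_repair = split_sentences(doc, [entity])
        assert len(without_repair) == 3
        assert len(with_repair) == 2

    def test_abbreviation_does_not_split(self):
        doc = Document("1", "", "Results from e.g. Smith were used. Final point.")
        assert len(split_sentences(doc)) == 2

    def test_spans_are_disjoint_ordered_and_cover_entities(self, small_corpus):
        docs, entities, _ = small_corpus
        for doc in docs:
            doc_ents = [e for e in entities if e.pmid == doc.pmid]
            spans = split_sentences(doc, doc_ents)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            for e in doc_ents:
                assert any(s <= e.start and e.end <= t for s, t in spans)


class TestEnumeratePairs:
    def test_single_co_mention_yields_one_pair(self):
        doc = Document("1", "", "Aspirin inhibits COX-1.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aspirin"),
            locate(doc, "T2", "GENE-Y", "COX-1"),
        ]
        pairs = enumerate_pairs(doc, entities)
        assert len(pairs) == 1
        assert pairs[0].same_sentence
        assert pairs[0].chem.term_id == "T1" and pairs[0].gene.term_id == "T2"

    def test_cartesian_count_in_one_sentence(self):
        doc = Document("1", "", "Aa and Bb bind Xx and Yy strongly.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aa"),
            locate(doc, "T2", "CHEMICAL", "Bb"),
            locate(doc, "T3", "GENE-N", "Xx"),
            locate(doc, "T4", "GENE-Y", "Yy"),
        ]
        assert len(enumerate_pairs(doc, entities)) == 4

    def test_cross_sentence_pair_excluded_by_sentence_scope(self):
        doc = Document("1", "", "Aspirin was given. COX-1 fell.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aspirin"),
            locate(doc, "T2", "GENE-Y", "COX-1"),
        ]
        assert enumerate_pairs(doc, entities, scope="sentence") == []
        window_pairs = enumerate_pairs(doc, entities, scope=128)
        assert len(window_pairs) == 1 and not window_pairs[0].same_sentence

    def test_window_scope_excludes_wide_pairs(self):
        filler = " ".join(["word"] * 200)
        doc = Document("1", "", f"Aspirin {filler} binds COX-1.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aspirin"),
            locate(doc, "T2", "GENE-Y", "COX-1"),
        ]
        assert enumerate_pairs(doc, entities, scope=64) == []
        assert len(enumerate_pairs(doc, entities, scope=512)) == 1


class TestMaxRecallBaseline:
    def test_one_pair_yields_all_13_types(self):
        doc = Document("1", "", "Aspirin inhibits COX-1.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aspirin"),
            locate(doc, "T2", "GENE-Y", "COX-1"),
        ]
        preds = max_recall_baseline([doc], entities)
        assert len(preds) == 13
        assert {p.rel_type for p in preds} == set(RELATION_TYPES)

    def test_four_pairs_yield_52_predictions(self):
        doc = Document("1", "", "Aa and Bb bind Xx and Yy strongly.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aa"),
            locate(doc, "T2", "CHEMICAL", "Bb"),
            locate(doc, "T3", "GENE-N", "Xx"),
            locate(doc, "T4", "GENE-Y", "Yy"),
        ]
        assert len(max_recall_baseline([doc], entities)) == 52

    def test_perfect_recall_and_closed_form_precision(self, intra_corpus):
        docs, entities, relations = intra_corpus
        preds = max_recall_baseline(docs, entities)
        result = evaluate(
            normalize_predictions(relations), normalize_predictions(preds)
        )
        assert result.recall == 1.0
        n_pairs = sum(len(enumerate_pairs(d, entities)) for d in docs)
        multi_typed = len(relations) - len(
            {(r.pmid, r.arg1, r.arg2) for r in relations}
        )
        if multi_typed == 0:  # closed form holds when pairs carry <= 1 type
            assert result.precision == pytest.approx(len(relations) / (13 * n_pairs))


class TestGenerateExamples:
    def _fixture(self):
        doc = Document("1", "", "Aspirin inhibits COX-1 in cells.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aspirin"),
            locate(doc, "T2", "GENE-Y", "COX-1"),
        ]
        relations = [RelationAnnotation("1", "INHIBITOR", "T1", "T2")]
        return [doc], entities, relations

    def test_marking_adds_exactly_four_tokens(self):
        docs, entities, relations = self._fixture()
        (example,) = generate_examples(docs, entities, relations, window=32)
        stripped = strip_markers(example.tokens)
        assert len(example.tokens) == len(stripped) + 4
        assert not MARKER_TOKENS & set(stripped)

    def test_marked_entity_is_contiguous(self):
        doc = Document("1", "", "insulin activates IR signaling.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "insulin"),
            locate(doc, "T2", "GENE-Y", "IR"),
        ]
        (example,) = generate_examples([doc], entities, window=32)
        tokens = list(example.tokens)
        i = tokens.index(CHEM_OPEN)
        assert tokens[i : i + 3] == [CHEM_OPEN, "insulin", CHEM_CLOSE]

    def test_mask_style_replaces_focus_mentions(self):
        docs, entities, relations = self._fixture()
        (example,) = generate_examples(docs, entities, relations, window=32, style="mask")
        assert CHEM_MASK in example.tokens and GENE_MASK in example.tokens
        assert "Aspirin" not in example.tokens and "COX" not in example.tokens

    def test_window_budget_is_respected(self, small_corpus):
        docs, entities, relations = small_corpus
        examples = generate_examples(docs, entities, relations, window=24)
        assert examples
        assert all(len(e.tokens) <= 24 for e in examples)
        for e in examples:
            assert len(strip_markers(e.tokens)) == len(e.tokens) - 4

    def test_pair_exceeding_window_produces_nothing(self):
        filler = " ".join(["word"] * 100)
        doc = Document("1", "", f"Aspirin {filler} binds COX-1.")
        entities = [
            locate(doc, "T1", "CHEMICAL", "Aspirin"),
            locate(doc, "T2", "GENE-Y", "COX-1"),
        ]
        assert generate_examples([doc], entities, window=32) == []

    def test_window_below_minimum_is_a_config_error(self):
        docs, entities, relations = self._fixture()
        with pytest.raises(ValueError, match="window"):
            generate_examples(docs, entities, relations, window=4)

    def test_labels_multi_vs_single(self):
        docs, entities, _ = self._fixture()
        relations = [
            RelationAnnotation("1", "INHIBITOR", "T1", "T2"),
            RelationAnnotation("1", "DIRECT-REGULATOR", "T1", "T2"),
        ]
        (multi,) = generate_examples(docs, entities, relations, window=32)
        assert multi.label == frozenset({"INHIBITOR", "DIRECT-REGULATOR"})
        (single,) = generate_examples(
            docs, entities, relations, window=32, label_mode="single"
        )
        assert single.label == frozenset({"DIRECT-REGULATOR"})


class TestReferenceClassifier:
    def test_separable_training_set_reaches_perfect_f1(self):
        # one relation per document with a type-specific cue word: the bag of
        # tokens determines the label, so the training set is separable
        cues = {
            "INHIBITOR": "inhibited",
            "ACTIVATOR": "activated",
            "SUBSTRATE": "metabolized",
        }
        docs, entities, relations = [], [], []
        for i, rel_type in enumerate([t for t in cues for _ in range(8)]):
            pmid = str(i)
            doc = Document(pmid, "Study", f"CHEM-{i:03d} {cues[rel_type]} GENE-{i:03d}.")
            docs.append(doc)
            entities.append(locate(doc, "T1", "CHEMICAL", f"CHEM-{i:03d}", pmid=pmid))
            entities.append(locate(doc, "T2", "GENE-Y", f"GENE-{i:03d}", pmid=pmid))
            relations.append(RelationAnnotation(pmid, rel_type, "T1", "T2"))
        examples = generate_examples(docs, entities, relations, window=32)
        assert len(examples) == len(docs)
        clf = ReferenceRelationClassifier().fit(examples)
        preds = classify_examples(examples, clf)
        result = evaluate(normalize_predictions(relations), normalize_predictions(preds))
        assert result.f1 == 1.0

    def test_predictions_are_subset_of_candidates_x_types(self, small_corpus):
        docs, entities, relations = small_corpus
        examples = generate_examples(docs, entities, relations, window=64)
        clf = ReferenceRelationClassifier().fit(examples)
        preds = classify_examples(examples, clf)
        allowed = {
            (e.pair.pmid, t, e.pair.chem.term_id, e.pair.gene.term_id)
            for e in examples
            for t in RELATION_TYPES
        }
        assert all((p.pmid, p.rel_type, p.arg1, p.arg2) in allowed for p in preds)

    def test_unfitted_classifier_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            ReferenceRelationClassifier().predict([])


def test_tokenizer_offsets_reconstruct_input():
    text = "Aspirin (1 mg) inhibits\tCOX-1."
    tokens = RegexTokenizer().tokenize(text)
    rebuilt = []
    pos = 0
    for t in tokens:
        rebuilt.append(text[pos : t.start])
        rebuilt.append(t.text)
        assert text[t.start : t.end] == t.text
        pos = t.end
    rebuilt.append(text[pos:])
    assert "".join(rebuilt) == text
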