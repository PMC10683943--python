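# Methods

This note documents the models, conventions and design choices behind
drugprotkit, in the order the data flows through the package.

## Corpus model and offset conventions

A document is a PubMed record (PMID, title, abstract). All standoff offsets
index into `full_text = title + "\t" + abstract`. The tab joiner is a
package constant (`corpus_io.TITLE_ABSTRACT_JOINER`): entity files index
into a single per-document string, and a tab is the one character guaranteed
not to occur inside either field (embedded tabs are illegal in all TSV
fields). Offsets are 0-based, half-open and counted in Unicode code points,
not bytes — "index of the first character" and "first character after the
span" are only deterministic under a code-point interpretation. This is a
convention: corpora produced by byte-offset tools must be re-indexed before
validation.

TSV files are UTF-8, `\n`-terminated, never quoted. Readers are strict by
default; a global lenient mode downgrades enum violations and duplicates to
logged warnings and is intended for large-scale silver-standard data, which
is typically dirty. Writers always emit the canonical `Arg1:T<n>`/`Arg2:T<n>`
argument dialect; readers also accept bare term ids.

The prediction JSON format groups run-level votes under relation-row keys.
A consequence is that `read(write(records))` preserves the record multiset
but not an interleaved input order; round-trip guarantees are stated at set
level.

## Evaluation

The scoring follows standard shared-task practice: a relation instance is
the tuple (PMID, type, chemical term id, gene term id); TP/FP/FN are pooled
over all documents and types (micro-averaging) and the same computation
restricted to each type gives the granular view. Term ids, not surface
strings, carry identity — predictors receive the gold entity annotations in
this task, so argument identity is unambiguous. Zero-denominator cases use
the common evaluator conventions (P=0 with no predictions, R=0 with no gold,
F1=0 when P+R=0). The GENE-Y/GENE-N distinction never enters scoring; the
large-scale silver corpus collapses both to GENE, and `collapse_gene_types`
applies the same normalization to gold data.

The error profile counts FN/FP by relation type and by participating surface
form, and histograms FN by the character distance between the nearer edges
of the two mention spans (bin width 50 characters by default, configurable).
Nearer-edge distance is used because it is the quantity that determines
whether a pair fits a context window.

## Candidate generation and examples

The sentence splitter is deliberately rule-based and deterministic:
boundaries after `[.!?]` followed by whitespace and an uppercase
letter/digit/bracket, a fixed dotted-abbreviation list, and a hard boundary
at the title/abstract tab. Any boundary falling inside an entity span is
suppressed, so no mention ever straddles a sentence (dotted units inside
chemical names are the common case). Determinism was chosen over linguistic
accuracy: identical inputs must yield identical candidates everywhere.

The default tokenizer is a regex word/punctuation tokenizer with character
offsets; token windows are counted in its tokens. Subword tokenizers of
specific vocabularies count differently, which is why the tokenizer is a
behavioral contract (`tokenize(text) -> tokens with offsets`) rather than a
fixed implementation — swapping one in changes window contents but no
semantics. A pair produces an example when its minimal token span plus the
four marker tokens fits the window (default 128). The remaining budget is
split evenly before/after the span, left-biased on odd remainders, with
unused budget at a text edge flowing to the other side. Marking inserts
`[unused1]…[unused2]` around the chemical and `[unused3]…[unused4]` around
the gene; removing the markers restores the original token sequence exactly.
Masking replaces each focus mention with a single role placeholder. Labels
are multi-label by default (a pair may carry several gold types); a
single-label mode is provided for classifiers that require it. Negative
pairs are all kept by default; subsampling is a knob, not a default, since
no prescribed ratio exists.

The bundled `ReferenceRelationClassifier` is a sparse bag-of-tokens model
with one logistic-regression head per relation type. It exists to make the
candidate → example → classify → evaluate pipeline runnable end to end at
desk scale and to pin down the classifier contract; it is not a competitive
extraction model, and transformer fine-tuning is explicitly out of scope.

## Ensembling

Majority voting operates per relation key, so multi-type pairs are voted
independently — consistent with the evaluation's independence rule. The
default threshold is strict majority (> n/2); ties under even run counts are
dropped, a conservative choice. `threshold=1.0` means unanimity
(intersection); thresholds approaching 0 approach the union.

## Knowledge graph

Edges are unique (chemical node, gene node, type) identities; the support of
an edge is every (team, run, precision) record that predicted it, after
dropping exact duplicates within a run. Weights attach to edges (the
combination is defined over the runs that predicted *the edge*), with
noisy-OR as the default combiner — run precisions are treated as independent
correctness probabilities, so w = 1 − ∏(1 − pᵢ) ∈ [max pᵢ, 1]. `max` and
`mean` combiners are provided for users who prefer a non-accumulating
semantics.

Node identity has two modes. `mention` (PMID + term id) counts mention
instances and is the mode whose node totals match per-mention corpus
statistics. `surface` (role-qualified surface string) merges mentions across
documents, producing the cross-document connectivity that component and
diameter analyses need. Role qualification keeps the surface graph strictly
bipartite, which forces clustering and transitivity to exactly 0; a nonzero
clustering on such a graph therefore implies some node-identity merge across
the two roles (e.g. unifying surface forms annotated under both), and any
reproduction of published nonzero values is best-effort without knowing that
rule. Topology statistics are computed on the undirected simple projection
(parallel typed edges collapsed) because the standard definitions of
clustering, transitivity and assortativity assume simple graphs;
assortativity is reported as undefined when degree variance is zero, and the
diameter is computed on the giant component only.

## Synthetic data

The generator emulates the *structure* that the machinery is sensitive to,
not biomedical language. Defaults and what they mirror:

- `relations_per_doc = 4.9` (Poisson mean): the gold corpus has 24 526
  relations over 5000 abstracts.
- `rel_type_weights`: proportional to the gold per-type totals (bundled
  table), so INHIBITOR dominates and AGONIST-ACTIVATOR is near-absent.
- `zipf_exponent = 1.5`, vocabularies of 400 chemical and 400 gene surface
  forms (`CHEM-00042`-style): reproduces heavy-tailed mention frequencies
  with a substantial rare-form fraction at desk-scale corpus sizes.
- `cross_sentence_fraction = 0.1`: a minority of relations span adjacent
  sentences, enough to exercise the cross-sentence window path; set to 0 for
  corpora where the max-recall baseline must reach recall 1.0.
- `distractors_per_doc = 1.0`: unrelated co-mentions, so candidate pools are
  strict supersets of the gold set.
- `gene_y_fraction = 0.7`: share of GPRO mentions typed GENE-Y vs GENE-N.

Sentences are fixed English skeletons with one type-specific cue verb per
relation type; entity surfaces fill slots, and offsets are derived during
assembly, so emitted corpora always validate. What this does **not**
emulate: real lexical variety, nested/overlapping mentions, CEM/GPRO
vocabulary overlap, annotation noise in offsets, or genuinely ambiguous
context — passing tests on synthetic corpora show the machinery is correct,
not that any classifier generalizes to real text.

Degraded runs keep each gold key with probability `target_recall` and add
`round(kept·(1−P)/P)` false keys from a candidate pool, so realized
precision concentrates on the target as the corpus grows (binomial sampling
error at small n). Records carry the run's realized precision, mirroring how
real silver-standard predictions are tagged with run-level test-set
precision. Every `generate` call uses a single seeded RNG stream; the CLI
makes seeds mandatory.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: corpora of 15–220
documents (up to ~1300 gold relations), five-run ensembles, and graphs of a
few hundred nodes — sizes at which every property being checked is exact or
has known sampling bounds (4σ binomial bounds for realized recall, ±0.05 for
realized precision at ≥1000 gold keys). The lower median is used for
length statistics (integer-valued, deterministic for even n). Surface-form
identity is case-sensitive exact match everywhere; the overlap computation
exposes an optional case-folding switch because published overlap counts do
not state their folding rule.

## Known limitations

- The sentence splitter's abbreviation list is fixed and small; unusual
  dotted tokens outside entity spans can still split sentences wrongly.
- The regex tokenizer's window counts diverge from subword token counts;
  window-boundary decisions near the limit differ from BERT-vocabulary
  pipelines unless a subword tokenizer is plugged in.
- GraphML/TSV edge exports do not serialize per-run provenance; re-imported
  graphs preserve edge identity, weight and support size only.
- The reference classifier is a lexical baseline; its scores on real corpora
  are far below transformer systems by design.
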