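# Methods

## Problem and model

Routine ophthalmology letters describe findings for the anterior and
posterior segments of the eye as free text, often in German, with heavy
local dialect. The package converts each record into a *set* of Human
Phenotype Ontology (HPO) codes by composing four stages — translation,
segmentation, exclusion/negation, retrieval — over a layered synonym
catalog. Two properties drive the design:

* **Grounding.** Retrieval is constrained to a fixed catalog of verified
  codes: the pipeline can mislink a finding, but it cannot invent a code
  that does not exist. Every pathological segment is assigned its single
  nearest catalog entry (K = 1, no abstention threshold); the cosine
  similarity is recorded so a caller *can* post-filter
  (`min_similarity`, default off), but the default reproduces the
  unconditional nearest-neighbour assignment, which means concepts absent
  from the catalog are inevitably mapped to their closest existing
  neighbour. The cure for that failure mode is catalog growth, not a
  threshold.
* **Repairability.** The exact tier sits above the embedding tier so that
  the correction loop has a deterministic guarantee: once a reviewed
  surface form is attached to its code as a local synonym, every later
  occurrence resolves to that code with similarity 1.0, independent of
  the embedding geometry. For identical strings the two tiers agree under
  any reasonable embedder, so the exact tier changes no behaviour except
  making the guarantee checkable.

### Retrieval details

Surface forms are normalized for the exact tier: Unicode NFC, lowercase,
whitespace collapsed, terminal punctuation stripped. Embedding vectors are
L2-normalized at build time, so the dot product is the cosine. Exact cosine
ties are broken in favour of the local layer (the curated site authority),
then the lexicographically smallest code — identical surface text in both
layers therefore resolves to the local code in both tiers. An
ignore-sentinel win (catalog code `0`) produces no annotation; sentinel
codes can never appear in predictions, and the evaluator rejects them as
input.

The default embedding backend is a signed character-trigram hashing
embedder (BLAKE2b bucket hashing, 256 dimensions, fixed seed). It is not a
semantic model: it measures lexical n-gram overlap. It was chosen because
it is deterministic, dependency-free and fast, and because the package's
correctness claims (tiering, tie-breaks, sentinel handling, the repair
loop) are independent of embedding quality. A production deployment swaps
in a multilingual sentence embedder behind the same `EmbeddingBackend`
contract (the interface accepts an instruction prefix for
instruction-tuned models); nothing else changes.

### Stage fallbacks

The generation-backend interface covers LLM-driven translation,
segmentation and classification, with prompt templates shipped as editable
text files (`{input}` placeholder) — prompts are configuration for domain
experts, not code. The deterministic fallbacks are:

* translation: longest-match phrase substitution from a packaged
  German→English ophthalmic lexicon; unknown tokens pass through verbatim;
* segmentation: split on sentence ends, semicolons, line breaks, and
  commas outside parentheses; only delimiters and whitespace are consumed,
  so every alphanumeric character survives in order;
* classification: negation-trigger match anywhere in the segment →
  `negated`; else normal-marker match → `normal`; else `pathological`.
  Negation scope is the whole segment because segments are already atomic
  findings; both trigger lists are packaged, bilingual, and
  user-extensible.

`normal` and `negated` are recorded as distinct statuses but treated
identically downstream (both are excluded before retrieval). Stage
failures skip the affected record, are logged with the record id, and
never abort a corpus.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `HashingNgramEmbedder(dim, ngram, seed)` | 256, 3, 17 | embedding space size, character n-gram order, hash seed; any fixed values give a deterministic space |
| `min_similarity` | off | optional cosine floor for embedding-tier matches |
| `GeneratorConfig.mean_findings` | 2.5 | Poisson mean of pathological findings per synthetic record, matching the ~2.5 terms/record such validation corpora exhibit |
| `GeneratorConfig.p_normal`, `p_negated` | 0.3, 0.2 | per-field probabilities of a normal / negated distractor phrase |
| `GeneratorConfig.p_german_surface` | 0.5 | probability that a planted finding uses its German lexicon variant, when one exists |
| `GeneratorConfig.synonym_miss_rate` | 0.0 | probability that a planted surface is replaced by an out-of-catalog paraphrase (its code stays in the truth set) |

Findings-per-record is modelled as Poisson because only the mean is
constrained; any over-dispersed alternative would need evidence the
desk-scale setting does not provide.

## Synthetic corpus: what it does and does not emulate

The generator emulates the *statistical structure* a validation corpus of
this kind: bilingual surface forms drawn from the catalog, ~2.5 planted
pathological findings per record (sampled without code repetition within a
record, so truth-set size equals the Poisson draw), normal and negated
distractors, anterior/posterior field assignment, and a controlled
synonym-miss channel. It does **not** emulate clinical prose style,
misspellings, abbreviation soup, discontinuous findings, or
inter-annotator disagreement. Consequently, passing end-to-end tests shows
the machinery is sound — stages compose, exclusion is sound, retrieval
tiers and the repair loop behave as specified — not that any particular
accuracy would be reached on real letters; real-world figures require a
manually annotated held-out corpus.

Three planted-surface constraints keep the ground truth exact: sentinel
rows are never planted (they carry no code), surfaces containing
segmentation delimiters (three catalog rows with commas) are excluded from
the planting pool so a planted finding always survives the splitter as one
segment, and paraphrase replacements are generated in English so the
translation stage cannot mask a planted miss. Records are tagged `de`
whenever any German phrase was planted.

Degradation behaves binomially by construction: each planted finding is
independently replaced with probability `synonym_miss_rate`, and under
exact-tier-only matching each miss is exactly one false negative (micro
precision stays 1.0 because abstention cannot hallucinate). Enabling the
embedding tier can only add matches, so it never lowers recall. Logging
every missed surface and applying the corrections restores per-record
F1 = 1.0, which is the repair-loop guarantee stated above.

## Evaluation conventions

Per record: `tp = |P∩T|`, `fp = |P∖T|`, `fn = |T∖P|`; Jaccard, precision,
recall, F1 as usual, with the algebraic identity `J = F1/(2−F1)`.
Degenerate records: both sets empty → all metrics 1.0 (a normal record
correctly predicted as having no pathology should not drag medians down);
exactly one side empty → 0.0. Medians are order-statistic medians (mean of
the middle two for even n). Reports carry *both* medians of per-record
metrics and micro metrics pooled over counts, plus mean and total term
counts for both sides, because the two aggregation conventions answer
different questions and are not interchangeable.

## Numerical and degenerate-input choices

* Codes are stored 7-digit zero-padded; any all-digit input (site catalogs
  print codes unpadded) and `HP:` CURIEs are accepted; the sentinel `0` is
  preserved verbatim. Some site-catalog codes (e.g. seven-digit `6000709`)
  may be local placeholders rather than released ontology ids; they are
  stored after padding with provenance `fixture`.
* Cosine ties are resolved on exact float equality; identical strings give
  identical vectors, which is the only tie class the tie-break must handle
  deterministically.
* An empty or fully non-alphanumeric query embeds to the zero vector; all
  cosines are then 0 and the tie-break picks the first local / smallest
  code — harmless, since classification never forwards empty segments.
* Catalog surface collisions: local beats standard; local-vs-local and
  standard-vs-standard with different codes are load errors (one reviewed
  code per surface).
* Corrections apply all-or-nothing per batch; conflicts (within the batch
  or against an existing local mapping) abort with every conflict listed.
  The CLI refuses correction logs tagged `source_tag: validation` to keep
  training and validation corpora distinct.

## Problem sizes

The shipped test-bench and the acceptance script run at desk scale, chosen
so each property is measured with adequate statistical resolution: the
worked-example lookups run against the 42-surface packaged catalog;
oracle-equivalence checks use a 600-surface random catalog and 120
queries; metric identities use 10,000 random set pairs; end-to-end
soundness uses 200 records; degradation/repair uses 800 records (~2,000
planted findings, giving a ±0.027 99% binomial band around recall 0.7);
generator calibration uses 2,000 records (3 standard errors ≈ 0.106 around
the mean 2.5).

## Known limitations

* The fallback translator is a phrase dictionary: adequate for
  catalog-derived surface forms and negation particles, not for free
  German prose. The fallback stages exist to make the pipeline's logic
  testable and deterministic, and to serve as the degradation floor when
  no language model is configured.
* K = 1 without a threshold means out-of-catalog concepts are always
  mapped somewhere; monitoring the recorded similarity and reviewing
  low-similarity annotations is the intended operating procedure.
* The hashing embedder has no cross-lingual geometry: untranslated German
  reaching the embedding tier will match poorly. Translation runs first
  precisely so retrieval operates on English text.
* Scope (anterior/posterior) is metadata only; retrieval searches the full
  merged catalog rather than restricting candidates by field of origin.
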