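# ocuphen

Local deep-phenotyping of ophthalmology letters: free-text anterior- and
posterior-segment findings go in, Human Phenotype Ontology (HPO) codes come
out. The package is aimed at clinical registries and research groups that
want structured phenotypes from routine physicians' letters without sending
text to external services: every component runs on-site and the default
backends are fully deterministic.

## The pipeline

Each record passes four stages:

1. **Translation** — German notes are rendered into English so that one
   (largely English) synonym catalog serves retrieval. Pluggable
   text-generation backend; the fallback is a phrase-lexicon substitution
   translator (unknown tokens pass through verbatim).
2. **Segmentation** — each text field is cut into discrete findings, one
   candidate phenotype per segment (fallback: sentence/semicolon/newline
   boundaries and commas outside parentheses).
3. **Exclusion & negation** — segments describing normal findings
   ("Cornea clear") or ruled-out pathologies ("no retinal detachment") are
   filtered with trigger lexicons so absent phenotypes are never recorded
   as present.
4. **Retrieval** — every remaining pathological segment is linked to
   exactly one code: an exact tier over normalized surface forms first,
   otherwise the single nearest neighbour (K = 1) by cosine similarity in
   embedding space over the whole catalog. There is no abstention
   threshold by default; the similarity is recorded so callers can
   post-filter (`--min-similarity`).

The catalog is layered: the **standard** layer carries ontology labels and
exact synonyms (loaded from OBO or HPO-dialect JSON); the **local** layer
carries site-curated surface forms per eye segment, including ignore-
sentinel rows (code `0`) whose matches deliberately produce no annotation.
Local entries win surface collisions. When a reviewer finds a misretrieval,
the surface is attached to its correct code as a local synonym
(`add_synonym` / the `augment` command), so the error cannot recur —
an expert-in-the-loop loop that monotonically grows site vocabulary.
Phenotypes missing from the ontology altogether are logged with a proposed
label and exported as a submission-ready TSV.

Record-level predictions are **sets** of codes. Evaluation against manual
ground truth reports, per record, Jaccard `tp/(tp+fp+fn)`, precision,
recall and `F1 = 2tp/(2tp+fp+fn)` (so `J = F1/(2−F1)`), aggregated both as
per-record medians and as micro metrics pooled over counts.

## Worked example

```python
from ocuphen import (ClinicalRecord, HashingNgramEmbedder, annotate_record,
                     build_fixture_catalog, build_index, evaluate_corpus)

catalog = build_fixture_catalog()           # packaged desk-scale catalog
index = build_index(catalog, HashingNgramEmbedder())

letter = ClinicalRecord(
    record_id="example-1",
    anterior_text="Hornhaut klar; Wimpernverlust",
    posterior_text="Amotio retinae. Roth-Fleck; kein Makulaödem; Motility",
    language="de",
)
codes, annotations = annotate_record(letter, catalog, index)
for a in annotations:
    print(f"{a.scope:9s} {a.text!r:24s} -> {a.curie}  tier={a.tier} sim={a.similarity:.2f}")
print("record-level prediction:", sorted(codes))

report = evaluate_corpus({"example-1": codes},
                         {"example-1": {"0000541", "0031805", "0011457"}})
print(f"Jaccard={report.median_jaccard:.2f} precision={report.median_precision:.2f} "
      f"recall={report.median_recall:.2f} F1={report.median_f1:.2f}")
```

prints

```
anterior  'Eyelash loss'           -> HP:0011457  tier=exact sim=1.00
posterior 'retinal detachment'     -> HP:0000541  tier=exact sim=1.00
posterior 'Roth spot'              -> HP:0031805  tier=exact sim=1.00
record-level prediction: ['0000541', '0011457', '0031805']
Jaccard=1.00 precision=1.00 recall=1.00 F1=1.00
```

Reading the output: `Hornhaut klar` was excluded as a normal finding,
`kein Makulaödem` as a negated one, and `Motility` matched an
ignore-sentinel catalog row, so none of the three produced a code. The
three pathological segments resolved on the exact tier (similarity 1.0)
after translation; the record-level set matches the manual annotation, so
all metrics are 1.0.

The same workflow is available from the shell:

```sh
ocuphen simulate --n-records 200 --seed 1 --out corpus/
ocuphen build-index --fixture --out index/
ocuphen annotate --index index/ --records corpus/records.jsonl --out annotated/
ocuphen evaluate --predictions annotated/predictions.jsonl \
                 --truth corpus/truth.jsonl --out report/
```

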