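# medinq — weakly supervised categorization of medical-information inquiries

Pharmaceutical medical-information contact centers receive large volumes of
free-text inquiries from healthcare professionals and patients — requests
for publications, adverse-event questions, dosing questions, meeting
requests, and so on. Routing and analytics need each inquiry categorized
into a fine-grained taxonomy, but manually labeling a training corpus is
prohibitively expensive and the data are too domain-specific for public
labeled sets to help. `medinq` implements a weak-supervision pipeline for
this problem:

1. **Preprocessing** — inquiries are cleaned (HTML/non-ASCII residue
   removed), split into sentences, spell-corrected with a symmetric-delete
   index verified by Damerau-Levenshtein distance, and concatenated words
   are re-segmented by dynamic programming under a unigram cost model.
2. **Heuristic weak labeling** — a rule engine extracts key phrases
   (lexicon-assisted noun-phrase chunks), maps them to entity types
   (Treatment, Condition, Document, Professional, …), approximates
   dependency relations (`modifies`, `subject`, `cooccur`), and evaluates
   prioritized declarative rules — conjunctions of entity, lexical,
   relation and knowledgebase-pair predicates — assigning each sentence
   exactly one of 23 subcategories (or the `General or Other` fallback),
   which rolls up to a root category through a two-level taxonomy.
3. **Cost-sensitive classification** — TF-IDF features (word 1–5-grams,
   top 20,000 by document frequency, L2-normalized rows) feed
   one-versus-rest linear classifiers and a single-layer sigmoid neural
   head trained on the weak labels. Class imbalance is corrected by two
   weighting schemes:

   - per binary problem, `weight_i = n_samples / (n_classes · bincount_i)`
     applied as sample weights, and
   - per label `n` with `K` of `T` training samples over `N` labels,
     `W_n = (T + K·SV) / (N·K)` (scale value `SV = 3`), multiplying the
     per-label binary cross-entropy
     `l_n = -W_n·[Y_n·log X_n + (1-Y_n)·log(1-X_n)]`, with the scalar loss
     `L = mean{l_1 … l_N}`.

Because the original corpus is proprietary, the package ships a synthetic
inquiry generator (`medinq.synthetic`) with ground-truth labels, Zipf class
imbalance, multi-topic sentences, and transcription noise, plus a demo
knowledgebase and rule set, so every stage is measurable end to end.

## Worked example

```python
from medinq import resources as res
from medinq.preprocessing import RawInquiry, PreprocessConfig, preprocess_corpus
from medinq.rule_engine import label_corpus

inquiry = RawInquiry("w1",
    "Would like to have any documentation available on allergies of Product-A. "
    "Are there any cases of having allergies after taking Product-A? "
    "I want MSL to meet me and discuss this further.")

cfg = PreprocessConfig(dictionary=res.demo_spelling_dictionary(),
                       protected_terms=frozenset(res.demo_lexicon().tokens()))
sentences = preprocess_corpus([inquiry], cfg)
ruleset, tree, rc = res.demo_rules()
ds = label_corpus(sentences, ruleset, res.demo_pairs(), res.demo_lexicon(),
                  tree, nouns=res.demo_nouns(), relation_config=rc)
for lab in ds.labels:
    print(lab.index, lab.subcategory, lab.rule_id, "->", lab.root)
```

prints

```
0 Publication Request pub-request-available-doc -> Scientific Exchange
1 Safety Data safety-adverse-pair -> Safety
2 Meeting Request meeting-professional-meet -> Scientific Exchange
```

Sentence 1 contains both an `available <modifies> Document` pattern
(Publication Request) and a Condition–Treatment pair known to the
knowledgebase as an adverse effect (Safety Data); the Publication Request
rule has higher precedence and overrules — sentence 2 carries only the
safety pattern, and sentence 3 fires `Professional <subject> meet`
(Meeting Request).

A command-line interface covers the same pipeline:

```bash
medinq simulate --n 20000 --zipf 1.2 --seed 42 --out corpus.jsonl --gold gold.jsonl
medinq preprocess --in corpus.jsonl --out sentences.jsonl
medinq label --sentences sentences.jsonl --out labels.jsonl
medinq train --labels labels.jsonl --algo ovr-logreg --balanced --seed 0
```

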