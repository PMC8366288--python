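# Methods

## Problem setting

Sentences from medical-information inquiries are assigned one of 23
subcategories arranged under five root categories, with a `General or
Other` fallback outside the trainable set. Labels are produced in two
stages: a heuristic rule engine generates weak labels programmatically,
and supervised classifiers are trained on those weak labels. The package
treats the rule engine, the weighting schemes and the evaluation protocol
as the object of study; transformer fine-tuning and commercial machine
translation of non-English inquiries are out of scope (non-English records
are tagged `untranslated` and passed through).

## Preprocessing

*Cleaning* removes HTML tags and entities and strips (not transliterates)
non-ASCII characters, then collapses whitespace. *Sentence splitting* is a
deterministic rule splitter: boundaries at `. ? !` followed by whitespace
and an upper-case letter or digit, with an abbreviation guard list; a
learned splitter can be substituted behind the same function signature,
but a rule splitter keeps runs reproducible. *Tokens* are whitespace units
with leading/trailing punctuation detached; internal hyphens are kept so
product codes (`Product-A`) survive intact.

*Spelling correction* uses a symmetric-delete index: every deletion
variant (up to `max_edit_distance = 2` characters removed) of every
dictionary term points back to its sources, so candidates for a query are
the union over the query's own deletion variants; candidates are verified
with restricted Damerau-Levenshtein (optimal string alignment) distance.
Ties are broken by higher term frequency, then lexicographically.
Corrections are applied only to alphabetic tokens of length ≥ 3 that are
absent from both the dictionary and the entity lexicon — lexicon surfaces
are protected so correction can never destroy a rule anchor.

*Concatenated words* (`anydocumentation`) are split by dynamic programming
over split points, minimizing summed unigram costs (negative log relative
frequency). Unknown segments cost `unknown_cost_per_char` per character,
set strictly above the largest known-word cost: a split into known words
always wins, while a fully unknown token (e.g. a product code) is never
split. Segmentation is attempted only for unknown tokens of length ≥ 6
after correction fails, and a split is accepted only when every segment is
in vocabulary. The pipeline is idempotent: its output passes through
unchanged.

## Weak labeling

Key phrases are maximal chunks of the pattern `determiner? adjective*
noun+` over small closed word lists plus a packaged noun list and the
lexicon's own tokens, together with all multi-token lexicon matches;
contained spans are dropped. Entity mapping tries the longest token suffix
of each phrase against the lexicon (case-insensitive exact match, no
stemming), so `any documentation` resolves through its head to the
`Document` type.

Dependency parsing is replaced by a windowed approximator: `modifies(A,B)`
when mention A precedes mention B within 6 tokens and the gap is empty or
contains a connective (`of`, `on`, `for`, `after`, `taking`, …);
`modifies(w,M)` for configured modifier tokens (e.g. `available`) within
the window of a mention; `subject(A,v)` for configured verb tokens with
the closest preceding mention; `cooccur` for every mention pair. A real
parser can be plugged in via the `relation_extractor` argument of
`analyze_sentence`. The approximator is intentionally simple: the demo
rules and the synthetic templates are written in a controlled grammar that
the approximator recovers exactly, which is what makes the rule engine
testable without a parser dependency.

Rules are declarative conjunctions of `ENTITY`, `LEXICAL`, `REL` and
`KB_PAIR` predicates; entity types referenced by a rule are bound to
concrete mentions by an exhaustive consistent-assignment search (sentences
carry only a handful of mentions, so the product search is cheap). Each
rule has an integer priority; among all firing rules the smallest priority
wins, ties broken by rule id, so labeling is independent of rule-file
order, and adding a rule can never relabel a sentence already matched at
strictly higher precedence. Sentences matched by no rule receive the
fallback label and are excluded from training and evaluation. Priorities
are a global total order — the simplest scheme consistent with observing
only pairwise "X overrules Y" behavior.

The packaged demo knowledgebase (6 treatments, 8 conditions, 6 document
types, 3 professional roles; all condition-treatment pairs registered as
`adverse_effect`) and 28-rule set cover the worked example and all
generator templates. They stand in for the production knowledgebase and
rule set, which are proprietary and far larger; 16 of the 23 subcategory
names are invented to fill the published taxonomy skeleton.

## Features

TF-IDF: word 1–5-grams after stop-word removal (packaged English list,
replaceable), vocabulary capped at the 20,000 n-grams with highest
document frequency (ties lexicographic), smooth idf
`ln((1+D)/(1+df)) + 1`, raw term counts, L2-normalized rows, computed at
sentence level. The cap is by document frequency — the standard reading of
"maximum features" — and refits are bit-identical. Whether sublinear tf or
a different normalization was used upstream is unknowable from the
published description; the smooth-idf + L2 convention is the dominant one.

Embeddings are a provider contract (`embed(texts) -> (n, dim)`); the
built-in provider is a salted-hash signed bag-of-words projection —
deterministic, download-free, any dimension — used as the test-time stand-in
for large pretrained sentence encoders. Stop words are not removed for
embeddings.

## Imbalance correction and classifiers

One-versus-rest: each of the 23 labels gets an independent binary
L2-regularized logistic regression (lbfgs, tol 1e-6, C = 1) or hinge-loss
linear SVM (C = 3) with probabilities from a Platt-style sigmoid fitted on
the training margins. With balancing on, the binary problem's samples are
weighted by `weight_i = n_samples/(n_classes·bincount_i)`, which satisfies
`weight_i·bincount_i = n_samples/n_classes` for both classes and reduces
to unit weights when balanced. Solvers are delegated to scikit-learn — the
contribution under study is the weighting and the pipeline, not the
optimizer.

Neural head: one linear layer (input dim → 23) with sigmoid outputs,
Xavier-uniform initialization, minibatch gradient descent (batch 32, 5
epochs) on the weighted binary cross-entropy; per-label losses are
averaged over the batch, then over the 23 labels. The rescaling weights
`W_n = (T + K·SV)/(N·K)` are strictly decreasing in `K` and equal
`1 + SV/N` at uniform class sizes, so the correction vanishes as imbalance
vanishes; `SV = 3` is the published operating point. The printed form of
this formula parenthesizes as `T + (K·SV)/(N·K) = T + SV/N`, independent
of `K`, which contradicts its stated minority-boosting behavior; the
implementation uses the `(T + K·SV)/(N·K)` reading, with the literal one
available behind a `literal=True` flag for auditing. Probabilities are
clipped at 1e-12 to keep the loss finite.

The learning rate defaults to 20. With the loss normalized by both batch
size and label count, per-parameter gradients are of order `1/(B·N)`; at
rates of order 0.1 the sigmoid outputs cannot cross the decision threshold
within the 5-epoch budget (all predictions fall back), while 20 gives a
smooth, monotone, near-converged loss curve on the reference corpus. The
weighted-versus-unweighted contrast is qualitatively stable across rates
5–40.

Decision rule (both heads): among labels whose positive probability
reaches the 0.5 threshold, the most probable wins (ties: lowest label
index); if none reaches it the sentence falls back to `General or Other`.
A `multi_label=True` mode returns all above-threshold labels; the
single-label default matches the rule engine's exactly-one-label contract.

## Evaluation

Per-label one-versus-rest confusion counts give precision, recall and F1
(F1 = 0 when P + R = 0), with micro, macro and support-weighted averages
always reported; scikit-learn's metrics serve as an independent
cross-check in the tests, not as the implementation. Cross-validation is
stratified by label (shuffled round-robin deal, overall fold sizes within
one), falling back to unstratified folds with a warning when a label has
fewer than k instances; the default is k = 10 — the protocol description
— while the published hyperparameter table lists k = 5; both run, k is a
parameter, and the discrepancy is inherited rather than resolved. Expert
review sheets (sentence, predicted subcategory, blank assessment) support
the `correct/incorrect/incomplete` leave-out protocol; scoring reports
accuracy and the per-assessment breakdown and refuses sheets with blank or
out-of-vocabulary assessments.

## Synthetic corpus

The generator emulates the statistical structure of the proprietary
corpus (~130K labeled sentences): inquiries of 1–4 sentences; label draws
from a Zipf distribution (exponent 1.2 over a fixed frequency ordering of
the 23 labels — the true distribution is unpublished, so this is a
stand-in, not a claim); 10% chit-chat sentences matched by no rule
(fallback gold); and transcription noise applied after gold assignment —
per-token random character edits (p = 0.03), dropped inter-word spaces
(q = 0.02), HTML/non-ASCII insertions (r = 0.01). Noise never crosses a
sentence boundary, so recovery is measured per sentence.

A fixed 25% of trainable sentences are **multi-topic**: a secondary
clause, drawn uniformly over labels, is appended (`… and also …`), and the
gold label is the component whose rule has the smallest priority number —
the same resolution the rule engine's prioritization applies. Multi-topic
sentences are a documented property of real inquiries (prioritization
exists precisely because one sentence can support several labels), and
they are what makes the imbalance correction measurable: anchors of
low-precedence minority labels then also occur in sentences labeled with
higher-precedence topics, so an unweighted one-versus-rest fit leaves
minority probabilities below threshold (near-perfect precision, collapsed
recall), while balanced weights recover recall at some precision cost.
The secondary topic is drawn uniformly rather than by Zipf, reflecting
minor topics surfacing as passing mentions.

What the generator does **not** emulate: real clinical language variety
(templates are a controlled grammar), genuine misspelling distributions
(edits are uniform random), translation artifacts, label definitions
beyond their anchors, and annotator-style label noise. Passing tests
therefore demonstrate the internal consistency and the imbalance
machinery of the pipeline on a corpus with known truth — not clinical-text
performance. Published absolute scores on the proprietary corpus are not
reproducible here and are not targeted.

## Problem sizes and numerical choices

Reference experiments use 2,000 sentences for rule-recovery checks and
20,000 sentences (seed 42, Zipf 1.2) for classifier experiments — large
enough for the smallest label to retain ~100 training instances. The
spell-correction oracle check compares the symmetric-delete index against
a brute-force full-dictionary Damerau-Levenshtein scan (5,000 random
terms, 1,000 corrupted queries, exact agreement, including tie-breaks);
the segmentation oracle check compares the DP against exhaustive
enumeration of all 2^(L-1) splits for words up to length 18. TF-IDF is
checked against a naive count-weight-normalize oracle at 1e-10. All
stochastic paths (generation, folds, training) are driven by explicit
seeds and are bit-identical on reruns.
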