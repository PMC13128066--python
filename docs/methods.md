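# Methods

## Problem and model

Nursing records are mostly free text, which blocks secondary use of
nursing data. Mapping each record to a standardized coded nursing
terminology — diagnosis terms and intervention terms, e.g. a CCC-style
vocabulary of 176 diagnoses and 201 interventions with NANDA-I / NIC
codes as supplementary standards — turns a narrative note into two code
sets per record. `nursemap` implements a two-stage retrieval-augmented
mapping pipeline plus the surrounding baselines and evaluation suite.

**Stage 1 — dense candidate retrieval.** A record is split on Chinese and
English clause punctuation (default set `。！？；，、` and `.!?;,`) into
chunk subqueries, and the whole record is kept as one more subquery, so
both local clauses and global context participate. Subqueries,
terminology entries (serialized as `label — description`) and annotated
corpus examples (raw text) are embedded into fixed-width dense vectors,
L2-normalized, and scored in one matrix product, so entry (i, j) of the
score matrix is the cosine similarity of subquery i and candidate j. Per
subquery, the top-k candidates are retrieved separately from the
terminology ("reference") index and from the annotated-example
("corpus") index; the union over subqueries and sources is deduplicated
by item id keeping each item's maximum score, and sorted by score
descending, giving the record's context window (size ≤ 2k × number of
subqueries).

**Stage 2 — constrained generation.** Each subquery is rendered with its
retrieved context into a fixed-order prompt (task instruction, coding
rules, retrieved terminology entries, worked examples, the subquery,
output schema note) under one of four strategies: `no_rag` (instruction
plus the full record, prompted once), `rag_zero_shot` (retrieved entries,
no examples), `rag_few_shot_retrieved` (entries plus the top-k most
similar annotated examples per subquery) and `few_shot_static` (entries
plus 20 examples drawn once per run with the recorded seed). The prompt
demands a bare JSON array of code strings — no prose, no duplicates,
empty array when nothing applies. The backend is a pluggable text→text
adapter; responses are parsed by regular expression (fenced JSON block
first, else the first bracketed span; anything unparseable degrades to an
empty list with a counted parse-error flag), every code is validated
against the terminology (surrounding whitespace trimmed, otherwise exact
case-preserving match; unknown codes dropped and counted), and a record's
prediction is the union over its subqueries, each code routed to the
diagnosis or intervention set by its terminology category. Union
aggregation favors recall; the per-record sets are what the evaluation
consumes.

## Evaluation suite

Per record with gold set G and predicted set P: TP = |G∩P|, FP = |P\G|,
FN = |G\P|; precision, recall, F1, and IoU = TP/(TP+FP+FN). F1 and IoU
are linked by F1 = 2·IoU/(1+IoU) on every non-degenerate record, which
the tests enforce. Degenerate convention (disclosed in reports): both
sets empty → all metrics 1.0; exactly one empty → all 0.0, keeping the
macro-average total. Overall scores are macro-averages; diagnoses and
interventions are always evaluated separately.

Retrieval is scored by Recall@k (default k ∈ {1, 3, 5, 10}): the
macro-averaged fraction of a record's gold codes among the top-k entries
of its merged reference ranking. Computing it over the merged window
(rather than per-source lists) is an interpretation choice; it is the
ranking the prompt actually sees.

Inter-rater agreement uses Fleiss' κ = (Po − Pe)/(1 − Pe) with per-item
pairwise agreement P_i = (Σ_j n_ij² − n)/(n(n−1)), Po the item mean and
Pe = Σ_j p_j². κ is undefined when all rating mass sits in one category
(Pe = 1); this raises an explicit degenerate-agreement error rather than
returning a sentinel. The default unit of analysis is the record × code
binary presence judgment over the code universe in use; because most
judgments are concordant absences this yields very high raw agreement at
moderate κ — the pattern typical of coding-agreement studies. Per-record
or custom units can be analyzed by building the `RatingTable` directly.

Terminology coverage reports the cardinality of the union of a
category's gold codes over all records against the category's inventory,
as a one-decimal percentage.

## Baselines

The TF-IDF baseline uses smoothed logarithmic IDF
(ln((1+N)/(1+df)) + 1), raw counts, and L2-normalized vectors
(scikit-learn's vectorizer behind the module surface), with character
bigrams by default so Chinese text needs no word segmenter; a
whitespace-token analyzer is available for English-only corpora. The
embedding-cosine baseline reuses the retrieval embedder contract, so a
contextual sentence encoder is an adapter choice, not separate code.
Rankings become predicted sets through an explicit rule — top-n, or
score ≥ τ (default: threshold, τ configurable) — because no single
canonical decision rule exists for turning a ranking into a set; both
rules are exposed and reported.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | per-source retrieval depth per subquery; 5 balances sensitivity against prompt length (Recall@k is reported for 1, 3, 5, 10) |
| embedding `dim` | 512 | vector width of the dense retriever; matches the sentence-embedding model the design targets |
| punctuation set | `。！？；，、.!?;,` | clause delimiters for segmentation; configurable |
| TF-IDF analyzer | char bigrams | script-agnostic tokenization |
| prediction rule | threshold τ | ranking → set conversion for baselines |
| report rounding | 4 decimals | table precision; internals stay full precision |

The built-in `HashedNGramEmbedder` (BLAKE2-salted character-trigram
feature hashing, 512-dim) is the default offline embedder: deterministic
across processes, no downloads, adequate for lexically grounded synthetic
text. It is a real embedder in its own right, not a semantic sentence
encoder: paraphrases sharing few character n-grams score low, so absolute
retrieval quality on real clinical text requires plugging in a trained
sentence-embedding adapter through the same contract.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of the study design the package
models: a 176-diagnosis / 201-intervention vocabulary, a 100-record
evaluation set with consensus gold sets, a disjoint 1500-example
annotated corpus, and a 3-rater agreement table. Each term carries a bank
of paraphrase clauses (templated rewordings containing the label
verbatim); a record is a shuffled, punctuation-delimited concatenation of
one paraphrase per gold code (1–4 codes per category, uniform) plus
Binomial(n_clauses, 0.2) irrelevant noise clauses. The noise rate 0.2 and
the rater flip rate 0.02 are fixed generator conditions chosen to look
like realistic filler density and like the near-ceiling raw agreement of
careful expert annotation, respectively. All outputs are byte-identical
given the same config and seed.

Two deterministic stand-ins close the loop offline. The one-hot embedder
maps each paraphrase clause to the basis vector of its term, making
retrieval exact by construction, so downstream stages can be tested in
isolation. The oracle backend answers each record's prompts with its
gold codes, each dropped with probability ε, plus one Bernoulli(ε)
spurious-known-code injection opportunity per gold code; the noisy set is
drawn once per record from a seed derived from (run seed, record id), so
outputs are identical across that record's subqueries and invariant to
processing order. Under this model macro recall converges to 1 − ε.

What passing tests therefore show: every computational stage matches its
from-definition oracle; the composed pipeline recovers planted gold
exactly with perfect components and degrades at the planted rate with
noised ones. What they do not show: performance on real nursing
narratives, whose paraphrases are not substring-recoverable, whose gold
annotation is itself uncertain, and whose generation step is a real
language model rather than a stub. Absolute scores on synthetic data say
nothing about absolute scores on hospital data.

## Numerical choices and edge cases

- Zero embedding rows (texts with no features) stay zero after
  normalization, score 0 against everything, and are counted in warnings.
- Cosine scores are clipped to [−1, 1] only at hit construction;
  similarity matrices are raw products of normalized vectors.
- Top-k ties break by ascending item ordinal (stable argsort); merged
  window ties break by first retrieval arrival. Both are arbitrary but
  deterministic.
- Unknown predicted codes are dropped, never fuzzily matched: validation
  is an integrity gate.
- Empty records produce no subqueries, an empty window, and empty
  predicted sets, each with a warning rather than an error.
- Macro metrics over zero records, Recall@k with all-empty gold, and κ
  with Pe = 1 raise explicit errors instead of returning NaN.

## Problem sizes used in the shipped checks

The acceptance script runs the perfect-component pipeline at the full
emulated scale (377 terms, 100 records, 1500 examples) and the ε = 0.2
degradation run at 200 records with a 200-example corpus; the random
oracle suites use 100–1000 randomized small instances. These sizes give
tight Monte-Carlo bands (the ±0.05 recall band at ε = 0.2 holds across
seeds) while the whole suite stays fast enough to run on every change.

## Known limitations

- No approximate nearest-neighbor index: retrieval is exact dense search,
  fine at terminology scale (hundreds of entries), quadratic beyond.
- No live generation adapter ships in the package; the backend protocol
  is the integration point and only deterministic stubs are bundled.
- The prompt template is a faithful reconstruction of the constrained
  JSON-array style the design calls for, in English; deployments should
  swap in their own bilingual template text (it is configuration).
- Fleiss κ's unit of analysis materially affects its value; the default
  (record × code presence) is one defensible choice and is labeled in
  outputs, not a canonical one.
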