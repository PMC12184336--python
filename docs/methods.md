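# Methods

## Problem setting

A diagnostic *case* is a clinical vignette with a gold-standard solution of
one or more correct concepts in a clinical terminology (in real collections
roughly a third of cases accept more than one answer). Each *diagnostician*
— a physician or an LLM — submits a ranked free-text list of candidate
diagnoses. The package links those strings to concept IDs, aggregates the
lists into a collective differential, learns per-diagnostician weights from
training data, and evaluates everything with top-k accuracy and mean
reciprocal rank under repeated cross-validation.

## Normalization and linking

Normalization is defined entirely by a versioned JSON *dialect*
(`data/dialect_default.json`): a stop-word list, a British→US spelling
table, an acronym-expansion table, and ordered suffix-rewrite plural rules,
plus case folding and punctuation stripping. The pipeline is idempotent by
construction: every rewrite emits tokens no rule fires on again. The plural
rules are deliberately approximate suffix rules (e.g. they turn "diabetes"
into "diabete"); because queries and the synonym index pass through the same
dialect, such quirks cannot break matching — only the dialect file defines
what "normalized" means. A trailing parenthesized semantic tag
("… (disorder)") is stripped before indexing so fully specified names and
plain synonyms share one token set.

Exact matching requires token-set equality (Jaccard similarity 1) against
any stored synonym. When several concepts share a token set, the semantic
tag disambiguates in the fixed order disorder > finding > morphologic
abnormality > body structure > person > organism > specimen > other; ties
within a tag fall back to the smallest concept ID, and remaining collisions
are surfaced by `match_audit` rather than silently resolved.

The fallback matcher embeds strings with character-trigram TF-IDF
(`char_wb`, n=3) fitted on the terminology's synonym corpus; both synonyms
and queries are rendered as their sorted normalized tokens, making the
embedding invariant to word order and dialect-absorbed variation while
trigrams give robustness to typos. The concept holding the most
cosine-similar synonym wins; ties break to the smallest concept ID. By
default every query receives a concept (`min_similarity=0`); a positive
threshold demotes weak hits to unmatched. Any object with `fit`/`transform`
over raw strings can replace the default vectorizer (e.g. a transformer
sentence embedder); the contract, not the embedding model, is what the rest
of the pipeline depends on. A query whose trigrams are entirely unknown to
the fitted vocabulary has a zero-norm embedding and is rejected as
degenerate rather than matched arbitrarily.

## Aggregation

Diagnostician *j*'s diagnosis at rank *r* earns *w_j / r*; a concept
repeated within one list contributes only from its best rank (a diagnosis
restated lower adds no information). Totals are summed over members and
sorted descending; ties break by best supporting individual rank, then
concept ID, so the output is deterministic and invariant to member order.
Because the ordering is invariant to positive rescaling of all weights,
learned weights are used as-is, without normalization. Member lists are
scored over their full length by default (`max_input_rank` can truncate);
the top-5 cutoff belongs to the evaluation metric, not to aggregation.

## Weight learning (WMVE)

Weights start at 1 and accumulate per training case:
`alpha_j = s_j * (n - sum_k s_k) / n`, with `s_j` the member's per-case
score under the configured metric (top-k indicator, or reciprocal rank with
the same rank-5 cutoff as evaluation). Since `0 <= s_j <= 1` and
`sum s <= n`, increments are non-negative: weights are monotone
non-decreasing and the final weight `1 + sum_i alpha_{j,i}` is independent
of case order.

Physicians share one weight (key `human_shared`). Per training case, all
groups of `n_humans` physicians are enumerated — or 100 unique groups
sampled when more exist — and each member's alpha is computed inside the
full ensemble (group + LLM members). The quantity averaged was a genuinely
open choice; this implementation averages alpha over group members and over
groups and applies **one update per case** (LLM alphas are likewise averaged
over groups, since they depend on the group's score total). The alternative
— one update per sampled group, i.e. increments summed rather than averaged
— is available as `per_group=True`. The per-case RNG for group sampling is
keyed by `(seed, case_id)` via a stable hash, which keeps learning
order-invariant and reproducible.

Training cases lacking a response from every LLM member, or with fewer
physicians than the configuration needs, are skipped and counted in the
`LearnReport`.

## Evaluation and cross-validation

`r_i` is the rank of the first entry matching any gold-standard concept;
`r_i = inf` beyond rank 5 or when absent, so such cases contribute 0 to MRR.
The cutoff of 5 is the field's convention and is exposed as a parameter for
sensitivity checks only.

Cross-validation is 10-times repeated five-fold (50 outcomes): per outcome
the training fold alone determines weights, the other four folds are scored,
and the summary is the mean of per-outcome means — not pooled ranks. Fold
assignment is uniform random per repeat (no stratification) under the plan's
seed. Human-containing configurations are evaluated per case by averaging
metrics over physician groups, reusing the same 100-group cap as weight
learning for consistency; cases with fewer physicians than `n_humans` are
filtered out (the minimum-five-physicians eligibility rule at n=5). The
`run_configuration` summary object records eligible and filtered counts.

## Complementarity analytics

`complementarity` tabulates, over paired per-case ranks from two sources, the
percentage of cases in each of the 36 rank combinations (1–5 and "not
ranked"); cells sum to 100 and the diagonal is same-rank co-occurrence. The
`both_wrong` condition restricts to cases where neither source is correct at
rank 1. `rank1_agreement` compares top-ranked *concepts* (not just ranks),
overall or restricted to both-wrong cases — the statistic that exposes
whether two sources err toward the same wrong answers.
`fraction_outperformed` compares each physician's mean per-case metric with
a reference on the same case subset and reports the population share
strictly below and below-or-tied.

## Synthetic worlds

The generator emulates the statistical structure of real multi-diagnostician
case collections without any licensed content:

* **Terminology**: each concept is "unique pseudo-word + category word"
  (e.g. "bacode infection"), with word-order, plural and British-spelling
  synonyms. The unique head word guarantees distinct token sets across
  concepts, so round-trip recovery is exact by design on uncorrupted input.
* **Cases**: one gold concept, or two with probability `multi_answer_prob`
  (default 0.34, the share observed in real cohorts).
* **Responses**: a diagnostician lists a correct concept with probability
  `p_correct`, at a rank drawn from a geometric distribution truncated at
  the list length (correct answers cluster near the top; the generative
  model is the package's own choice). Wrong entries are a `rho`-mixture of a
  per-case shared "attractive wrong answer" pool — one pool per
  `error_pool` label, inducing correlated errors within a label — and
  idiosyncratic uniform draws. Disjoint labels (e.g. `human` vs `llm`) give
  complementary error structure.
* **Rendering**: each entry becomes free text via synonym choice plus
  plural / British / word-order / typo corruption at configured
  probabilities (defaults 0.10/0.05/0.10/0.02, synonym swap 0.20); the
  intended concept is recorded as ground truth. The typo model
  (single-character substitution or deletion) specifically exercises the
  trigram fallback; the other corruption classes are absorbed exactly by the
  dialect.

What passing tests on these worlds do **not** show: real free text is
messier than the corruption model (abbreviation idiosyncrasies, multi-word
reorderings with inserted qualifiers, misspellings beyond one character),
real terminologies contain near-duplicate concepts the trigram fallback can
confuse, real diagnostician errors are not a clean two-component mixture,
and real physician coverage is far sparser than the default full coverage.
Absolute accuracy numbers on synthetic cohorts therefore characterize the
machinery, not clinical performance.

## Numerical and design notes

* Ranks are 1-based everywhere; "not ranked" serializes as `null`, never 0.
* Cosine similarities are clipped at 1 to absorb floating-point overshoot;
  fallback candidate lists keep the top 5 concepts for audit.
* All stochastic stages take explicit seeds; group sampling inside weight
  learning and evaluation derives per-case RNGs from `(seed, case_id)`
  hashes so results do not depend on iteration order.
* Problem sizes in the test and acceptance runs (1,000-concept
  terminologies, 2,000-case cohorts, 150-case CV worlds, 20 paired seeds)
  were chosen as the smallest sizes at which the stochastic properties under
  test are stable well beyond their assertion margins.
* The LLM-response cleanup (`strip_llm_preamble`) drops a recognized
  conversational first line and strips list numbering using a versioned
  pattern file (`data/llm_cleanup.json`); the pattern set covers the common
  forms, not an exhaustive grammar.

## Known limitations

* The shared-human-weight averaging semantics and the group-evaluation cap
  are interpretations of an under-specified procedure; both alternatives are
  implemented and flagged where they diverge.
* The dialect ships small curated rule tables; it is not a full lexical
  normalizer and makes no claim of bit-compatibility with any external tool.
* No Bayesian uncertainty on performance comparisons — per-outcome standard
  deviations in the CV summary are descriptive only.
* Equity/fairness-aware weighting and specialty-conditional weights are out
  of scope; specialty labels are taken as given metadata.
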