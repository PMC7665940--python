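# Methods

## The problem

Dictionary-based text analysis programs in the LIWC tradition tag text word
by word against lexicons of words, word stems and emoticons organised into
a category hierarchy (here: anxiety, anger and sadness nested under
negative emotion; positive and negative emotion nested under total affect)
and report, per writer, the percentage of their words falling in each
category. Whether those machine tags mean what a human reader would mean is
an empirical question. `lexemo` implements the token-level validation
design for answering it: treat each word token as one observation, treat
consensus human coding as the reference standard, and evaluate a tagger per
category as a screening test.

## The statistical battery

For one category and one tagger, the 2×2 token-level confusion table gives

- sensitivity = TP/(TP+FN) — emotion words (per the coders) the tagger catches;
- specificity = TN/(TN+FP) — non-emotion words it leaves alone;
- PPV (precision) = TP/(TP+FP); NPV = TN/(TN+FN);
- F = 2·PPV·sens/(PPV+sens), the harmonic mean of precision and recall.

Proportions carry 95% confidence intervals. The default is the Wilson score
interval (a Wald option exists): the battery routinely produces proportions
near 1 (specificity ≈ 0.997) and near 0, where Wald intervals degenerate or
escape [0, 1]. Intervals come from `statsmodels.stats.proportion`.

Taggers are compared per category and metric with a pooled two-proportion
z test, two-sided:

    z = (p1 − p2) / sqrt(p̂(1 − p̂)(1/n1 + 1/n2)),   p̂ = (x1 + x2)/(n1 + n2).

Each metric uses its natural denominator (sensitivity: TP+FN, specificity:
TN+FP, PPV: TP+FP, NPV: TN+FN). F scores have no exact sampling
distribution here; the comparison treats F as a proportion with effective
denominator equal to the category's human-coded reference-word count and is
flagged `approximate` in every output. Family-wise error is controlled by
Bonferroni division, with two configurable families whose defaults are
m = 24 (the grid of diagnostic-metric comparisons, per-test threshold
.0021) and m = 6 (the per-category F comparisons, threshold .0083).

PPV depends on category prevalence π by Bayes' rule,

    PPV = sens·π / (sens·π + (1 − spec)(1 − π)),

which the package exposes analytically (`ppv_from_prevalence`) for
extrapolating precision to populations with different base rates of
emotional expression. Computed from the same confusion table, the identity
holds to floating-point rounding, and the test suite asserts it at relative
tolerance 1e-12.

Inter-rater agreement uses Cohen's κ = (p_o − p_e)/(1 − p_e) (value
delegated to scikit-learn; the degenerate p_e = 1 case is detected locally
and raised as an error). Per-participant percentage tables are compared
across taggers and coders with Pearson correlations; a constant column is
an error at the library level and is dropped, not imputed, in pipeline
reports.

## Matching semantics

Tokenization: words are maximal runs of letters (with internal
apostrophes) after Unicode NFC normalization and case-folding; hyphenated
compounds split; digits and punctuation yield no tokens; a
whitespace-delimited chunk equal to a known emoticon becomes an emoticon
token. Emoticon tokens join the word-count denominator only when the
dictionary declares `emoticons_count_as_words`, reflecting that only newer
dictionary generations treat netspeak as countable emotion entries.

Matching, per token: context rules for the token's normalized form run
first — a rule fires when a neighbour within ±2 positions matches one of
its conditions (the "like" rule fires after "I"/"they"/"will" and the
like); when a rule for the target exists but none fires and the rule is
marked `suppress`, the token gets no categories at all. Otherwise an exact
entry beats every stem; among stems the longest prefix wins and its full
category set applies. Every hit is closed upward through the hierarchy, so
a sadness hit also increments negative emotion and total affect, and a
multi-category entry increments each of its categories once per token.
These precedence choices (exact-over-stem, longest-stem) are the least
surprising conventions; they are pinned down by a brute-force
entry-by-entry oracle that the engine must agree with on hundreds of
randomized lexicon/document instances.

The dictionary file dialect (magic header, TAB-separated category table,
whitespace-separated entry lines with `*` stem suffix, a `%rules` section)
is this package's own, with read/write round-trip identity enforced by
test; real LIWC dictionaries are proprietary and are neither shipped nor
reconstructed.

## Reference coding and rollup

Human coding uses a closed eight-way scheme: positive feelings, optimism,
other positive, anxiety, anger, sadness, other negative, not-emotion — one
label per token. For machine comparison a label is rolled up through the
hierarchy (sadness → {sadness, negative emotion, total affect}). The three
positive subcategories all map to positive emotion with no machine
subcategory target, because later dictionary generations dropped those
subcategories for poor base rates; the same rollup is used against every
version so that one human reference column serves all comparisons. A
human/machine disagreement at subcategory level (human anxiety, machine
sadness) therefore counts as a true positive at every shared ancestor and
as FN/FP at the subcategory level — a direct consequence of one-vs-rest
evaluation, made explicit here.

## Synthetic data

The generator emulates the study conditions under which such validations
are run: 63 participants at 2,631 tokens each (165,753 words, matching the
~165,754-word scale of the motivating corpus as closely as uniform
per-participant counts allow), with per-token single-label reference draws
at the human-coder prevalences: total affect 1.8% of words, positive 0.9%,
negative 0.9%, anxiety 0.3%, anger 0.1%, sadness 0.2%. The negative mass
not claimed by a subcategory (0.3%) is "other negative"; the positive mass
is split positive-feelings 0.4% / optimism 0.2% / other-positive 0.3%
(no published split exists; the choice is fixed here and configurable).
Optional beta-distributed participant effects emulate between-participant
heterogeneity and default to off. Vocabulary is synthetic pseudo-words with
emotion and non-emotion words disjoint, which keeps oracle bookkeeping
exact; nothing about topic, syntax or discourse is modelled, so passing
tests demonstrate correctness of the measurement machinery, not linguistic
performance on real text.

Synthetic taggers are dialed to per-category (sensitivity, specificity)
operating points; the defaults are the published per-category values of the
three dictionary generations being emulated. Two constraints make naive
independent per-category coin flips wrong: (a) hierarchy consistency — a
subcategory flag must imply its ancestors — and (b) at the default
operating points a child can be more sensitive than its parent (positive
emotion 0.873 vs total affect 0.858), and independent sibling
false-positive rates would union past the parent's dialed false-positive
rate. The sampler therefore draws all leaf categories from one shared
uniform per token (sibling false positives are comonotone, as in real
dictionaries where overlapping hits come from the same word) and gives each
parent the union of its children plus an independent top-up whose rate is
calibrated against the empirical union counts, separately within the
parent's reference-positive and reference-negative token groups. Leaf
operating points hold exactly per token; parent operating points hold
unbiasedly at group level — which is precisely the level a confusion table
measures. When a requested parent point lies below the children's union
the union stands and the dialed point is unattainable (not the case at the
defaults).

The mini-lexicon fixture generator (`generate_lexicon`) builds a small
dictionary exercising every entry kind — exact words, an over-matching stem
(so false positives like a "saddle" under "sad*" are planted on purpose), a
multi-category stem, a context-gated word, an emoticon — together with a
shuffled corpus assembled from one- and two-token units whose reference
label and predicted category set are known at construction time. End-to-end
confusion counts must equal this planted log token for token, which pins
the whole path (file round-trip, tokenizer, matcher, alignment, counting)
to an external bookkeeping oracle.

## Numerical and design choices

- All randomness flows from one top-level integer seed through
  `numpy.random.SeedSequence`; per-tagger streams are offset by a CRC-32 of
  the tagger tag so they are stable across processes. Same seed ⇒
  byte-identical corpora, predictions and reports (reports carry no
  timestamps; JSON is written with sorted keys).
- Degenerate inputs are errors, not NaNs: zero metric denominators, pooled
  proportions of 0 or 1 in the z test, chance agreement 1 in κ, constant
  columns in correlations, participants with zero countable tokens. The
  vectorized z used in simulation studies returns NaN instead, documented.
- Percentages are computed per participant and averaged unweighted across
  participants (with SDs) for summary tables; confusion-based metrics pool
  tokens across participants.
- Problem sizes in the test and acceptance workloads (200 oracle
  instances, 200 recovery replicates at 63×2,600 tokens, 5,000 calibration
  simulations at 2,000 per arm, a single 165,753-token end-to-end study)
  are chosen so every Monte-Carlo band in the suite is several standard
  errors wide at desk-top runtimes.

## Known limitations

- The F-score difference test's effective denominator is a stated
  approximation, not a derived sampling distribution.
- The context-rule mechanism covers bounded-window neighbour conditions
  only; nothing about tense, scope or long-range attribution.
- Group-level (rather than per-token) parent operating points mean the
  synthetic parent flags carry slightly less variance than a pure binomial
  draw; recovery coverage of Wilson intervals is therefore conservative.
- Correlations between a tagger and reference on synthetic corpora reflect
  the generator's independence assumptions, not the shared-topic
  correlation structure of real writing.
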