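# lexemo

Validation toolkit for dictionary-based emotion tagging.

Dictionary ("word count") text analysis programs tag text word by word
against lexicons of words, word stems and emoticons arranged in an emotion
hierarchy — anxiety, anger and sadness inside negative emotion; positive
and negative emotion inside total affect — and report the percentage of
each writer's words in each category. `lexemo` is for researchers who need
to know how much those tags agree with human judgment: it re-implements the
token-level validation design in which every word is one observation,
consensus human coding is the reference standard, and each tagger ×
category is evaluated as a screening test.

The package provides:

- **lexicon engine** — a LIWC-style dictionary format (exact words, `*`
  stems, emoticons, context rules such as "like" counting as emotion only
  after "I"/"they"/"will"), a tokenizer, hierarchical word-by-word
  matching, and per-participant category percentages;
- **reference annotation** — the eight-way human coding scheme (positive
  feelings, optimism, anxiety, anger, sadness, other positive, other
  negative, not-emotion), hierarchy rollup, token-level alignment with
  machine tags, and Cohen's κ;
- **accuracy metrics** — sensitivity, specificity, PPV, NPV with Wilson
  (or Wald) 95% CIs; F scores; pooled two-proportion z tests with
  Bonferroni correction; Pearson correlations; and the Bayes relation
  PPV = sens·π / (sens·π + (1−spec)(1−π)) linking precision to category
  prevalence π;
- **synthetic data** — seeded corpora of 63 participants × 2,631
  pseudo-word tokens with single-label reference draws at realistic
  prevalences (total affect 1.8% of words), synthetic taggers dialed to
  per-category operating points, and mini-lexicon fixtures whose
  end-to-end confusion counts are known at construction time;
- **CLI** — `lexemo tag | validate | simulate | report` for end-to-end
  runs producing deterministic JSON reports and rendered CSV tables.

See `docs/methods.md` for the statistical model, matching semantics and
design choices.

## Worked example

Simulate a study-scale corpus with a tagger dialed to sensitivity 0.858 /
specificity 0.967 for total affect, then measure it back:

```python
import lexemo as lx

cfg = lx.GeneratorConfig(seed=1)          # 63 participants, 165,753 words
truth = lx.generate_reference(cfg)
lx.generate_predictions(truth, "2001")
c = truth.realized_counts("2001", "affect")
sens, ppv = lx.sensitivity(c), lx.ppv(c)
print(f"confusion   tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}")
print(f"sensitivity {sens.value:.3f} (95% CI {sens.ci_low:.3f}-{sens.ci_high:.3f})")
print(f"ppv         {ppv.value:.3f} (95% CI {ppv.ci_low:.3f}-{ppv.ci_high:.3f})")
print(f"F score     {lx.f_score(ppv.value, sens.value).value:.3f}")
```

prints

```
confusion   tp=2576 fp=5351 fn=442 tn=157384
sensitivity 0.854 (95% CI 0.840-0.866)
ppv         0.325 (95% CI 0.315-0.335)
F score     0.471
```

The tagger finds 85% of the words human coders would call emotional, yet
only a third of its flags are words a coder agreed with — the
characteristic signature of a sensitive tagger at ~1.8% prevalence, and
exactly what the Bayes relation predicts:
`lx.ppv_from_prevalence(0.854, 0.967, 0.018)` ≈ 0.325. Comparing two
taggers' sensitivities (0.858 vs 0.904 at ~3,000 reference words each)
with the Bonferroni-corrected two-proportion test:

```python
res = lx.two_proportion_test(0.858, 3018, 0.904, 3018,
                             alpha_corrected=lx.bonferroni(0.05, 24))
print(f"z = {res.z:.2f}, p = {res.p_value:.2e}, significant: {res.significant}")
# z = -5.52, p = 3.33e-08, significant: True
```

From the shell, the same pipeline runs on files:

```sh
lexemo simulate --seed 4 --out study --with-minilex
lexemo validate --lexicon mini=study/minilex.dic \
    --corpus study/minilex_corpus.tsv --reference study/minilex_reference.tsv \
    --out run
```

which writes `run/report.json` plus CSV tables (metric grids with CIs and
pairwise significance letters, percentage summaries, correlation
matrices). Identical configuration and seed reproduce the report byte for
byte.

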