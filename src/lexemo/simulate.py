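"""Seeded synthetic corpora, reference annotations and taggers.

The generator emulates the structure of a token-level validation study of
dictionary-based emotion tagging: a support-group-style corpus of 63
participants and ~165,000 words in which human coders label each word with
at most one of eight emotion subcategories, and one or more automated
taggers flag words with configurable per-category sensitivity and
specificity.  Default prevalences are the human-coder rates observed in
such corpora (total affect 1.8% of words, positive 0.9%, negative 0.9%,
anxiety 0.3%, anger 0.1%, sadness 0.2%); default operating points are the
published per-category sensitivity/specificity of three dictionary
versions.  Vocabulary is synthetic pseudo-words, which removes linguistic
confounds from oracle tests.

Everything is driven by a single seed: the same seed reproduces the corpus,
labels and predictions byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .lexicon import (
    ContextRule,
    Document,
    Lexicon,
    LexiconEntry,
    Token,
    default_hierarchy,
)
from .metrics import ConfusionCounts
from .reference import SUBCATEGORIES, ReferenceLabel, rollup

__all__ = [
    "CATEGORY_ORDER",
    "DEFAULT_OPERATING_POINTS",
    "DEFAULT_PREVALENCE",
    "GeneratorConfig",
    "MiniLexiconFixture",
    "SyntheticTruth",
    "generate_corpus",
    "generate_lexicon",
    "generate_predictions",
    "generate_reference",
]

#: canonical category column order used by all boolean matrices
CATEGORY_ORDER: tuple[str, ...] = (
    "affect", "posemo", "negemo", "anx", "anger", "sad",
)

#: human-coder fraction of words per category (proportions, not percent)
DEFAULT_PREVALENCE: dict[str, float] = {
    "affect": 0.018,
    "posemo": 0.009,
    "negemo": 0.009,
    "anx": 0.003,
    "anger": 0.001,
    "sad": 0.002,
}

# how the positive-emotion mass is split across the three human positive
# subcategories (the machine hierarchy has no positive subcategories)
_POSITIVE_SPLIT: dict[str, float] = {
    "positive-feelings": 4.0 / 9.0,
    "optimism": 2.0 / 9.0,
    "other-positive": 3.0 / 9.0,
}

#: published per-category (sensitivity, specificity) of the three
#: dictionary versions used as default synthetic taggers
DEFAULT_OPERATING_POINTS: dict[str, dict[str, tuple[float, float]]] = {
    "2001": {
        "affect": (0.858, 0.967), "posemo": (0.873, 0.976),
        "negemo": (0.822, 0.990), "anx": (0.862, 0.998),
        "anger": (0.663, 0.998), "sad": (0.699, 0.997),
    },
    "2007": {
        "affect": (0.896, 0.955), "posemo": (0.913, 0.967),
        "negemo": (0.814, 0.987), "anx": (0.892, 0.997),
        "anger": (0.679, 0.998), "sad": (0.718, 0.997),
    },
    "2015": {
        "affect": (0.904, 0.955), "posemo": (0.928, 0.967),
        "negemo": (0.810, 0.988), "anx": (0.883, 0.997),
        "anger": (0.695, 0.999), "sad": (0.856, 0.997),
    },
}

# boolean rollup table: subcategory index -> category columns
_SUB_TO_CAT = np.zeros((len(SUBCATEGORIES), len(CATEGORY_ORDER)), dtype=bool)
for _i, _sub in enumerate(SUBCATEGORIES):
    for _c in rollup(_sub):
        _SUB_TO_CAT[_i, CATEGORY_ORDER.index(_c)] = True


@dataclass
class GeneratorConfig:
    """Conditions of one synthetic validation study.

    ``prevalence`` maps machine categories to the fraction of words human
    coders label with them (children must sum to at most the parent);
    ``operating_points`` maps tagger tag -> category -> (sens, spec).
    ``participant_sd`` switches on between-participant prevalence
    heterogeneity via a symmetric scaling drawn from a beta distribution.
    """

    seed: int
    n_participants: int = 63
    tokens_per_participant: int = 2631
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    operating_points: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_OPERATING_POINTS.items()
        }
    )
    emotion_vocab_size: int = 140
    nonemotion_vocab_size: int = 4000
    participant_sd: float | None = None

    def subcategory_probs(self) -> np.ndarray:
        """Per-token multinomial over the eight human subcategories."""
        prev = dict(self.prevalence)
        for key in CATEGORY_ORDER:
            prev.setdefault(key, 0.0)
        for key, v in prev.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"prevalence[{key!r}]={v} outside [0,1]")
        neg_sub = prev["anx"] + prev["anger"] + prev["sad"]
        if neg_sub > prev["negemo"] + 1e-12:
            raise ConfigError(
                "anxiety+anger+sadness prevalence exceeds negative emotion"
            )
        if prev["posemo"] + prev["negemo"] > prev["affect"] + 1e-12:
            raise ConfigError(
                "positive+negative prevalence exceeds total affect"
            )
        probs = dict.fromkeys(SUBCATEGORIES, 0.0)
        for sub, w in _POSITIVE_SPLIT.items():
            probs[sub] = prev["posemo"] * w
        probs["anxiety"] = prev["anx"]
        probs["anger"] = prev["anger"]
        probs["sadness"] = prev["sad"]
        probs["other-negative"] = prev["negemo"] - neg_sub
        emotion_mass = prev["affect"]
        probs["not-emotion"] = 1.0 - emotion_mass
        # any affect mass not claimed by posemo/negemo is not representable
        # in the single-label scheme; fold it into the two branches pro rata
        unclaimed = emotion_mass - prev["posemo"] - prev["negemo"]
        if unclaimed > 1e-12:
            raise ConfigError(
                "total-affect prevalence must equal positive + negative "
                "(single-label coding has no affect-only label)"
            )
        return np.array([probs[s] for s in SUBCATEGORIES])

    def validate(self) -> None:
        if self.n_participants < 1 or self.tokens_per_participant < 1:
            raise ConfigError("need ≥1 participant and ≥1 token each")
        self.subcategory_probs()
        for tagger, ops in self.operating_points.items():
            for cat, (s, sp) in ops.items():
                if not (0 <= s <= 1 and 0 <= sp <= 1):
                    raise ConfigError(
                        f"operating point ({s}, {sp}) for "
                        f"{tagger}/{cat} outside the unit square"
                    )


@dataclass
class SyntheticTruth:
    """Planted ground truth and per-tagger assignment logs."""

    config: GeneratorConfig
    participant_ids: np.ndarray  # str per token
    positions: np.ndarray  # int per token
    subcategory_codes: np.ndarray  # index into SUBCATEGORIES per token
    ref: np.ndarray  # bool (n_tokens, len(CATEGORY_ORDER))
    words: np.ndarray | None = None
    predictions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_tokens(self) -> int:
        return len(self.subcategory_codes)

    def realized_prevalence(self, category: str) -> float:
        return float(self.ref[:, CATEGORY_ORDER.index(category)].mean())

    def realized_counts(self, tagger: str, category: str) -> ConfusionCounts:
        j = CATEGORY_ORDER.index(category)
        ref = self.ref[:, j]
        pred = self.predictions[tagger][:, j]
        return ConfusionCounts(
            category,
            tp=int(np.count_nonzero(ref & pred)),
            fp=int(np.count_nonzero(~ref & pred)),
            fn=int(np.count_nonzero(ref & ~pred)),
            tn=int(np.count_nonzero(~ref & ~pred)),
        )

    def labels(self) -> tuple[ReferenceLabel, ...]:
        """Materialize the planted labels (not-emotion tokens carry none)."""
        not_emotion = SUBCATEGORIES.index("not-emotion")
        out = []
        for pid, pos, code in zip(
            self.participant_ids, self.positions, self.subcategory_codes
        ):
            if code != not_emotion:
                out.append(
                    ReferenceLabel(str(pid), int(pos), SUBCATEGORIES[code])
                )
        return tuple(out)


def generate_reference(config: GeneratorConfig) -> SyntheticTruth:
    """Draw planted per-token subcategory labels for the whole corpus.

    Each token independently receives one of the eight subcategories with
    the configured prevalences; with ``participant_sd`` set, each
    participant's emotion mass is scaled by a beta-distributed random
    effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = config.subcategory_probs()
    n_p, n_t = config.n_participants, config.tokens_per_participant
    pid_strings = np.array(
        [f"p{i:03d}" for i in range(n_p)], dtype=object
    )
    if config.participant_sd is None:
        codes = rng.choice(len(SUBCATEGORIES), size=n_p * n_t, p=probs)
    else:
        emotion = probs.copy()
        emotion[SUBCATEGORIES.index("not-emotion")] = 0.0
        mass = emotion.sum()
        # symmetric beta scaling of each participant's emotion mass,
        # mean 1, sd = participant_sd (in units of the mass)
        cv = config.participant_sd
        a = max((1.0 / cv**2 - 1.0) / 2.0, 0.5)
        scale = rng.beta(a, a, size=n_p) * 2.0  # mean 1
        chunks = []
        for i in range(n_p):
            p_i = emotion * scale[i]
            total = p_i.sum()
            if total >= 1.0:
                p_i = p_i / total * 0.99
                total = 0.99
            p_i[SUBCATEGORIES.index("not-emotion")] = 1.0 - total
            chunks.append(
                rng.choice(len(SUBCATEGORIES), size=n_t, p=p_i)
            )
        codes = np.concatenate(chunks)
    return SyntheticTruth(
        config=config,
        participant_ids=np.repeat(pid_strings, n_t),
        positions=np.tile(np.arange(n_t), n_p),
        subcategory_codes=codes,
        ref=_SUB_TO_CAT[codes],
    )


def _materialize_words(truth: SyntheticTruth, rng: np.random.Generator):
    cfg = truth.config
    n_sub = len(SUBCATEGORIES) - 1  # emotion subcategories
    per_sub = max(cfg.emotion_vocab_size // n_sub, 1)
    emo_vocab = {
        i: np.array(
            [f"{SUBCATEGORIES[i].replace('-', '')}w{k:03d}"
             for k in range(per_sub)]
        )
        for i in range(n_sub)
    }
    plain = np.array(
        [f"w{k:05d}" for k in range(cfg.nonemotion_vocab_size)]
    )
    words = plain[rng.integers(len(plain), size=truth.n_tokens)]
    for i in range(n_sub):
        mask = truth.subcategory_codes == i
        k = int(mask.sum())
        if k:
            words[mask] = emo_vocab[i][
                rng.integers(len(emo_vocab[i]), size=k)
            ]
    truth.words = words


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[tuple[Document, ...], tuple[ReferenceLabel, ...], SyntheticTruth]:
    """Generate documents, reference labels and the planted truth.

    Emotion tokens draw their surface from a subcategory-specific
    pseudo-word vocabulary, non-emotion tokens from a disjoint plain
    vocabulary; documents contain word tokens only.
    """
    truth = generate_reference(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x776F7264])
    )
    _materialize_words(truth, rng)
    docs = []
    n_t = config.tokens_per_participant
    for i in range(config.n_participants):
        lo = i * n_t
        pid = str(truth.participant_ids[lo])
        tokens = tuple(
            Token(surface=w, norm=w, position=j)
            for j, w in enumerate(truth.words[lo:lo + n_t])
        )
        docs.append(Document(pid, tokens))
    return tuple(docs), truth.labels(), truth


# ---------------------------------------------------------------------------
# synthetic taggers

_CHILDREN: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("negemo", ("anx", "anger", "sad")),
    ("affect", ("posemo", "negemo")),
)
_LEAVES: tuple[str, ...] = ("posemo", "anx", "anger", "sad")


def generate_predictions(
    truth: SyntheticTruth,
    tagger: str,
    operating_points: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate one tagger's per-token flags at dialed operating points.

    Leaf categories (positive emotion, anxiety, anger, sadness) are drawn
    from one shared uniform per token: a reference-positive token is
    flagged with probability sensitivity, a reference-negative one with
    probability 1 − specificity, and sibling false positives are
    comonotone — mirroring real dictionaries, where overlapping hits come
    from the same word, not independent coin flips.  A parent category is
    the union of its children plus an independent conditional top-up whose
    rate is calibrated against the empirical union counts, separately
    within the parent's reference-positive and reference-negative groups,
    so the parent's group-level sensitivity and specificity are unbiased
    for the dialed-in values while child ⇒ parent consistency holds.
    (An exact per-token parent marginal is infeasible whenever a child's
    operating point exceeds the parent's — consistency puts a floor under
    that child's branch — so the parent's point is honoured at the level a
    confusion table measures: the group rate.)  The result is stored in
    ``truth.predictions[tagger]`` and returned.
    """
    if operating_points is None:
        operating_points = truth.config.operating_points[tagger]
    if seed is None:
        seed = truth.config.seed
    # crc32 keeps the tagger-derived stream offset stable across processes
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(tagger.encode("utf-8"))])
    )
    n = truth.n_tokens
    col = {c: CATEGORY_ORDER.index(c) for c in CATEGORY_ORDER}
    pred: dict[str, np.ndarray] = {}
    u_leaf = rng.random(n)
    for c in _LEAVES:
        s, sp = operating_points[c]
        p = np.where(truth.ref[:, col[c]], s, 1.0 - sp)
        pred[c] = u_leaf < p
    for parent, children in _CHILDREN:
        s, sp = operating_points[parent]
        union = np.zeros(n, dtype=bool)
        for ch in children:
            union |= pred[ch]
        ref_parent = truth.ref[:, col[parent]]
        pred_parent = union.copy()
        draws = rng.random(n)
        for mask, target in ((ref_parent, s), (~ref_parent, 1.0 - sp)):
            n_group = int(mask.sum())
            if n_group == 0:
                continue
            already = int(union[mask].sum())
            room = n_group - already
            if room <= 0:
                continue
            rate = (target * n_group - already) / room
            rate = min(max(rate, 0.0), 1.0)
            pred_parent[mask] |= draws[mask] < rate
        pred[parent] = pred_parent
    matrix = np.column_stack([pred[c] for c in CATEGORY_ORDER])
    truth.predictions[tagger] = matrix
    return matrix


# ---------------------------------------------------------------------------
# mini-lexicon fixtures with exactly known end-to-end behaviour


@dataclass
class MiniLexiconFixture:
    """A small dictionary plus a paired corpus whose tag output is planted.

    ``planted_tags[d][i]`` is the category set the lexicon engine must
    produce for token ``i`` of document ``d``; confusion counts derived
    from the planted log equal the end-to-end pipeline's output exactly.
    """

    lexicon: Lexicon
    documents: tuple[Document, ...]
    labels: tuple[ReferenceLabel, ...]
    planted_tags: tuple[tuple[frozenset[str], ...], ...]

    def planted_confusion(self, category: str) -> ConfusionCounts:
        by_token = {
            (lab.participant_id, lab.position): lab.subcategory
            for lab in self.labels
        }
        tp = fp = fn = tn = 0
        for doc, tags in zip(self.documents, self.planted_tags):
            for tok, cats in zip(doc.tokens, tags):
                if tok.is_emoticon and not (
                    self.lexicon.count_emoticons_as_words
                ):
                    continue
                sub = by_token.get((doc.participant_id, tok.position))
                in_ref = category in (
                    rollup(sub) if sub is not None else frozenset()
                )
                in_pred = category in cats
                if in_ref and in_pred:
                    tp += 1
                elif in_pred:
                    fp += 1
                elif in_ref:
                    fn += 1
                else:
                    tn += 1
        return ConfusionCounts(category, tp=tp, fp=fp, fn=fn, tn=tn)


def generate_lexicon(
    seed: int,
    n_docs: int = 4,
    units_per_doc: int = 120,
) -> MiniLexiconFixture:
    """Build a mini-lexicon (exact words, a stem, a context rule, an
    emoticon) and a corpus realizing known confusion counts.

    The corpus is assembled from shuffled "units" — one or two adjacent
    tokens with a construction-time-known reference label and predicted
    category set — so end-to-end tagging must reproduce the planted log
    token for token.
    """
    if n_docs < 1 or units_per_doc < 10:
        raise ConfigError("need ≥1 document and ≥10 units per document")
    rng = np.random.default_rng(seed)
    hierarchy = default_hierarchy()
    entries = [
        LexiconEntry("gladly", frozenset({"posemo"})),
        LexiconEntry("cheer", frozenset({"posemo"})),
        LexiconEntry("dread", frozenset({"anx"})),
        LexiconEntry("fume", frozenset({"anger"})),
        LexiconEntry("wept", frozenset({"sad"})),
        LexiconEntry("bleak", frozenset({"negemo"})),
        LexiconEntry("zorm", frozenset({"sad"}), is_stem=True),
        LexiconEntry("muddl", frozenset({"anx", "sad"}), is_stem=True),
        LexiconEntry(":)", frozenset({"posemo"}), is_emoticon=True),
    ]
    rule = ContextRule(
        target="blike",
        conditions=((-1, frozenset({"i", "they", "will"})),),
        grant=frozenset({"posemo"}),
        suppress_default=True,
    )
    lex = Lexicon(
        version_tag=f"mini-{seed}",
        categories=hierarchy,
        entries=tuple(entries),
        context_rules=(rule,),
        count_emoticons_as_words=True,
    )
    expand = lex.expand

    # unit blueprints: (token surfaces, reference subcat per token,
    #                   planted predicted set per token), with weights
    pos = expand({"posemo"})
    none: frozenset[str] = frozenset()
    blueprints: list[tuple[tuple[str, ...], tuple[str | None, ...],
                           tuple[frozenset[str], ...], float]] = [
        # true positives on exact entries
        (("gladly",), ("positive-feelings",), (pos,), 0.05),
        (("dread",), ("anxiety",), (expand({"anx"}),), 0.04),
        (("fume",), ("anger",), (expand({"anger"}),), 0.02),
        (("wept",), ("sadness",), (expand({"sad"}),), 0.03),
        (("bleak",), ("other-negative",), (expand({"negemo"}),), 0.03),
        # stem hits: a true extension and an overmatch false positive
        (("zormed",), ("sadness",), (expand({"sad"}),), 0.03),
        (("zormle",), (None,), (expand({"sad"}),), 0.02),
        # multi-category stem
        (("muddled",), ("anxiety",), (expand({"anx", "sad"}),), 0.02),
        # false positives on exact entries
        (("cheer",), (None,), (pos,), 0.04),
        # false negatives: emotion words missing from the dictionary
        (("plornt",), ("sadness",), (none,), 0.03),
        (("skree",), ("optimism",), (none,), 0.03),
        # context rule: fires after a pronoun/auxiliary, suppressed after
        # anything else
        (("i", "blike"), (None, "positive-feelings"), (none, pos), 0.04),
        (("will", "blike"), (None, "other-positive"), (none, pos), 0.02),
        (("rock", "blike"), (None, None), (none, none), 0.03),
        # emoticon (counts as a word for this dictionary)
        ((":)",), ("positive-feelings",), (pos,), 0.02),
        # plain true negatives
        (("stone",), (None,), (none,), 0.25),
        (("table",), (None,), (none,), 0.30),
    ]
    weights = np.array([b[3] for b in blueprints])
    weights = weights / weights.sum()

    docs: list[Document] = []
    labels: list[ReferenceLabel] = []
    planted: list[tuple[frozenset[str], ...]] = []
    for d in range(n_docs):
        pid = f"fix{d:02d}"
        choice = rng.choice(len(blueprints), size=units_per_doc, p=weights)
        tokens: list[Token] = []
        doc_tags: list[frozenset[str]] = []
        pos_i = 0
        for u in choice:
            surfaces, subs, preds, _ = blueprints[u]
            for surface, sub, pred_set in zip(surfaces, subs, preds):
                is_emo = surface == ":)"
                tokens.append(
                    Token(surface, surface if not is_emo else surface,
                          pos_i, is_word=not is_emo, is_emoticon=is_emo)
                )
                if sub is not None:
                    labels.append(ReferenceLabel(pid, pos_i, sub))
                doc_tags.append(pred_set)
                pos_i += 1
        docs.append(Document(pid, tuple(tokens)))
        planted.append(tuple(doc_tags))
    return MiniLexiconFixture(
        lexicon=lex,
        documents=tuple(docs),
        labels=tuple(labels),
        planted_tags=tuple(planted),
    )
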