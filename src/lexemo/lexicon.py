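"""LIWC-style lexicon representation, tokenization and word-by-word tagging.

A :class:`Lexicon` maps words, word stems (prefix patterns such as
``stammer*``) and emoticons onto a hierarchy of emotion categories
(subcategories such as sadness nest inside negative emotion, which nests
inside total affect).  Tagging proceeds word by word: each token is compared
against the dictionary, every matching entry contributes its categories, and
a hit on a subcategory also counts toward every ancestor category.  Context
rules reproduce the newer-dictionary behaviour where a word such as "like"
only counts as emotion in specific syntactic contexts ("I like", "will
like").

Per-participant output is the percentage of a participant's words carrying
each category, the canonical word-count statistic of dictionary-based text
analysis.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    EmptyParticipantError,
    LexiconParseError,
    MalformedLexiconError,
)

__all__ = [
    "Category",
    "ContextRule",
    "Document",
    "Lexicon",
    "LexiconEntry",
    "TaggedCorpus",
    "Token",
    "DEFAULT_HIERARCHY",
    "category_percentages",
    "default_hierarchy",
    "match_token",
    "read_lexicon",
    "tag_corpus",
    "tokenize",
    "write_lexicon",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Category:
    """One node of the category hierarchy.

    ``parent`` is the id of the enclosing category, or ``None`` for a root
    (total affect in the default emotion hierarchy).
    """

    id: str
    name: str
    parent: str | None = None


@dataclass(frozen=True)
class LexiconEntry:
    """A dictionary entry: an exact word, a stem, or an emoticon.

    A stem entry matches any word of which ``pattern`` is a prefix
    (including the bare stem itself).  Emoticon entries match the raw
    surface of emoticon tokens exactly.
    """

    pattern: str
    categories: frozenset[str]
    is_stem: bool = False
    is_emoticon: bool = False

    def __post_init__(self):
        if not self.pattern:
            raise MalformedLexiconError("entry pattern must be nonempty")
        if not self.categories:
            raise MalformedLexiconError(
                f"entry {self.pattern!r} must map to at least one category"
            )
        if self.is_stem and self.is_emoticon:
            raise MalformedLexiconError(
                f"entry {self.pattern!r} cannot be both stem and emoticon"
            )


@dataclass(frozen=True)
class ContextRule:
    """Context-dependent categorisation of a single target word.

    ``conditions`` is a tuple of ``(offset, norms)`` pairs; the rule fires
    when, for at least one pair, the token at ``position + offset`` exists
    and its normalized form is in ``norms``.  Offsets are bounded to a ±2
    token window.  When ``suppress_default`` is true and no rule for the
    target fires, the target word receives no categories at all (the
    2015-style "like" behaviour); otherwise unfired rules fall back to
    ordinary dictionary lookup.
    """

    target: str
    conditions: tuple[tuple[int, frozenset[str]], ...]
    grant: frozenset[str]
    suppress_default: bool = True

    def __post_init__(self):
        for offset, norms in self.conditions:
            if offset == 0 or abs(offset) > 2:
                raise MalformedLexiconError(
                    f"context rule for {self.target!r}: offset {offset} "
                    "outside the ±2 window"
                )
            if not norms:
                raise MalformedLexiconError(
                    f"context rule for {self.target!r}: empty condition set"
                )

    def fires(self, tokens: Sequence["Token"], position: int) -> bool:
        for offset, norms in self.conditions:
            j = position + offset
            if 0 <= j < len(tokens) and tokens[j].norm in norms:
                return True
        return False


@dataclass(frozen=True)
class Token:
    surface: str
    norm: str
    position: int
    is_word: bool = True
    is_emoticon: bool = False

    def __post_init__(self):
        if self.is_word and self.is_emoticon:
            raise ValueError("a token is either a word or an emoticon")
        if self.is_word and not self.norm:
            raise ValueError("word token with empty normalized form")


@dataclass(frozen=True)
class Document:
    participant_id: str
    tokens: tuple[Token, ...]

    def __post_init__(self):
        for i, tok in enumerate(self.tokens):
            if tok.position != i:
                raise ValueError(
                    f"document {self.participant_id}: token positions must "
                    f"increase from 0 (got {tok.position} at index {i})"
                )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Lexicon:
    """A versioned dictionary plus its category hierarchy and context rules."""

    version_tag: str
    categories: tuple[Category, ...]
    entries: tuple[LexiconEntry, ...]
    context_rules: tuple[ContextRule, ...] = ()
    count_emoticons_as_words: bool = False

    # lazily-built lookup index
    _index: "_MatchIndex | None" = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        self.validate()

    # -- hierarchy ----------------------------------------------------------

    def category_table(self) -> dict[str, Category]:
        return {c.id: c for c in self.categories}

    def ancestors(self, category_id: str) -> frozenset[str]:
        """All strict ancestors of a category, root-most last."""
        table = self.category_table()
        out: list[str] = []
        seen = {category_id}
        cur = table[category_id].parent
        while cur is not None:
            if cur in seen:
                raise MalformedLexiconError(
                    f"cyclic category hierarchy at {cur!r}"
                )
            seen.add(cur)
            out.append(cur)
            cur = table[cur].parent
        return frozenset(out)

    def expand(self, category_ids: Iterable[str]) -> frozenset[str]:
        """Close a category set under parent expansion."""
        out: set[str] = set()
        for cid in category_ids:
            out.add(cid)
            out.update(self.ancestors(cid))
        return frozenset(out)

    def validate(self) -> None:
        table = self.category_table()
        if len(table) != len(self.categories):
            raise MalformedLexiconError("duplicate category id")
        for c in self.categories:
            if c.parent is not None and c.parent not in table:
                raise MalformedLexiconError(
                    f"category {c.id!r} has unknown parent {c.parent!r}"
                )
        for c in self.categories:
            self.ancestors(c.id)  # raises on cycles
        seen: set[tuple[str, bool]] = set()
        for e in self.entries:
            key = (e.pattern, e.is_stem)
            if key in seen:
                raise MalformedLexiconError(
                    f"duplicate entry {e.pattern!r} (stem={e.is_stem})"
                )
            seen.add(key)
            for cid in e.categories:
                if cid not in table:
                    raise MalformedLexiconError(
                        f"entry {e.pattern!r} references unknown category "
                        f"{cid!r}"
                    )
        for r in self.context_rules:
            for cid in r.grant:
                if cid not in table:
                    raise MalformedLexiconError(
                        f"context rule {r.target!r} grants unknown category "
                        f"{cid!r}"
                    )

    # -- matching index ------------------------------------------------------

    def index(self) -> "_MatchIndex":
        if self._index is None:
            self._index = _MatchIndex(self)
        return self._index


class _MatchIndex:
    """Precompiled lookup tables for fast word-by-word matching."""

    def __init__(self, lex: Lexicon):
        self.exact: dict[str, frozenset[str]] = {}
        self.stems: dict[str, frozenset[str]] = {}
        self.emoticons: dict[str, frozenset[str]] = {}
        for e in lex.entries:
            cats = lex.expand(e.categories)
            if e.is_emoticon:
                self.emoticons[e.pattern] = cats
            elif e.is_stem:
                self.stems[e.pattern] = cats
            else:
                self.exact[e.pattern] = cats
        self.max_stem_len = max((len(p) for p in self.stems), default=0)
        self.rules: dict[str, list[ContextRule]] = {}
        self.rule_grants: dict[ContextRule, frozenset[str]] = {}
        for r in lex.context_rules:
            self.rules.setdefault(r.target, []).append(r)
            self.rule_grants[r] = lex.expand(r.grant)


# ---------------------------------------------------------------------------
# tokenization

# letters (no digits/underscore) with optional internal apostrophes;
# hyphenated compounds split because '-' is outside the class
_WORD_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*", re.UNICODE)


def _normalize(word: str) -> str:
    return unicodedata.normalize("NFC", word).casefold()


def tokenize(
    text: str, emoticons: Iterable[str] = ()
) -> tuple[Token, ...]:
    """Split raw text into word and emoticon tokens.

    Words are maximal runs of letters and internal apostrophes after Unicode
    case-folding; hyphenated forms split at the hyphen; pure punctuation and
    whitespace yield no tokens.  A whitespace-delimited chunk equal to a
    member of ``emoticons`` becomes a single emoticon token.
    """
    emoticon_set = set(emoticons)
    tokens: list[Token] = []
    pos = 0
    for chunk in text.replace("’", "'").split():
        if chunk in emoticon_set:
            tokens.append(
                Token(chunk, chunk, pos, is_word=False, is_emoticon=True)
            )
            pos += 1
            continue
        for m in _WORD_RE.finditer(chunk):
            surface = m.group(0)
            tokens.append(Token(surface, _normalize(surface), pos))
            pos += 1
    return tuple(tokens)


# ---------------------------------------------------------------------------
# matching


def match_token(lexicon: Lexicon, doc: Document, position: int) -> frozenset[str]:
    """Categories matched by the token at ``position``, closed upward.

    Context rules for the token's normalized form are evaluated first; when
    any fires, the union of firing grants is returned.  When none fires and
    a rule declares ``suppress_default``, the token yields no categories.
    Otherwise an exact entry beats all stems, and among stems the longest
    prefix wins, its full category set applying.
    """
    idx = lexicon.index()
    tok = doc.tokens[position]
    if tok.is_emoticon:
        return idx.emoticons.get(tok.surface, frozenset())

    rules = idx.rules.get(tok.norm)
    if rules:
        fired = [r for r in rules if r.fires(doc.tokens, position)]
        if fired:
            out: set[str] = set()
            for r in fired:
                out |= idx.rule_grants[r]
            return frozenset(out)
        if any(r.suppress_default for r in rules):
            return frozenset()

    hit = idx.exact.get(tok.norm)
    if hit is not None:
        return hit
    # longest-prefix stem match
    limit = min(len(tok.norm), idx.max_stem_len)
    for k in range(limit, 0, -1):
        hit = idx.stems.get(tok.norm[:k])
        if hit is not None:
            return hit
    return frozenset()


@dataclass
class TaggedCorpus:
    """Per-token predicted category sets for a document collection."""

    lexicon_tag: str
    documents: tuple[Document, ...]
    tags: tuple[tuple[frozenset[str], ...], ...]
    count_emoticons_as_words: bool = False

    def iter_tokens(self):
        for doc, doc_tags in zip(self.documents, self.tags):
            for tok, cats in zip(doc.tokens, doc_tags):
                yield doc.participant_id, tok, cats

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pid, tok.position, tok.surface, tok.norm,
             ",".join(sorted(cats)))
            for pid, tok, cats in self.iter_tokens()
        ]
        return pd.DataFrame(
            rows,
            columns=["participant_id", "position", "surface", "norm",
                     "categories"],
        )


def tag_corpus(lexicon: Lexicon, docs: Sequence[Document]) -> TaggedCorpus:
    """Tag every token of every document; deterministic given its inputs."""
    if not docs:
        raise ValueError("empty document collection")
    tags = tuple(
        tuple(match_token(lexicon, doc, i) for i in range(len(doc)))
        for doc in docs
    )
    return TaggedCorpus(
        lexicon.version_tag, tuple(docs), tags,
        lexicon.count_emoticons_as_words,
    )


def category_percentages(
    tagged: TaggedCorpus, categories: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-participant percentage of countable tokens carrying each category.

    The denominator is the participant's word tokens, plus emoticon tokens
    when the lexicon counts emoticons as words.  Raises
    :class:`EmptyParticipantError` for a participant with denominator zero.
    """
    if categories is None:
        cats: list[str] = sorted(
            {c for _, _, cs in tagged.iter_tokens() for c in cs}
        )
    else:
        cats = list(categories)
    counts: dict[str, dict[str, int]] = {}
    denoms: dict[str, int] = {}
    for pid, tok, cset in tagged.iter_tokens():
        countable = tok.is_word or (
            tok.is_emoticon and tagged.count_emoticons_as_words
        )
        if not countable:
            continue
        denoms[pid] = denoms.get(pid, 0) + 1
        row = counts.setdefault(pid, {})
        for c in cset:
            row[c] = row.get(c, 0) + 1
    for doc in tagged.documents:
        if denoms.get(doc.participant_id, 0) == 0:
            raise EmptyParticipantError(
                f"participant {doc.participant_id!r} has no countable tokens"
            )
    data = {
        pid: [100.0 * counts.get(pid, {}).get(c, 0) / denoms[pid]
              for c in cats]
        for pid in denoms
    }
    out = pd.DataFrame.from_dict(data, orient="index", columns=cats)
    out.index.name = "participant_id"
    return out.sort_index()


# ---------------------------------------------------------------------------
# default emotion hierarchy

DEFAULT_HIERARCHY: tuple[Category, ...] = (
    Category("affect", "Total Affect", None),
    Category("posemo", "Positive Emotion", "affect"),
    Category("negemo", "Negative Emotion", "affect"),
    Category("anx", "Anxiety", "negemo"),
    Category("anger", "Anger", "negemo"),
    Category("sad", "Sadness", "negemo"),
)


def default_hierarchy() -> tuple[Category, ...]:
    """Total affect over positive/negative emotion, with anxiety, anger and
    sadness nested under negative emotion."""
    return DEFAULT_HIERARCHY


# ---------------------------------------------------------------------------
# dictionary file dialect
#
#   ! lexemo-dictionary v1          magic line (required)
#   !version <tag>                  directives
#   !emoticons_count_as_words true
#   %                               category table, TAB-separated:
#   affect<TAB>Total Affect<TAB>-   id, display name, parent id ('-' = root)
#   %                               entry lines, whitespace-separated:
#   cried sad                       pattern [*-suffix = stem] categories...
#   :) posemo                       non-letter pattern = emoticon
#   %rules                          optional context-rule section:
#   like<TAB>-1:i|they|will<TAB>posemo<TAB>suppress

_MAGIC = "! lexemo-dictionary v1"


def _pattern_is_word(pattern: str) -> bool:
    m = _WORD_RE.fullmatch(pattern)
    return m is not None


def read_lexicon(path: str | Path) -> Lexicon:
    """Parse a dictionary file in the documented dialect."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise LexiconParseError(f"missing magic header {_MAGIC!r}", line=1)
    version_tag = "unversioned"
    emoticons_count = False
    categories: list[Category] = []
    entries: list[LexiconEntry] = []
    rules: list[ContextRule] = []
    section = "directives"
    known: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() == "%":
            if section == "directives":
                section = "categories"
            elif section == "categories":
                section = "entries"
            else:
                raise LexiconParseError("unexpected '%'", line=lineno)
            continue
        if line.strip() == "%rules":
            if section != "entries":
                raise LexiconParseError(
                    "'%rules' must follow the entry section", line=lineno
                )
            section = "rules"
            continue
        try:
            if section == "directives":
                if not line.startswith("!"):
                    raise LexiconParseError(
                        "expected '!' directive or '%'", line=lineno
                    )
                key, _, value = line[1:].partition(" ")
                if key == "version":
                    version_tag = value.strip()
                elif key == "emoticons_count_as_words":
                    emoticons_count = value.strip().lower() == "true"
                else:
                    raise LexiconParseError(
                        f"unknown directive {key!r}", line=lineno
                    )
            elif section == "categories":
                parts = line.split("\t")
                if len(parts) != 3:
                    raise LexiconParseError(
                        "category line needs 3 TAB-separated fields "
                        "(id, name, parent)", line=lineno
                    )
                cid, name, parent = (p.strip() for p in parts)
                categories.append(
                    Category(cid, name, None if parent == "-" else parent)
                )
                known.add(cid)
            elif section == "entries":
                parts = line.split()
                if len(parts) < 2:
                    raise LexiconParseError(
                        "entry line needs a pattern and ≥1 category",
                        line=lineno,
                    )
                pattern, cats = parts[0], parts[1:]
                for c in cats:
                    if c not in known:
                        raise LexiconParseError(
                            f"unknown category {c!r} in entry "
                            f"{pattern!r}", line=lineno
                        )
                is_stem = pattern.endswith("*")
                if is_stem:
                    pattern = pattern[:-1]
                if not pattern:
                    raise LexiconParseError("empty pattern", line=lineno)
                is_emoticon = not is_stem and not _pattern_is_word(pattern)
                entries.append(
                    LexiconEntry(
                        pattern if is_emoticon else _normalize(pattern),
                        frozenset(cats),
                        is_stem=is_stem,
                        is_emoticon=is_emoticon,
                    )
                )
            else:  # rules
                parts = line.split("\t")
                if len(parts) != 4:
                    raise LexiconParseError(
                        "rule line needs 4 TAB-separated fields "
                        "(target, conditions, grants, mode)", line=lineno
                    )
                target, conds_s, grants_s, mode = (
                    p.strip() for p in parts
                )
                conds = []
                for piece in conds_s.split(";"):
                    off_s, _, norms_s = piece.partition(":")
                    try:
                        off = int(off_s)
                    except ValueError:
                        raise LexiconParseError(
                            f"bad condition offset {off_s!r}", line=lineno
                        ) from None
                    norms = frozenset(
                        _normalize(w) for w in norms_s.split("|") if w
                    )
                    conds.append((off, norms))
                grants = frozenset(
                    g for g in grants_s.split(",") if g
                )
                for g in grants:
                    if g not in known:
                        raise LexiconParseError(
                            f"unknown category {g!r} in rule "
                            f"{target!r}", line=lineno
                        )
                if mode not in ("suppress", "fallback"):
                    raise LexiconParseError(
                        f"rule mode must be 'suppress' or 'fallback', "
                        f"got {mode!r}", line=lineno
                    )
                rules.append(
                    ContextRule(
                        _normalize(target),
                        tuple(conds),
                        grants,
                        suppress_default=(mode == "suppress"),
                    )
                )
        except MalformedLexiconError as exc:
            raise LexiconParseError(str(exc), line=lineno) from exc
    if section in ("directives", "categories"):
        raise LexiconParseError(
            "file ended before the entry section", line=len(lines)
        )
    try:
        return Lexicon(
            version_tag=version_tag,
            categories=tuple(categories),
            entries=tuple(entries),
            context_rules=tuple(rules),
            count_emoticons_as_words=emoticons_count,
        )
    except MalformedLexiconError as exc:
        raise LexiconParseError(str(exc)) from exc


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Serialize a lexicon; ``read_lexicon(write_lexicon(L)) == L``."""
    out: list[str] = [_MAGIC]
    out.append(f"!version {lexicon.version_tag}")
    out.append(
        "!emoticons_count_as_words "
        + ("true" if lexicon.count_emoticons_as_words else "false")
    )
    out.append("%")
    for c in lexicon.categories:
        out.append(f"{c.id}\t{c.name}\t{c.parent if c.parent else '-'}")
    out.append("%")
    for e in lexicon.entries:
        pattern = e.pattern + "*" if e.is_stem else e.pattern
        out.append(f"{pattern} {' '.join(sorted(e.categories))}")
    if lexicon.context_rules:
        out.append("%rules")
        for r in lexicon.context_rules:
            conds = ";".join(
                f"{off}:{'|'.join(sorted(norms))}"
                for off, norms in r.conditions
            )
            mode = "suppress" if r.suppress_default else "fallback"
            out.append(
                f"{r.target}\t{conds}\t{','.join(sorted(r.grant))}\t{mode}"
            )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
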