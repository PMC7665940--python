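"""Independent brute-force oracles and random-instance generators.

The scanner here re-derives token matching from the documented semantics by
direct equality/prefix comparison over every entry, without using any of
the library's lookup machinery, so it can stand as an independent check of
the engine.
"""

from __future__ import annotations

import numpy as np

from lexemo.lexicon import (
    ContextRule,
    Document,
    Lexicon,
    LexiconEntry,
    Token,
    default_hierarchy,
)

CAT_IDS = tuple(c.id for c in default_hierarchy())


def _expand(cats, table):
    out = set()
    for c in cats:
        cur = c
        while cur is not None:
            out.add(cur)
            cur = table[cur].parent
    return frozenset(out)


def brute_force_match(lex: Lexicon, doc: Document, pos: int) -> frozenset:
    """Entry-by-entry scanner implementing the documented precedence:
    context rules first, exact entries over stems, longest stem wins."""
    table = {c.id: c for c in lex.categories}
    tok = doc.tokens[pos]
    if tok.is_emoticon:
        for e in lex.entries:
            if e.is_emoticon and e.pattern == tok.surface:
                return _expand(e.categories, table)
        return frozenset()
    rules = [r for r in lex.context_rules if r.target == tok.norm]
    if rules:
        granted: set[str] = set()
        fired = False
        for r in rules:
            hit = any(
                0 <= pos + off < len(doc.tokens)
                and doc.tokens[pos + off].norm in norms
                for off, norms in r.conditions
            )
            if hit:
                fired = True
                granted |= set(r.grant)
        if fired:
            return _expand(granted, table)
        if any(r.suppress_default for r in rules):
            return frozenset()
    exact = [
        e for e in lex.entries
        if not e.is_stem and not e.is_emoticon and e.pattern == tok.norm
    ]
    if exact:
        cats: set[str] = set()
        for e in exact:
            cats |= set(e.categories)
        return _expand(cats, table)
    stems = [
        e for e in lex.entries
        if e.is_stem and tok.norm.startswith(e.pattern)
    ]
    if stems:
        best = max(stems, key=lambda e: len(e.pattern))
        return _expand(best.categories, table)
    return frozenset()


_ALPHABET = "abz"


def _random_word(rng: np.random.Generator, lo=1, hi=6) -> str:
    k = int(rng.integers(lo, hi + 1))
    return "".join(
        _ALPHABET[i] for i in rng.integers(len(_ALPHABET), size=k)
    )


def random_lexicon(rng: np.random.Generator, max_entries: int = 50) -> Lexicon:
    """A random mini-lexicon over the default hierarchy, with stems,
    multi-category entries, an emoticon and sometimes a context rule."""
    seen: set[tuple[str, bool]] = set()
    entries: list[LexiconEntry] = []
    n = int(rng.integers(1, max_entries + 1))
    while len(entries) < n:
        pattern = _random_word(rng, 2, 5)
        is_stem = bool(rng.random() < 0.4)
        if (pattern, is_stem) in seen:
            continue
        seen.add((pattern, is_stem))
        k = 1 + int(rng.random() < 0.2)
        cats = frozenset(
            rng.choice(CAT_IDS, size=k, replace=False).tolist()
        )
        entries.append(LexiconEntry(pattern, cats, is_stem=is_stem))
    if rng.random() < 0.5:
        entries.append(
            LexiconEntry(":)", frozenset({"posemo"}), is_emoticon=True)
        )
    rules = ()
    if rng.random() < 0.5:
        offsets = [o for o in (-2, -1, 1, 2) if rng.random() < 0.5] or [-1]
        conds = tuple(
            (o, frozenset(_random_word(rng, 1, 3) for _ in range(3)))
            for o in offsets
        )
        rules = (
            ContextRule(
                target=_random_word(rng, 2, 4),
                conditions=conds,
                grant=frozenset({str(rng.choice(CAT_IDS))}),
                suppress_default=bool(rng.random() < 0.7),
            ),
        )
    return Lexicon(
        version_tag=f"rand-{rng.integers(1 << 30)}",
        categories=default_hierarchy(),
        entries=tuple(entries),
        context_rules=rules,
        count_emoticons_as_words=bool(rng.random() < 0.5),
    )


def random_document(
    rng: np.random.Generator, max_tokens: int = 500
) -> Document:
    n = int(rng.integers(1, max_tokens + 1))
    tokens = []
    for i in range(n):
        if rng.random() < 0.03:
            tokens.append(Token(":)", ":)", i, is_word=False,
                                is_emoticon=True))
        else:
            w = _random_word(rng)
            tokens.append(Token(w, w, i))
    return Document("r", tuple(tokens))
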