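"""Tokenizer, matcher, percentages and dictionary-file round trips."""

import numpy as np
import pytest

from lexemo.errors import (
    EmptyParticipantError,
    LexiconParseError,
    MalformedLexiconError,
)
from lexemo.lexicon import (
    Document,
    Lexicon,
    LexiconEntry,
    category_percentages,
    default_hierarchy,
    match_token,
    read_lexicon,
    tag_corpus,
    tokenize,
    write_lexicon,
)

from oracles import brute_force_match, random_document, random_lexicon


def doc_of(text: str, emoticons=(":)",)) -> Document:
    return Document("p", tokenize(text, emoticons=emoticons))


class TestTokenize:
    def test_empty_text_yields_no_tokens(self):
        assert tokenize("") == ()
        assert tokenize("   ... !!! 123") == ()

    @pytest.mark.parametrize(
        "text,norms",
        [
            ("stammered, stammering.", ["stammered", "stammering"]),
            ("I LIKE you", ["i", "like", "you"]),
            ("well-being", ["well", "being"]),  # hyphens split
            ("don't cry", ["don't", "cry"]),
            ("Crying… so über-sad", ["crying", "so", "über", "sad"]),
        ],
    )
    def test_words_are_letter_runs_after_casefolding(self, text, norms):
        assert [t.norm for t in tokenize(text)] == norms

    def test_emoticons_become_emoticon_tokens(self):
        toks = tokenize("I like you :)", emoticons=[":)"])
        assert [t.norm for t in toks] == ["i", "like", "you", ":)"]
        assert [t.is_emoticon for t in toks] == [False] * 3 + [True]
        assert [t.position for t in toks] == [0, 1, 2, 3]

    def test_unknown_emoticon_is_just_punctuation(self):
        assert tokenize("fine :(", emoticons=[":)"]) == tokenize(
            "fine", emoticons=[":)"]
        )


class TestMatchToken:
    def test_subcategory_hit_expands_to_ancestors(self, mini_lexicon):
        doc = doc_of("she cried today")
        assert match_token(mini_lexicon, doc, 1) == {
            "sad", "negemo", "affect"
        }

    def test_stem_matches_extended_forms(self, mini_lexicon):
        doc = doc_of("he stammered badly")
        assert match_token(mini_lexicon, doc, 1) == {"negemo", "affect"}

    def test_stem_matches_the_bare_stem_itself(self, mini_lexicon):
        doc = doc_of("so sad")
        assert match_token(mini_lexicon, doc, 1) == {
            "sad", "negemo", "affect"
        }

    def test_exact_entry_overrides_stem(self, mini_lexicon):
        # "saddle" is an exact posemo entry even though "sad*" also matches
        doc = doc_of("the saddle broke")
        assert match_token(mini_lexicon, doc, 1) == {"posemo", "affect"}

    def test_longest_stem_wins(self):
        lex = Lexicon(
            "t", default_hierarchy(),
            (
                LexiconEntry("sa", frozenset({"posemo"}), is_stem=True),
                LexiconEntry("sad", frozenset({"sad"}), is_stem=True),
            ),
        )
        doc = doc_of("sadness sand")
        assert match_token(lex, doc, 0) == {"sad", "negemo", "affect"}
        assert match_token(lex, doc, 1) == {"posemo", "affect"}

    def test_no_match_yields_empty_set(self, mini_lexicon):
        doc = doc_of("completely neutral words")
        assert match_token(mini_lexicon, doc, 0) == frozenset()

    @pytest.mark.parametrize(
        "text,pos,expect_hit",
        [
            ("i like it", 1, True),
            ("they like it", 1, True),
            ("will like it", 1, True),
            ("it looks like rain", 2, False),
            ("like it or not", 0, False),  # no left neighbor
        ],
    )
    def test_context_rule_gates_like(self, mini_lexicon, text, pos,
                                     expect_hit):
        doc = doc_of(text)
        got = match_token(mini_lexicon, doc, pos)
        assert got == ({"posemo", "affect"} if expect_hit else frozenset())

    def test_emoticon_entry_matches_emoticon_token(self, mini_lexicon):
        doc = doc_of("so happy :)")
        assert match_token(mini_lexicon, doc, 2) == {"posemo", "affect"}

    def test_multi_category_entry_counts_each_once(self):
        lex = Lexicon(
            "t", default_hierarchy(),
            (LexiconEntry("torn", frozenset({"anx", "sad"})),),
        )
        got = match_token(lex, doc_of("torn"), 0)
        assert got == {"anx", "sad", "negemo", "affect"}

    def test_unknown_category_rejected_at_construction(self):
        with pytest.raises(MalformedLexiconError):
            Lexicon(
                "t", default_hierarchy(),
                (LexiconEntry("x", frozenset({"nope"})),),
            )


class TestOracleEquivalence:
    def test_matches_bruteforce_scanner_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            lex = random_lexicon(rng)
            doc = random_document(rng, max_tokens=200)
            for i in range(len(doc)):
                assert match_token(lex, doc, i) == brute_force_match(
                    lex, doc, i
                ), (lex.entries, doc.tokens[i])


class TestTagCorpus:
    def test_counts_and_determinism(self, mini_lexicon):
        docs = [doc_of("happy happy cried plain"), doc_of("nothing here")]
        t1 = tag_corpus(mini_lexicon, docs)
        t2 = tag_corpus(mini_lexicon, docs)
        assert t1.tags == t2.tags
        assert sum("posemo" in c for c in t1.tags[0]) == 2
        assert all(c == frozenset() for c in t1.tags[1])

    def test_hierarchy_conservation(self, mini_lexicon):
        rng = np.random.default_rng(5)
        doc = random_document(rng, max_tokens=300)
        tags = tag_corpus(mini_lexicon, [doc]).tags[0]
        table = {c.id: c for c in mini_lexicon.categories}
        for cat in table:
            parent = table[cat].parent
            if parent is None:
                continue
            child_n = sum(cat in s for s in tags)
            parent_n = sum(parent in s for s in tags)
            assert child_n <= parent_n

    def test_adding_an_entry_never_decreases_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lex = random_lexicon(rng, max_entries=20)
            doc = random_document(rng, max_tokens=150)
            extra = LexiconEntry("zz", frozenset({"anger"}), is_stem=True)
            if any(e.pattern == "zz" and e.is_stem for e in lex.entries):
                continue
            bigger = Lexicon(
                lex.version_tag, lex.categories,
                lex.entries + (extra,), lex.context_rules,
                lex.count_emoticons_as_words,
            )
            before = tag_corpus(lex, [doc]).tags[0]
            after = tag_corpus(bigger, [doc]).tags[0]
            for cat in ("affect", "posemo", "negemo", "anx", "anger", "sad"):
                assert (
                    sum(cat in s for s in before)
                    <= sum(cat in s for s in after)
                )


class TestCategoryPercentages:
    def test_simple_fraction(self, mini_lexicon):
        words = ["happy"] + ["plain"] * 99
        tagged = tag_corpus(mini_lexicon, [doc_of(" ".join(words))])
        pct = category_percentages(tagged, ["posemo", "affect"])
        assert pct.loc["p", "posemo"] == pytest.approx(1.0)

    def test_all_tokens_in_category_gives_100(self, mini_lexicon):
        tagged = tag_corpus(mini_lexicon, [doc_of("happy happy happy")])
        pct = category_percentages(tagged, ["affect"])
        assert pct.loc["p", "affect"] == 100.0

    def test_child_bounded_by_parent(self, mini_lexicon):
        rng = np.random.default_rng(7)
        doc = Document("p", random_document(rng).tokens)
        tagged = tag_corpus(mini_lexicon, [doc])
        pct = category_percentages(
            tagged, ["affect", "posemo", "negemo", "sad"]
        )
        row = pct.loc["p"]
        assert 0 <= row["sad"] <= row["negemo"] <= row["affect"] <= 100
        assert row["posemo"] <= row["affect"]

    def test_empty_participant_is_an_error(self, mini_lexicon):
        empty = Document("q", ())
        tagged = tag_corpus(mini_lexicon, [doc_of("fine"), empty])
        with pytest.raises(EmptyParticipantError):
            category_percentages(tagged)

    def test_emoticon_denominator_flag(self):
        entries = (LexiconEntry(":)", frozenset({"posemo"}),
                   is_emoticon=True),)
        with_emo = Lexicon("a", default_hierarchy(), entries,
                           count_emoticons_as_words=True)
        without = Lexicon("b", default_hierarchy(), entries,
                          count_emoticons_as_words=False)
        doc = doc_of("one two three :)")
        pct_with = category_percentages(
            tag_corpus(with_emo, [doc]), ["posemo"]
        )
        pct_without = category_percentages(
            tag_corpus(without, [doc]), ["posemo"]
        )
        assert pct_with.loc["p", "posemo"] == pytest.approx(25.0)
        assert pct_without.loc["p", "posemo"] == pytest.approx(0.0)


class TestDictionaryFiles:
    def test_round_trip_identity(self, mini_lexicon, tmp_path):
        path = tmp_path / "mini.dic"
        write_lexicon(mini_lexicon, path)
        assert read_lexicon(path) == mini_lexicon

    def test_round_trip_random_lexicons(self, tmp_path):
        rng = np.random.default_rng(3)
        for i in range(10):
            lex = random_lexicon(rng)
            path = tmp_path / f"r{i}.dic"
            write_lexicon(lex, path)
            assert read_lexicon(path) == lex

    def test_stem_entry_line_parses(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text(
            "! lexemo-dictionary v1\n!version t\n%\n"
            "affect\tTotal Affect\t-\n"
            "negemo\tNegative Emotion\taffect\n"
            "%\nstammer* negemo\n",
            encoding="utf-8",
        )
        lex = read_lexicon(path)
        (entry,) = lex.entries
        assert entry.is_stem and entry.pattern == "stammer"
        assert entry.categories == {"negemo"}

    def test_unknown_category_names_the_line(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text(
            "! lexemo-dictionary v1\n%\naffect\tA\t-\n%\nword nocat\n",
            encoding="utf-8",
        )
        with pytest.raises(LexiconParseError, match="line 5"):
            read_lexicon(path)

    def test_duplicate_entry_rejected(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text(
            "! lexemo-dictionary v1\n%\naffect\tA\t-\n%\n"
            "word affect\nword affect\n",
            encoding="utf-8",
        )
        with pytest.raises(LexiconParseError):
            read_lexicon(path)

    def test_missing_magic_header(self, tmp_path):
        path = tmp_path / "d.dic"
        path.write_text("%\naffect\tA\t-\n%\n", encoding="utf-8")
        with pytest.raises(LexiconParseError, match="line 1"):
            read_lexicon(path)
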