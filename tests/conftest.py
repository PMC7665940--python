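import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lexemo.lexicon import (
    ContextRule,
    Lexicon,
    LexiconEntry,
    default_hierarchy,
)


@pytest.fixture
def mini_lexicon() -> Lexicon:
    """A handcrafted dictionary exercising every entry kind: exact words,
    a stem, a context-gated word and an emoticon."""
    return Lexicon(
        version_tag="mini-2015",
        categories=default_hierarchy(),
        entries=(
            LexiconEntry("cried", frozenset({"sad"})),
            LexiconEntry("happy", frozenset({"posemo"})),
            LexiconEntry("worried", frozenset({"anx"})),
            LexiconEntry("stammer", frozenset({"negemo"}), is_stem=True),
            LexiconEntry("sad", frozenset({"sad"}), is_stem=True),
            # exact entry coexisting with the "sad*" stem
            LexiconEntry("saddle", frozenset({"posemo"})),
            LexiconEntry(":)", frozenset({"posemo"}), is_emoticon=True),
        ),
        context_rules=(
            ContextRule(
                target="like",
                conditions=(
                    (-1, frozenset({"i", "they", "we", "you", "will"})),
                ),
                grant=frozenset({"posemo"}),
                suppress_default=True,
            ),
        ),
        count_emoticons_as_words=True,
    )
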