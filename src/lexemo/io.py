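"""Plain-text corpus, reference and tag-table input/output.

Three TSV dialects, all UTF-8 with a header row:

* corpus:    ``participant_id<TAB>text`` (one row per participant), or a
  directory of ``<participant_id>.txt`` files;
* reference: ``participant_id<TAB>position<TAB>surface<TAB>subcategory``;
* tagged:    ``participant_id<TAB>position<TAB>surface<TAB>norm<TAB>categories``
  with categories comma-joined.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError
from .lexicon import Document, TaggedCorpus, tokenize
from .reference import ReferenceLabel

__all__ = [
    "read_corpus",
    "read_reference",
    "write_corpus",
    "write_reference",
    "write_tagged",
]


def read_corpus(
    path: str | Path, emoticons: Iterable[str] = ()
) -> tuple[Document, ...]:
    """Read and tokenize a corpus from a TSV file or a directory of
    one-participant text files."""
    p = Path(path)
    docs: list[Document] = []
    if p.is_dir():
        files = sorted(p.glob("*.txt"))
        if not files:
            raise ConfigError(f"no .txt files in corpus directory {p}")
        for f in files:
            docs.append(
                Document(
                    f.stem,
                    tokenize(f.read_text(encoding="utf-8"), emoticons),
                )
            )
        return tuple(docs)
    table = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    required = {"participant_id", "text"}
    if not required.issubset(table.columns):
        raise ConfigError(
            f"corpus TSV needs columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    grouped = table.groupby("participant_id", sort=True)["text"].agg(
        "\n".join
    )
    for pid, text in grouped.items():
        docs.append(Document(str(pid), tokenize(text, emoticons)))
    return tuple(docs)


def write_corpus(docs: Sequence[Document], path: str | Path) -> None:
    """Write documents as a corpus TSV (token surfaces joined by spaces)."""
    rows = [
        (doc.participant_id, " ".join(t.surface for t in doc.tokens))
        for doc in docs
    ]
    pd.DataFrame(rows, columns=["participant_id", "text"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference(path: str | Path) -> tuple[ReferenceLabel, ...]:
    """Read a token-level reference annotation TSV."""
    table = pd.read_csv(
        Path(path), sep="\t", dtype=str, keep_default_na=False
    )
    required = {"participant_id", "position", "subcategory"}
    if not required.issubset(table.columns):
        raise ConfigError(
            f"reference TSV needs columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    return tuple(
        ReferenceLabel(
            str(row.participant_id),
            int(row.position),
            str(row.subcategory),
        )
        for row in table.itertuples(index=False)
    )


def write_reference(
    labels: Sequence[ReferenceLabel],
    path: str | Path,
    surfaces: dict[tuple[str, int], str] | None = None,
) -> None:
    rows = [
        (
            lab.participant_id,
            lab.position,
            (surfaces or {}).get((lab.participant_id, lab.position), ""),
            lab.subcategory,
        )
        for lab in labels
    ]
    pd.DataFrame(
        rows,
        columns=["participant_id", "position", "surface", "subcategory"],
    ).to_csv(path, sep="\t", index=False)


def write_tagged(tagged: TaggedCorpus, path: str | Path) -> None:
    tagged.to_frame().to_csv(path, sep="\t", index=False)
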