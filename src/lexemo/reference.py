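"""Human-coded token-level emotion labels and their alignment with machine tags.

Human coders assign each emotional word to one of eight subcategories
(positive feelings, optimism, anxiety, anger, sadness, other positive,
other negative, or not-emotion).  For comparison with dictionary taggers the
single label is rolled up through the machine hierarchy: a sadness label
also counts as negative emotion and total affect, while the positive
subcategories — which newer dictionaries dropped for poor base rates — all
roll up to positive emotion.  Alignment pairs every word token with its
reference set and predicted set, the unit of analysis being the individual
word.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import (
    PositionMismatchError,
    UndefinedKappaError,
    UnknownSubcategoryError,
)
from .lexicon import TaggedCorpus

__all__ = [
    "SUBCATEGORIES",
    "AlignedCorpus",
    "ReferenceLabel",
    "align",
    "cohen_kappa",
    "reference_percentages",
    "rollup",
]

#: the closed human coding scheme
SUBCATEGORIES: tuple[str, ...] = (
    "positive-feelings",
    "optimism",
    "anxiety",
    "anger",
    "sadness",
    "other-positive",
    "other-negative",
    "not-emotion",
)

# machine-hierarchy rollup of each human subcategory; the positive
# subcategories have no machine counterpart, so they stop at posemo
_ROLLUP: dict[str, frozenset[str]] = {
    "positive-feelings": frozenset({"posemo", "affect"}),
    "optimism": frozenset({"posemo", "affect"}),
    "other-positive": frozenset({"posemo", "affect"}),
    "anxiety": frozenset({"anx", "negemo", "affect"}),
    "anger": frozenset({"anger", "negemo", "affect"}),
    "sadness": frozenset({"sad", "negemo", "affect"}),
    "other-negative": frozenset({"negemo", "affect"}),
    "not-emotion": frozenset(),
}


def rollup(subcategory: str) -> frozenset[str]:
    """Machine category set implied by one human subcategory label."""
    try:
        return _ROLLUP[subcategory]
    except KeyError:
        raise UnknownSubcategoryError(
            f"unknown subcategory {subcategory!r}; expected one of "
            f"{SUBCATEGORIES}"
        ) from None


@dataclass(frozen=True)
class ReferenceLabel:
    participant_id: str
    position: int
    subcategory: str

    def __post_init__(self):
        rollup(self.subcategory)  # validates membership


@dataclass
class AlignedCorpus:
    """Token-level pairing of reference and predicted category sets.

    ``frame`` has one row per word token with boolean columns
    ``ref_<cat>`` and ``pred_<cat>`` for every category in ``categories``;
    both sides are closed under parent expansion by construction.
    """

    frame: pd.DataFrame
    categories: tuple[str, ...]

    @property
    def total_tokens(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> list[str]:
        return sorted(self.frame["participant_id"].unique())

    def ref_column(self, category: str) -> np.ndarray:
        return self.frame[f"ref_{category}"].to_numpy()

    def pred_column(self, category: str) -> np.ndarray:
        return self.frame[f"pred_{category}"].to_numpy()

    @classmethod
    def from_arrays(
        cls,
        participant_ids: Sequence[str] | np.ndarray,
        positions: Sequence[int] | np.ndarray,
        ref: np.ndarray,
        pred: np.ndarray,
        categories: Sequence[str],
    ) -> "AlignedCorpus":
        """Vectorized constructor from boolean (n_tokens, n_categories)
        reference and prediction matrices."""
        cats = tuple(categories)
        data: dict[str, np.ndarray] = {
            "participant_id": np.asarray(participant_ids),
            "position": np.asarray(positions),
        }
        for j, c in enumerate(cats):
            data[f"ref_{c}"] = np.asarray(ref[:, j], dtype=bool)
        for j, c in enumerate(cats):
            data[f"pred_{c}"] = np.asarray(pred[:, j], dtype=bool)
        return cls(pd.DataFrame(data), cats)


def align(
    labels: Iterable[ReferenceLabel],
    tagged: TaggedCorpus,
    categories: Sequence[str] = ("affect", "posemo", "negemo", "anx",
                                 "anger", "sad"),
) -> AlignedCorpus:
    """Pair every word token with its reference and predicted sets.

    Word tokens lacking a reference label get an empty reference set
    (not-emotion).  A label whose position does not correspond to a word
    token of its participant raises :class:`PositionMismatchError`.
    """
    by_token: dict[tuple[str, int], str] = {}
    for lab in labels:
        key = (lab.participant_id, lab.position)
        if key in by_token and by_token[key] != lab.subcategory:
            raise PositionMismatchError(
                f"conflicting labels at participant "
                f"{lab.participant_id!r} position {lab.position}"
            )
        by_token[key] = lab.subcategory

    cats = tuple(categories)
    pids: list[str] = []
    positions: list[int] = []
    ref_rows: list[list[bool]] = []
    pred_rows: list[list[bool]] = []
    word_positions: set[tuple[str, int]] = set()
    for pid, tok, pred_set in tagged.iter_tokens():
        if not tok.is_word and not (
            tok.is_emoticon and tagged.count_emoticons_as_words
        ):
            continue
        word_positions.add((pid, tok.position))
        sub = by_token.get((pid, tok.position))
        ref_set = rollup(sub) if sub is not None else frozenset()
        pids.append(pid)
        positions.append(tok.position)
        ref_rows.append([c in ref_set for c in cats])
        pred_rows.append([c in pred_set for c in cats])

    stray = set(by_token) - word_positions
    if stray:
        pid, pos = sorted(stray)[0]
        raise PositionMismatchError(
            f"reference label at participant {pid!r} position {pos} does "
            "not correspond to a countable token"
        )
    return AlignedCorpus.from_arrays(
        np.asarray(pids, dtype=object),
        np.asarray(positions),
        np.asarray(ref_rows, dtype=bool).reshape(len(pids), len(cats)),
        np.asarray(pred_rows, dtype=bool).reshape(len(pids), len(cats)),
        cats,
    )


def reference_percentages(
    labels: Iterable[ReferenceLabel],
    tokens_per_participant: Mapping[str, int],
    categories: Sequence[str] = ("affect", "posemo", "negemo", "anx",
                                 "anger", "sad"),
) -> pd.DataFrame:
    """Human-coder per-participant category percentages.

    ``tokens_per_participant`` supplies each participant's word-count
    denominator.
    """
    cats = tuple(categories)
    counts = {pid: dict.fromkeys(cats, 0) for pid in tokens_per_participant}
    for lab in labels:
        if lab.participant_id not in counts:
            raise PositionMismatchError(
                f"label for unknown participant {lab.participant_id!r}"
            )
        for c in rollup(lab.subcategory):
            if c in counts[lab.participant_id]:
                counts[lab.participant_id][c] += 1
    data = {
        pid: [100.0 * counts[pid][c] / n for c in cats]
        for pid, n in tokens_per_participant.items()
    }
    out = pd.DataFrame.from_dict(data, orient="index", columns=list(cats))
    out.index.name = "participant_id"
    return out.sort_index()


def cohen_kappa(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> float:
    """Chance-corrected agreement between two raters over the same tokens.

    κ = (p_o − p_e) / (1 − p_e).  Raises :class:`UndefinedKappaError` in the
    degenerate case p_e = 1 (both raters use a single common category).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("raters must label the same nonempty token set")
    values = np.union1d(a, b)
    pa = np.array([(a == v).mean() for v in values])
    pb = np.array([(b == v).mean() for v in values])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "chance agreement is 1; kappa undefined"
        )
    return float(cohen_kappa_score(a, b))
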