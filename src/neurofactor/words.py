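"""The 60-noun stimulus set: twelve taxonomic categories with five exemplars each.

The word set is the fixed vocabulary of the whole pipeline: activation
profiles, factor scores, ratings and decoding labels are all indexed by these
60 concrete nouns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["WordSet", "builtin_wordset"]

# category -> five exemplars, in printed order
_CATEGORIES: dict[str, tuple[str, ...]] = {
    "body parts": ("leg", "arm", "eye", "foot", "hand"),
    "furniture": ("chair", "table", "bed", "desk", "dresser"),
    "vehicles": ("car", "airplane", "train", "truck", "bicycle"),
    "animals": ("horse", "dog", "bear", "cow", "cat"),
    "kitchen utensils": ("glass", "knife", "bottle", "cup", "spoon"),
    "tools": ("chisel", "hammer", "screwdriver", "pliers", "saw"),
    "buildings": ("apartment", "barn", "house", "church", "igloo"),
    "building parts": ("window", "door", "chimney", "closet", "arch"),
    "clothing": ("coat", "dress", "shirt", "skirt", "pants"),
    "insects": ("fly", "ant", "bee", "butterfly", "beetle"),
    "vegetables": ("lettuce", "tomato", "carrot", "corn", "celery"),
    "man-made objects": ("refrigerator", "key", "telephone", "watch", "bell"),
}


@dataclass(frozen=True)
class WordSet:
    """An ordered word list with per-word category labels.

    Attributes
    ----------
    words:
        Word strings in canonical order.
    categories:
        Per-word taxonomic category label, aligned with ``words``.
    """

    words: tuple[str, ...]
    categories: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.words) != len(set(self.words)):
            raise ValueError("duplicate words in word set")
        if len(self.categories) != len(self.words):
            raise ValueError("categories must align with words")
        object.__setattr__(
            self, "_index", {w: i for i, w in enumerate(self.words)}
        )

    def __len__(self) -> int:
        return len(self.words)

    def index(self, word: str) -> int:
        return self._index[word]

    @property
    def lengths(self) -> tuple[int, ...]:
        """Letter count of each word."""
        return tuple(len(w) for w in self.words)

    @property
    def category_names(self) -> tuple[str, ...]:
        """Distinct categories in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.categories:
            seen.setdefault(c)
        return tuple(seen)

    def category_members(self, category: str) -> tuple[str, ...]:
        return tuple(
            w for w, c in zip(self.words, self.categories) if c == category
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.words,
                "category": self.categories,
                "length": self.lengths,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WordSet":
        return cls(
            words=tuple(frame["word"].astype(str)),
            categories=tuple(frame["category"].astype(str)),
        )


def builtin_wordset() -> WordSet:
    """The built-in 60-noun stimulus set (12 categories x 5 exemplars)."""
    words: list[str] = []
    cats: list[str] = []
    for cat, members in _CATEGORIES.items():
        words.extend(members)
        cats.extend([cat] * len(members))
    return WordSet(words=tuple(words), categories=tuple(cats))
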