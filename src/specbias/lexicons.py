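"""Target and attribute word lists.

The built-in lists operationalize moral standing for a speciesism audit:
six target groups (humans, four animal categories, worthless objects as a
lower-bound benchmark) and two bipolar attribute dimensions (concern vs.
indifference, value vs. valueless).  Lists ship as plain-text data files —
one token per line — so other group/attribute audits can swap them out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "Lexicon",
    "BipolarAttribute",
    "builtin_lexicons",
    "load_lexicon",
    "expand_spelling_variants",
    "TARGET_GROUPS",
    "ATTRIBUTES",
]

TARGET_GROUPS = (
    "humans",
    "companion_animals",
    "appealing_wild",
    "food_animals",
    "unappealing_wild",
    "worthless_objects",
)
ANIMAL_GROUPS = ("companion_animals", "appealing_wild", "food_animals", "unappealing_wild")
ATTRIBUTES = ("concern_vs_indifference", "value_vs_valueless")

# British spellings kept verbatim; American variants available via
# expand_spelling_variants (off by default).
_SPELLING_VARIANTS = {
    "disfavour": "disfavor",
    "disfavours": "disfavors",
    "disfavoured": "disfavored",
    "disfavouring": "disfavoring",
}


@dataclass(frozen=True)
class Lexicon:
    """A named, ordered list of unique single-word tokens."""

    name: str
    words: tuple[str, ...]

    def __post_init__(self):
        seen = set()
        for w in self.words:
            if not w or any(c.isspace() for c in w):
                raise ValueError(f"lexicon {self.name!r}: invalid token {w!r}")
            if w in seen:
                raise ValueError(f"lexicon {self.name!r}: duplicate token {w!r}")
            seen.add(w)
        if not self.words:
            raise ValueError(f"lexicon {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self) -> Iterator[str]:
        return iter(self.words)


@dataclass(frozen=True)
class BipolarAttribute:
    """A bipolar construct operationalized as two opposing word lists.

    A target word's differential association is its mean cosine to the
    ``positive`` pole minus its mean cosine to the ``negative`` pole.
    """

    name: str
    positive: Lexicon
    negative: Lexicon

    def __post_init__(self):
        overlap = set(self.positive.words) & set(self.negative.words)
        if overlap:
            raise ValueError(f"attribute {self.name!r}: poles share tokens {sorted(overlap)}")


def _read_builtin(name: str) -> Lexicon:
    ref = resources.files("specbias") / "data" / "lexicons" / f"{name}.txt"
    words = tuple(w for w in ref.read_text(encoding="utf-8").split("\n") if w)
    return Lexicon(name=name, words=words)


def builtin_lexicons() -> dict:
    """Registry of the built-in target lexicons and bipolar attributes.

    Returns a dict with keys ``targets`` (six Lexicons, in canonical order)
    and ``attributes`` (two BipolarAttributes).
    """
    targets = {name: _read_builtin(name) for name in TARGET_GROUPS}
    attributes = {
        "concern_vs_indifference": BipolarAttribute(
            "concern_vs_indifference", _read_builtin("concern"), _read_builtin("indifference")
        ),
        "value_vs_valueless": BipolarAttribute(
            "value_vs_valueless", _read_builtin("value"), _read_builtin("valueless")
        ),
    }
    return {"targets": targets, "attributes": attributes}


def load_lexicon(path: str | Path, name: str | None = None) -> Lexicon:
    """Load a one-token-per-line lexicon file.

    Duplicates are removed keeping the first occurrence (with a warning);
    a line containing whitespace-separated tokens is an error, since targets
    and attribute words are single tokens.
    """
    path = Path(path)
    words: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            if any(c.isspace() for c in token):
                raise ValueError(f"{path}: line {lineno}: multi-token line {token!r}")
            if token in seen:
                warnings.warn(f"{path}: duplicate token {token!r} (keeping first)")
                continue
            seen.add(token)
            words.append(token)
    if not words:
        raise ValueError(f"{path}: empty lexicon file")
    return Lexicon(name=name or path.stem, words=tuple(words))


def expand_spelling_variants(lex: Lexicon) -> Lexicon:
    """Append American spellings of any British tokens (opt-in)."""
    extra = tuple(
        v for w in lex.words if (v := _SPELLING_VARIANTS.get(w)) and v not in lex.words
    )
    if not extra:
        return lex
    return Lexicon(name=lex.name, words=lex.words + extra)
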