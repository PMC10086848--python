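"""Reading, writing and querying word-embedding models.

Supports the three vector-file dialects the common pre-trained models ship
in: word2vec text (optional ``V D`` header), word2vec binary, and GloVe text
(identical to word2vec text but never carries a header).  Out-of-vocabulary
words are values (``None``), not errors: attrition is a first-class part of
the audit and is summarised by :func:`coverage_report`.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "EmbeddingModel",
    "CoverageReport",
    "FormatError",
    "load_embeddings",
    "save_word2vec_text",
    "lookup",
    "coverage_report",
]

FORMATS = ("word2vec-text", "word2vec-binary", "glove-text")
POLICIES = ("exact", "exact-then-lowercase")


class FormatError(ValueError):
    """A vector file does not conform to its declared dialect."""


@dataclass
class EmbeddingModel:
    """A named vocabulary-to-vector map of fixed dimension.

    Vectors are stored row-wise in a single float64 matrix; ``index`` maps
    token -> row.  Every row has length ``dim`` and nonzero norm (zero
    vectors are dropped at load time, since they have no direction and no
    cosine).
    """

    name: str
    matrix: np.ndarray
    index: dict[str, int] = field(repr=False)

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def vocabulary(self) -> set[str]:
        return set(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        """Stored vector for an exact token; KeyError if absent."""
        return self.matrix[self.index[word]]

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, Sequence[float]]]) -> "EmbeddingModel":
        """Build a model from (token, vector) pairs; keep-first on duplicates."""
        index: dict[str, int] = {}
        rows: list[np.ndarray] = []
        for token, vec in pairs:
            v = np.asarray(vec, dtype=np.float64)
            if token in index:
                warnings.warn(f"duplicate token {token!r}: keeping first occurrence")
                continue
            if not np.any(v):
                warnings.warn(f"token {token!r} has an all-zero vector: dropped")
                continue
            index[token] = len(rows)
            rows.append(v)
        if not rows:
            raise FormatError("model has no usable vectors")
        return cls(name=name, matrix=np.vstack(rows), index=index)


@dataclass(frozen=True)
class CoverageReport:
    """Partition of a queried word list into found / missing for one model."""

    model: str
    lexicon: str
    found: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def n_found(self) -> int:
        return len(self.found)

    @property
    def n_missing(self) -> int:
        return len(self.missing)


def _parse_text(path: Path, *, allow_header: bool, vocab_limit: Optional[int]) -> tuple[list[tuple[str, np.ndarray]], Optional[tuple[int, int]]]:
    pairs: list[tuple[str, np.ndarray]] = []
    header: Optional[tuple[int, int]] = None
    dim: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and allow_header and len(parts) == 2:
                try:
                    header = (int(parts[0]), int(parts[1]))
                    continue
                except ValueError:
                    pass  # a two-column data row, not a header
            token = parts[0]
            try:
                vec = np.array(parts[1:], dtype=np.float64)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric vector entry") from exc
            if dim is None:
                dim = vec.size
                if dim == 0:
                    raise FormatError(f"{path}: line {lineno}: row has no vector entries")
            elif vec.size != dim:
                raise FormatError(
                    f"{path}: line {lineno}: row has {vec.size} values, expected {dim}"
                )
            pairs.append((token, vec))
            if vocab_limit is not None and len(pairs) >= vocab_limit:
                break
    if header is not None and dim is not None and header[1] != dim:
        raise FormatError(f"{path}: header declares dim {header[1]} but rows have {dim}")
    return pairs, header


def _parse_binary(path: Path, vocab_limit: Optional[int]) -> list[tuple[str, np.ndarray]]:
    # word2vec binary: ASCII header "V D\n", then per word: token bytes up to
    # a space, D little-endian float32s, optional trailing newline.
    pairs: list[tuple[str, np.ndarray]] = []
    with open(path, "rb") as fh:
        header = fh.readline()
        try:
            vocab_size, dim = (int(x) for x in header.split())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed binary header {header!r}") from exc
        n = vocab_size if vocab_limit is None else min(vocab_limit, vocab_size)
        width = 4 * dim
        for _ in range(n):
            token_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise FormatError(f"{path}: truncated binary file")
                if ch == b" ":
                    break
                if ch != b"\n":  # some writers pad with newlines between rows
                    token_bytes.extend(ch)
            raw = fh.read(width)
            if len(raw) != width:
                raise FormatError(f"{path}: truncated vector for token {bytes(token_bytes)!r}")
            vec = np.frombuffer(raw, dtype="<f4").astype(np.float64)
            pairs.append((token_bytes.decode("utf-8"), vec))
    return pairs


def load_embeddings(
    path: str | Path,
    format: str = "word2vec-text",
    vocab_limit: Optional[int] = None,
    name: Optional[str] = None,
) -> EmbeddingModel:
    """Load an embedding model from a vector file.

    Parameters
    ----------
    path
        Vector file to read.
    format
        One of ``word2vec-text`` (optional ``V D`` header line),
        ``word2vec-binary``, or ``glove-text`` (headerless).
    vocab_limit
        Keep only the first N rows (pre-trained files are sorted by corpus
        frequency, so this keeps the most frequent words).
    name
        Model label; defaults to the file stem.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "word2vec-binary":
        pairs = _parse_binary(path, vocab_limit)
    else:
        pairs, _ = _parse_text(
            path, allow_header=(format == "word2vec-text"), vocab_limit=vocab_limit
        )
    if not pairs:
        raise FormatError(f"{path}: no vector rows")
    return EmbeddingModel.from_pairs(name or path.stem, pairs)


def save_word2vec_text(model: EmbeddingModel, path: str | Path, header: bool = True) -> None:
    """Write a model as word2vec text (with header) or GloVe text (without)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(model)} {model.dim}\n")
        for token, row in model.index.items():
            vals = " ".join(repr(float(x)) for x in model.matrix[row])
            fh.write(f"{token} {vals}\n")


def save_word2vec_binary(model: EmbeddingModel, path: str | Path) -> None:
    """Write a model in the word2vec binary format (float32 payload)."""
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(f"{len(model)} {model.dim}\n".encode("utf-8"))
        for token, row in model.index.items():
            fh.write(token.encode("utf-8") + b" ")
            fh.write(struct.pack(f"<{model.dim}f", *model.matrix[row].astype(np.float32)))
            fh.write(b"\n")


def lookup(model: EmbeddingModel, word: str, policy: str = "exact-then-lowercase") -> Optional[np.ndarray]:
    """Resolve a word to its vector under a casing policy; None if missing.

    ``exact`` tries the token as given; ``exact-then-lowercase`` falls back
    to the lowercased token (mixed-case corpora such as news vs. lowercased
    GloVe vocabularies).  Missing is a value, never an arbitrary vector.
    """
    if not word:
        raise ValueError("word must be a non-empty token")
    if policy not in POLICIES:
        raise ValueError(f"unknown lookup policy {policy!r}; expected one of {POLICIES}")
    if word in model.index:
        return model.vector(word)
    if policy == "exact-then-lowercase":
        low = word.lower()
        if low in model.index:
            return model.vector(low)
    return None


def coverage_report(model: EmbeddingModel, lexicon, policy: str = "exact-then-lowercase") -> CoverageReport:
    """Partition a lexicon into words found / missing in the model."""
    words = list(lexicon.words) if hasattr(lexicon, "words") else list(lexicon)
    if not words:
        raise ValueError("lexicon is empty")
    found = tuple(w for w in words if lookup(model, w, policy) is not None)
    missing = tuple(w for w in words if lookup(model, w, policy) is None)
    label = getattr(lexicon, "name", "lexicon")
    return CoverageReport(model=model.name, lexicon=label, found=found, missing=missing)
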