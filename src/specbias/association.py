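"""Per-word differential cosine associations against a bipolar attribute.

For a target word *w* and an attribute with poles A (e.g. concern) and B
(e.g. indifference), the raw score is

    s(w) = mean_{a in A} cos(w, a)  -  mean_{b in B} cos(w, b),

a relative index in [-2, 2] of how much more strongly *w* associates with
pole A than pole B.  Scores are standardized within one model (and one
attribute) by dividing by the sample standard deviation of the raw scores
of all target words scored in the run; no mean-centering, so the zero point
(equal association with both poles) keeps its meaning.  Group contrasts
downstream are invariant to this common positive rescaling.

Attribute words missing from a model are dropped and logged as attrition,
never imputed; a target word that does not resolve simply yields no score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import CoverageReport, EmbeddingModel, coverage_report, lookup
from .lexicons import BipolarAttribute, Lexicon

__all__ = ["WordScore", "ScoreTable", "cosine", "word_association", "score_model"]


@dataclass(frozen=True)
class WordScore:
    word: str
    group: str
    model: str
    raw: float
    standardized: float


@dataclass
class ScoreTable:
    """All per-word scores for one model x attribute, plus attrition.

    ``sd_used`` is the sample SD (ddof=1) of the raw scores of every target
    word in the table; ``standardized = raw / sd_used``.
    """

    model: str
    attribute: str
    scores: list[WordScore]
    sd_used: float
    attrition: dict[str, CoverageReport] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [s.model for s in self.scores],
                "attribute": self.attribute,
                "group": [s.group for s in self.scores],
                "word": [s.word for s in self.scores],
                "raw": [s.raw for s in self.scores],
                "standardized": [s.standardized for s in self.scores],
            }
        )

    def group_scores(self, group: str, standardized: bool = True) -> np.ndarray:
        vals = [
            (s.standardized if standardized else s.raw)
            for s in self.scores
            if s.group == group
        ]
        return np.asarray(vals, dtype=np.float64)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.scores:
            seen.setdefault(s.group, None)
        return tuple(seen)


def cosine(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity u.v / (|u||v|), clamped to [-1, 1] against rounding."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector lengths differ: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _pole_matrix(model: EmbeddingModel, pole: Lexicon, policy: str) -> Optional[np.ndarray]:
    rows = [vec for w in pole.words if (vec := lookup(model, w, policy)) is not None]
    if not rows:
        return None
    return np.vstack(rows)


def _unit(rows: np.ndarray) -> np.ndarray:
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


def word_association(
    model: EmbeddingModel,
    word: str,
    attr: BipolarAttribute,
    policy: str = "exact-then-lowercase",
) -> Optional[float]:
    """Raw differential association of one word; None if the word is missing.

    Raises if an entire attribute pole is unresolvable in the model (the
    attribute is undefined there).
    """
    pos = _pole_matrix(model, attr.positive, policy)
    neg = _pole_matrix(model, attr.negative, policy)
    if pos is None or neg is None:
        side = attr.positive.name if pos is None else attr.negative.name
        raise ValueError(f"attribute pole {side!r} has no vectors in model {model.name!r}")
    vec = lookup(model, word, policy)
    if vec is None:
        return None
    u = vec / np.linalg.norm(vec)
    return float(np.clip(_unit(pos) @ u, -1, 1).mean() - np.clip(_unit(neg) @ u, -1, 1).mean())


def score_model(
    model: EmbeddingModel,
    targets: Sequence[tuple[str, Lexicon]],
    attr: BipolarAttribute,
    policy: str = "exact-then-lowercase",
) -> ScoreTable:
    """Score every resolvable target word and standardize within the model.

    Parameters
    ----------
    model
        The embedding model to audit.
    targets
        Ordered (group label, lexicon) pairs; all scored words enter the
        standardization pool.
    attr
        The bipolar attribute dimension.
    policy
        Word-lookup casing policy.

    Raises
    ------
    ValueError
        If fewer than two target words resolve, if the raw scores are all
        identical (sample SD zero, standardization undefined), or if an
        entire attribute pole is missing from the model.
    """
    pos = _pole_matrix(model, attr.positive, policy)
    neg = _pole_matrix(model, attr.negative, policy)
    if pos is None or neg is None:
        side = attr.positive.name if pos is None else attr.negative.name
        raise ValueError(f"attribute pole {side!r} has no vectors in model {model.name!r}")
    pos_u, neg_u = _unit(pos), _unit(neg)

    attrition = {
        attr.positive.name: coverage_report(model, attr.positive, policy),
        attr.negative.name: coverage_report(model, attr.negative, policy),
    }

    entries: list[tuple[str, str]] = []  # (group, word), resolvable only
    vecs: list[np.ndarray] = []
    for group, lex in targets:
        attrition[group] = coverage_report(model, lex, policy)
        for w in lex.words:
            vec = lookup(model, w, policy)
            if vec is not None:
                entries.append((group, w))
                vecs.append(vec)
    if len(entries) < 2:
        raise ValueError(f"model {model.name!r}: fewer than two target words resolvable")

    tmat = _unit(np.vstack(vecs))
    raw = (
        np.clip(tmat @ pos_u.T, -1, 1).mean(axis=1)
        - np.clip(tmat @ neg_u.T, -1, 1).mean(axis=1)
    )
    sd = float(np.std(raw, ddof=1))
    if sd == 0.0:
        raise ValueError(
            f"model {model.name!r}: all raw scores identical; standardization undefined"
        )
    scores = [
        WordScore(word=w, group=g, model=model.name, raw=float(r), standardized=float(r / sd))
        for (g, w), r in zip(entries, raw)
    ]
    return ScoreTable(
        model=model.name, attribute=attr.name, scores=scores, sd_used=sd, attrition=attrition
    )
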