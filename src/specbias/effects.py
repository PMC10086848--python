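"""Effect sizes from score tables: group contrasts and score correlations.

A group contrast is Cohen's d between two groups' standardized word scores
within one model, with the usual large-sample variance

    var(d) = (n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2)),

which is what the inverse-variance meta-analysis downstream weights by.
Because standardization is a common positive rescaling within a model, d is
identical whether computed from raw or standardized scores.

Correlations between two attributes' scores (e.g. concern vs. value) are
Pearson r over words paired by token within one model, carried on the
Fisher-z scale with variance 1/(n-3) for pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .association import ScoreTable

__all__ = ["GroupContrast", "CorrelationEstimate", "cohens_d", "contrast_model", "score_correlation"]


@dataclass(frozen=True)
class GroupContrast:
    model: str
    attribute: str
    group1: str
    group2: str
    n1: int
    n2: int
    d: float
    var_d: float


@dataclass(frozen=True)
class CorrelationEstimate:
    model: str
    r: float
    n: int

    @property
    def fisher_z(self) -> float:
        return float(np.arctanh(self.r))

    @property
    def var_z(self) -> float:
        return 1.0 / (self.n - 3)


def cohens_d(
    scores1: Sequence[float],
    scores2: Sequence[float],
    *,
    hedges: bool = False,
    model: str = "",
    attribute: str = "",
    group1: str = "group1",
    group2: str = "group2",
) -> GroupContrast:
    """Standardized mean difference (group1 minus group2) with its variance.

    ``hedges`` applies the small-sample correction J = 1 - 3/(4(n1+n2)-9)
    to both d and its variance (Hedges' g); off by default.
    """
    x1 = np.asarray(scores1, dtype=np.float64)
    x2 = np.asarray(scores2, dtype=np.float64)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs at least 2 scores (got {n1}, {n2})")
    s2p = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2p == 0.0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    d = float((x1.mean() - x2.mean()) / np.sqrt(s2p))
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    var_d = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    return GroupContrast(
        model=model, attribute=attribute, group1=group1, group2=group2,
        n1=n1, n2=n2, d=d, var_d=float(var_d),
    )


def contrast_model(
    table: ScoreTable, group1: str, group2: str, *, hedges: bool = False
) -> GroupContrast:
    """Cohen's d between two groups' standardized scores in one table."""
    for g in (group1, group2):
        if g not in table.groups:
            raise ValueError(f"group {g!r} not present in score table for {table.model!r}")
    return cohens_d(
        table.group_scores(group1),
        table.group_scores(group2),
        hedges=hedges,
        model=table.model,
        attribute=table.attribute,
        group1=group1,
        group2=group2,
    )


def score_correlation(table_a: ScoreTable, table_b: ScoreTable) -> CorrelationEstimate:
    """Pearson r between two attributes' word scores, paired by token.

    Only words scored in both tables enter; requires at least 4 complete
    pairs (Fisher-z variance 1/(n-3) needs n > 3).
    """
    if table_a.model != table_b.model:
        raise ValueError(
            f"tables come from different models: {table_a.model!r} vs {table_b.model!r}"
        )
    a = {s.word: s.standardized for s in table_a.scores}
    b = {s.word: s.standardized for s in table_b.scores}
    common = [w for w in a if w in b]
    if len(common) < 4:
        raise ValueError(f"only {len(common)} paired words; need at least 4")
    xa = np.array([a[w] for w in common])
    xb = np.array([b[w] for w in common])
    if xa.std() == 0.0 or xb.std() == 0.0:
        raise ValueError("zero variance in paired scores; correlation undefined")
    r = float(stats.pearsonr(xa, xb).statistic)
    return CorrelationEstimate(model=table_a.model, r=r, n=len(common))
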