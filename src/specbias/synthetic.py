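"""Synthetic embedding families with planted group-association structure.

Each synthetic model plants a unit attribute axis u in dimension ``dim``:
pole-A attribute words sit at gamma*u + noise, pole-B words at -gamma*u +
noise, and every word of target group g at delta_{g,m}*u + noise, with
isotropic Gaussian noise of sd ``noise_sd``.  The realized per-model shift

    delta_{g,m} = delta_g + eta_{g,m},    eta_{g,m} ~ N(0, tau_plant^2)

drawn independently per group and model, so tau_plant > 0 plants genuine
between-model heterogeneity in the group contrasts (a shift common to all
groups would cancel in every contrast).

delta is an axis shift, not a target cosine: the cosine readout is
nonlinear in delta, so recovery is validated by sign, ordering and error
rates rather than by an exact mapping from delta to d.  Generation is
deterministic given (seed, model_index); per-model streams use seed +
model_index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .association import score_model
from .effects import contrast_model
from .embeddings import EmbeddingModel
from .lexicons import BipolarAttribute, Lexicon
from .meta import MetaResult, pool

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "PlantedTruth",
    "RecoveryReport",
    "make_synthetic_model",
    "spec_targets",
    "spec_attribute",
    "run_recovery",
    "default_family_spec",
]


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_words: int
    delta: float

    def __post_init__(self):
        if self.n_words < 2:
            raise ValueError(f"group {self.label!r}: need at least 2 words")


@dataclass(frozen=True)
class SyntheticSpec:
    """Family of k synthetic embedding models sharing planted structure.

    Defaults emulate the audit's study conditions: 7 models, per-group word
    noise sd 0.3 around axis shifts of order 1, pole strength gamma = 1.
    ``second_attribute_axis_corr``, when set, adds a second bipolar
    attribute whose axis correlates at that level with the first (so the
    two attributes' word scores correlate, as concern and value do).
    """

    groups: tuple[GroupSpec, ...]
    dim: int = 50
    pole_size: int = 20
    gamma: float = 1.0
    noise_sd: float = 0.3
    k: int = 7
    tau_plant: float = 0.0
    seed: int = 0
    second_attribute_axis_corr: Optional[float] = None

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.pole_size < 1:
            raise ValueError("pole_size must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.tau_plant < 0:
            raise ValueError("tau_plant must be >= 0")
        if not self.groups:
            raise ValueError("at least one group required")


@dataclass(frozen=True)
class PlantedTruth:
    """Realized per-model shifts and the attribute axis used."""

    model_index: int
    deltas: dict[str, float]
    axis: np.ndarray = field(repr=False)
    axis2: Optional[np.ndarray] = field(default=None, repr=False)


def spec_targets(spec: SyntheticSpec) -> list[tuple[str, Lexicon]]:
    """The (group label, lexicon) pairs a synthetic family defines."""
    return [
        (g.label, Lexicon(g.label, tuple(f"{g.label}_{j}" for j in range(g.n_words))))
        for g in spec.groups
    ]


def spec_attribute(spec: SyntheticSpec, which: int = 1) -> BipolarAttribute:
    """The synthetic bipolar attribute (which=2 for the optional second)."""
    tag = "" if which == 1 else "2"
    return BipolarAttribute(
        f"attr{tag or '1'}",
        Lexicon(f"pos{tag}", tuple(f"pos{tag}_{i}" for i in range(spec.pole_size))),
        Lexicon(f"neg{tag}", tuple(f"neg{tag}_{i}" for i in range(spec.pole_size))),
    )


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def make_synthetic_model(spec: SyntheticSpec, model_index: int) -> tuple[EmbeddingModel, PlantedTruth]:
    """Generate the model_index-th model of the family, with its truth."""
    rng = np.random.default_rng(spec.seed + model_index)
    u = _unit_vector(rng, spec.dim)
    u2 = None
    if spec.second_attribute_axis_corr is not None:
        rho = spec.second_attribute_axis_corr
        w = rng.standard_normal(spec.dim)
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        u2 = rho * u + np.sqrt(1.0 - rho**2) * w

    deltas = {
        g.label: g.delta + (rng.normal(0.0, spec.tau_plant) if spec.tau_plant > 0 else 0.0)
        for g in spec.groups
    }

    pairs: list[tuple[str, np.ndarray]] = []

    def noisy(center: np.ndarray, count: int, prefix: str):
        eps = rng.normal(0.0, spec.noise_sd, size=(count, spec.dim))
        for i, row in enumerate(center + eps):
            pairs.append((f"{prefix}_{i}", row))

    noisy(spec.gamma * u, spec.pole_size, "pos")
    noisy(-spec.gamma * u, spec.pole_size, "neg")
    if u2 is not None:
        noisy(spec.gamma * u2, spec.pole_size, "pos2")
        noisy(-spec.gamma * u2, spec.pole_size, "neg2")
    for g in spec.groups:
        noisy(deltas[g.label] * u, g.n_words, g.label)

    model = EmbeddingModel.from_pairs(f"synth_{model_index}", pairs)
    return model, PlantedTruth(model_index=model_index, deltas=deltas, axis=u, axis2=u2)


@dataclass
class RecoveryReport:
    """Pooled contrasts of a synthetic family against the planted truth."""

    spec: SyntheticSpec
    meta: dict[tuple[str, str], MetaResult]
    planted_gap: dict[tuple[str, str], float]
    alpha: float = 0.05

    def detected(self, pair: tuple[str, str]) -> bool:
        """Planted non-null pair recovered: significant with the right sign."""
        res, gap = self.meta[pair], self.planted_gap[pair]
        return res.p < self.alpha and np.sign(res.estimate) == np.sign(gap)

    def rejected(self, pair: tuple[str, str]) -> bool:
        return self.meta[pair].p < self.alpha

    def sign_in_ci(self, pair: tuple[str, str]) -> bool:
        """Does the 95% CI lie on (or cover) the planted-gap side of zero?"""
        res, gap = self.meta[pair], self.planted_gap[pair]
        if gap > 0:
            return res.ci_high > 0
        if gap < 0:
            return res.ci_low < 0
        return res.ci_low <= 0 <= res.ci_high


def run_recovery(spec: SyntheticSpec, method: str = "DL", alpha: float = 0.05) -> RecoveryReport:
    """Generate the family and run the full score -> contrast -> pool pipeline.

    Returns pooled d per ordered group pair together with the planted
    delta-gap, so callers can check sign recovery, detection and error
    rates.
    """
    if spec.k < 2:
        raise ValueError("need k >= 2 models for a meta-analysis")
    attr = spec_attribute(spec)
    targets_proto = spec_targets(spec)
    pairs = list(itertools.combinations([g.label for g in spec.groups], 2))
    per_pair: dict[tuple[str, str], list] = {p: [] for p in pairs}
    for m in range(spec.k):
        model, _ = make_synthetic_model(spec, m)
        table = score_model(model, targets_proto, attr, policy="exact")
        for g1, g2 in pairs:
            per_pair[(g1, g2)].append(contrast_model(table, g1, g2))
    base = {g.label: g.delta for g in spec.groups}
    meta = {p: pool(per_pair[p], method=method) for p in pairs}
    gaps = {(g1, g2): base[g1] - base[g2] for g1, g2 in pairs}
    return RecoveryReport(spec=spec, meta=meta, planted_gap=gaps, alpha=alpha)


def default_family_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default six-group family emulating the audit's study conditions.

    Group sizes match the packaged word lists; planted shifts decrease from
    humans through companion, appealing-wild, food and unappealing-wild
    animals down to worthless objects, at magnitudes chosen so the pooled
    contrasts land in the d ~ 0.2-1.3 range typical of embedding-bias
    audits; mild between-model heterogeneity (tau_plant = 0.05).
    """
    spec = SyntheticSpec(
        groups=(
            GroupSpec("humans", 34, 0.34),
            GroupSpec("companion_animals", 10, 0.26),
            GroupSpec("appealing_wild", 8, 0.12),
            GroupSpec("food_animals", 19, 0.10),
            GroupSpec("unappealing_wild", 11, 0.06),
            GroupSpec("worthless_objects", 12, -0.12),
        ),
        dim=50,
        pole_size=20,
        gamma=1.0,
        noise_sd=0.3,
        k=7,
        tau_plant=0.05,
        seed=seed,
        second_attribute_axis_corr=0.6,
    )
    return replace(spec, **overrides) if overrides else spec
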