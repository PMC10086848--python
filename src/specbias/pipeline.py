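"""End-to-end audit: score every model, contrast every group pair, pool.

A run is driven by a single YAML config naming the embedding models (vector
files), the target lexicons, the bipolar attributes, the contrast list and
the meta-analysis options.  Outputs are plain CSVs (scores.csv,
contrasts.csv, meta.csv) plus a JSON manifest recording options, seed,
versions and word attrition, so a run is reproducible and auditable.

A model that cannot support a particular contrast (an entire pole or group
missing from its vocabulary) is dropped from that contrast with a warning —
k shrinks — rather than aborting the run; only a contrast supported by no
model at all is an error.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .association import ScoreTable, score_model
from .effects import CorrelationEstimate, GroupContrast, contrast_model, score_correlation
from .embeddings import load_embeddings
from .lexicons import BipolarAttribute, Lexicon, builtin_lexicons, load_lexicon
from .meta import MetaResult, pool, pool_correlations

__all__ = ["ModelEntry", "RunConfig", "ResultsBundle", "run", "load_config"]

log = logging.getLogger("specbias")


@dataclass(frozen=True)
class ModelEntry:
    name: str
    path: str
    format: str = "word2vec-text"


@dataclass
class RunConfig:
    """Validated configuration for one audit run."""

    models: tuple[ModelEntry, ...]
    targets: dict[str, Lexicon]
    attributes: dict[str, BipolarAttribute]
    contrasts: tuple[tuple[str, str], ...]
    correlation: Optional[tuple[str, str]] = None
    lookup_policy: str = "exact-then-lowercase"
    tau2_method: str = "DL"
    hedges: bool = False
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if not self.models:
            raise ValueError("config names no models")
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ValueError("duplicate model names in config")
        for g1, g2 in self.contrasts:
            if g1 == g2:
                raise ValueError(f"contrast pairs must be distinct labels: {g1!r}")
            for g in (g1, g2):
                if g not in self.targets:
                    raise ValueError(f"contrast references unknown group {g!r}")
        if self.correlation is not None:
            for a in self.correlation:
                if a not in self.attributes:
                    raise ValueError(f"correlation references unknown attribute {a!r}")


def _all_pairwise(groups: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple(itertools.combinations(groups, 2))


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config (before loading any model)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    models = tuple(
        ModelEntry(m["name"], str(_resolve(m["path"])), m.get("format", "word2vec-text"))
        for m in raw["models"]
    )
    builtin = builtin_lexicons()
    lex_cfg = raw.get("lexicons", "builtin")
    if lex_cfg == "builtin":
        targets = dict(builtin["targets"])
    else:
        targets = {name: load_lexicon(_resolve(p), name=name) for name, p in lex_cfg.items()}

    attr_cfg = raw.get("attributes", list(builtin["attributes"]))
    attributes: dict[str, BipolarAttribute] = {}
    if isinstance(attr_cfg, list):
        for name in attr_cfg:
            if name not in builtin["attributes"]:
                raise ValueError(f"unknown builtin attribute {name!r}")
            attributes[name] = builtin["attributes"][name]
    else:
        for name, spec in attr_cfg.items():
            attributes[name] = BipolarAttribute(
                name,
                load_lexicon(_resolve(spec["positive"])),
                load_lexicon(_resolve(spec["negative"])),
            )

    contrasts_cfg = raw.get("contrasts", "all-pairwise")
    if contrasts_cfg == "all-pairwise":
        contrasts = _all_pairwise(list(targets))
    else:
        contrasts = tuple((c[0], c[1]) for c in contrasts_cfg)

    corr = raw.get("correlation")
    if corr is None and len(attributes) >= 2:
        corr = list(attributes)[:2]
    meta_cfg = raw.get("meta", {})
    return RunConfig(
        models=models,
        targets=targets,
        attributes=attributes,
        contrasts=contrasts,
        correlation=tuple(corr) if corr else None,
        lookup_policy=raw.get("lookup_policy", "exact-then-lowercase"),
        tau2_method=meta_cfg.get("tau2", "DL"),
        hedges=bool(meta_cfg.get("hedges", False)),
        output_dir=raw.get("output_dir"),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class ResultsBundle:
    """Everything one run produces, writable as CSV + manifest."""

    config: RunConfig
    tables: dict[tuple[str, str], ScoreTable]
    contrasts: list[GroupContrast]
    meta: dict[tuple[str, str, str], MetaResult]
    correlations: list[CorrelationEstimate] = field(default_factory=list)
    pooled_correlation: Optional[MetaResult] = None

    def scores_frame(self) -> pd.DataFrame:
        frames = [t.to_frame() for t in self.tables.values()]
        return pd.concat(frames, ignore_index=True)

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": c.model, "attribute": c.attribute,
                    "group1": c.group1, "group2": c.group2,
                    "n1": c.n1, "n2": c.n2, "d": c.d, "var_d": c.var_d,
                }
                for c in self.contrasts
            ]
        )

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for (attr, g1, g2), r in self.meta.items():
            rows.append(
                {
                    "attribute": attr, "group1": g1, "group2": g2, "k": r.k,
                    "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "z": r.z, "p": r.p, "tau2": r.tau2,
                    "Q": r.Q, "I2": r.I2, "method": r.method, "scale": r.scale,
                }
            )
        if self.pooled_correlation is not None:
            r = self.pooled_correlation
            a, b = self.config.correlation
            rows.append(
                {
                    "attribute": f"corr({a},{b})", "group1": "", "group2": "", "k": r.k,
                    "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "z": r.z, "p": r.p, "tau2": r.tau2,
                    "Q": r.Q, "I2": r.I2, "method": r.method, "scale": r.scale,
                }
            )
        return pd.DataFrame(rows)

    def attrition_summary(self) -> dict:
        out: dict = {}
        for (model, attr), table in self.tables.items():
            for lex, rep in table.attrition.items():
                if rep.n_missing:
                    out.setdefault(model, {}).setdefault(attr, {})[lex] = list(rep.missing)
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores_frame().to_csv(outdir / "scores.csv", index=False)
        self.contrasts_frame().to_csv(outdir / "contrasts.csv", index=False)
        self.meta_frame().to_csv(outdir / "meta.csv", index=False)
        manifest = {
            "specbias_version": __version__,
            "seed": self.config.seed,
            "lookup_policy": self.config.lookup_policy,
            "tau2_method": self.config.tau2_method,
            "hedges": self.config.hedges,
            "models": [m.name for m in self.config.models],
            "attributes": list(self.config.attributes),
            "contrasts": [list(c) for c in self.config.contrasts],
            "attrition": self.attrition_summary(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run(config: RunConfig) -> ResultsBundle:
    """Execute the full audit described by the config."""
    models = []
    for entry in config.models:
        try:
            models.append(load_embeddings(entry.path, entry.format, name=entry.name))
        except Exception as exc:
            raise RuntimeError(f"model {entry.name!r} failed to load: {exc}") from exc

    targets = list(config.targets.items())
    tables: dict[tuple[str, str], ScoreTable] = {}
    for model in models:
        for attr_name, attr in config.attributes.items():
            try:
                tables[(model.name, attr_name)] = score_model(
                    model, targets, attr, policy=config.lookup_policy
                )
            except ValueError as exc:
                warnings.warn(f"model {model.name!r} skipped for {attr_name!r}: {exc}")
                log.warning("model %s skipped for %s: %s", model.name, attr_name, exc)

    all_contrasts: list[GroupContrast] = []
    meta: dict[tuple[str, str, str], MetaResult] = {}
    for attr_name in config.attributes:
        for g1, g2 in config.contrasts:
            per_model = []
            for model in models:
                table = tables.get((model.name, attr_name))
                if table is None:
                    continue
                try:
                    per_model.append(
                        contrast_model(table, g1, g2, hedges=config.hedges)
                    )
                except ValueError as exc:
                    warnings.warn(
                        f"model {model.name!r} dropped from {g1} vs {g2} ({attr_name}): {exc}"
                    )
            if not per_model:
                raise RuntimeError(
                    f"contrast {g1} vs {g2} ({attr_name}) supported by no model"
                )
            all_contrasts.extend(per_model)
            meta[(attr_name, g1, g2)] = pool(per_model, method=config.tau2_method)

    correlations: list[CorrelationEstimate] = []
    pooled_corr = None
    if config.correlation is not None:
        a, b = config.correlation
        for model in models:
            ta, tb = tables.get((model.name, a)), tables.get((model.name, b))
            if ta is None or tb is None:
                continue
            try:
                correlations.append(score_correlation(ta, tb))
            except ValueError as exc:
                warnings.warn(f"model {model.name!r} dropped from correlation: {exc}")
        if correlations:
            pooled_corr = pool_correlations(correlations, method=config.tau2_method)

    bundle = ResultsBundle(
        config=config, tables=tables, contrasts=all_contrasts, meta=meta,
        correlations=correlations, pooled_correlation=pooled_corr,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
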