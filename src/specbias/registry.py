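"""Default model registry: metadata for the seven embedding models the audit
was designed around (internet, news, Wikipedia, Twitter, TV/film, books and
conversation corpora).  Metadata only — the vector files are multi-gigabyte
external downloads the user supplies; ``path`` stays None until configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

__all__ = ["ModelInfo", "default_registry"]


@dataclass(frozen=True)
class ModelInfo:
    name: str
    description: str
    medium: str
    algorithm: str
    format: str
    tokens_approx: float
    time_period: str
    path: Optional[str] = None


def default_registry() -> tuple[ModelInfo, ...]:
    """The seven default models, in registry order."""
    ref = resources.files("specbias") / "data" / "models.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return tuple(
        ModelInfo(**{**entry, "tokens_approx": float(entry["tokens_approx"])})
        for entry in raw["models"]
    )
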