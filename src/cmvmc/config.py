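"""Run configuration: one YAML file mirroring every CLI flag.

Sections: ``views`` (normalization), ``amosa`` (cooling schedule and
archive bounds), ``consensus`` (similarity combination), ``ensemble``
(vote threshold), ``evaluate`` (accuracy mapping), plus a global ``seed``.
CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .amosa import AnnealConfig


@dataclass
class CmvmcConfig:
    seed: int = 0
    views: dict = field(default_factory=lambda: {"normalize": "minmax"})
    amosa: AnnealConfig = field(default_factory=AnnealConfig)
    consensus: dict = field(default_factory=lambda: {"combine": "mean"})
    ensemble: dict = field(default_factory=lambda: {"threshold": 0.5})
    evaluate: dict = field(default_factory=lambda: {"mapping": "modal"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CmvmcConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CmvmcConfig":
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        amosa_raw = dict(raw.get("amosa", {}))
        amosa_raw.pop("seed", None)  # the global seed governs all randomness
        # accept the short YAML keys sl/hl as aliases
        if "sl" in amosa_raw:
            amosa_raw["soft_limit"] = amosa_raw.pop("sl")
        if "hl" in amosa_raw:
            amosa_raw["hard_limit"] = amosa_raw.pop("hl")
        cfg.amosa = AnnealConfig(**amosa_raw)
        for section in ("views", "consensus", "ensemble", "evaluate"):
            getattr(cfg, section).update(raw.get(section, {}))
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        return out
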