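"""Pipeline configuration: typed, serialisable, unknown keys rejected."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError
from .stim import StimProtocol

__all__ = ["SsnaConfig", "CvnaConfig", "PipelineConfig", "config_hash"]


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SsnaConfig:
    """Spike-chain parameters (band-pass + notch, noise-floor threshold)."""

    band: tuple[float, float] = (300.0, 1000.0)
    order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0
    k: float = 3.0
    refractory_s: float = 0.001


@dataclass(frozen=True)
class CvnaConfig:
    """Burst-chain parameters (strict band-pass, leaky integration, merging)."""

    band: tuple[float, float] = (300.0, 550.0)
    order: int = 4
    tau_s: float = 0.1
    env_k: float = 2.0
    min_separation_s: float = 0.2
    merge_gap_s: float = 0.3


@dataclass(frozen=True)
class PipelineConfig:
    input: str | None = None
    nerve_channel: str = "nerve"
    bp_channel: str | None = None
    postmortem_label: str = "postmortem"
    ssna: SsnaConfig = field(default_factory=SsnaConfig)
    cvna: CvnaConfig = field(default_factory=CvnaConfig)
    stim: StimProtocol = field(default_factory=StimProtocol)
    bin_s: float = 600.0
    seed: int = 0
    out_dir: str = "out"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "ssna" in data:
            sub = dict(data["ssna"])
            if "band" in sub:
                sub["band"] = tuple(sub["band"])
            data["ssna"] = _from_dict(SsnaConfig, sub)
        if "cvna" in data:
            sub = dict(data["cvna"])
            if "band" in sub:
                sub["band"] = tuple(sub["band"])
            data["cvna"] = _from_dict(CvnaConfig, sub)
        if "stim" in data:
            data["stim"] = _from_dict(StimProtocol, dict(data["stim"]))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration, embedded in every output."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
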