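"""Run configuration: YAML in, resolved sidecar out, seed fan-out.

A run has one global seed; every stochastic component draws from a
named substream derived from it, so data generation, weight
initialization and loop draws are independently reproducible.  Every
command writes back the fully resolved configuration (defaults
included) as ``config.resolved.yaml``; re-running from that sidecar
reproduces the run exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .gan_core import TrainingConfig
from .loop_learning import LoopConfig
from .synthetic_data import SyntheticSpec


def substream_seed(seed: int, name: str) -> int:
    """Deterministic child seed for a named substream (below 2^31)."""
    return (zlib.crc32(name.encode()) ^ (seed * 2654435761)) % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    split_fraction: float = 0.8
    split_mode: str = "matrix_level"
    augment: bool = False
    scale: bool = True
    synth: SyntheticSpec = field(default_factory=SyntheticSpec)
    gan: TrainingConfig = field(default_factory=TrainingConfig)
    loop: LoopConfig = field(default_factory=LoopConfig)

    def resolve_seeds(self) -> "RunConfig":
        self.synth.seed = substream_seed(self.seed, "data")
        self.gan.seed = substream_seed(self.seed, "init")
        self.loop.seed = substream_seed(self.seed, "loop-draws")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gan"]["betas"] = list(d["gan"]["betas"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {"synth": SyntheticSpec, "gan": TrainingConfig, "loop": LoopConfig}
        kwargs = {}
        for name, typ in sub.items():
            if name in d:
                section = dict(d.pop(name))
                if name == "gan" and "betas" in section:
                    section["betas"] = tuple(section["betas"])
                valid = {f.name for f in fields(typ)}
                unknown = set(section) - valid
                if unknown:
                    raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
                kwargs[name] = typ(**section)
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def write_sidecar(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config.resolved.yaml"
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
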