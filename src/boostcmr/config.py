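"""Run configuration: one YAML-serializable object driving the pipelines.

All lengths are mm, times ms, angles degrees.  Every random operation
consumes a named seed derived from ``seed`` so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .phantom import PhantomSpec, RespiratoryModel, Vial, default_phantom
from .sequences import SequenceParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    sequence: SequenceParams = field(default_factory=SequenceParams)
    phantom: PhantomSpec = field(default_factory=default_phantom)
    respiration: RespiratoryModel = field(default_factory=RespiratoryModel)
    noise_sigma: float = 0.05
    seed: int = 0
    n_lines_per_beat_acq: int = 32
    normalize: bool = False
    motion_correction: bool = True
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sequence" in d:
            d["sequence"] = SequenceParams(**d["sequence"])
        if "phantom" in d:
            p = dict(d["phantom"])
            p["matrix"] = tuple(p.get("matrix", (3, 192, 192)))
            p["fov_mm"] = tuple(p.get("fov_mm", (320.0, 320.0)))
            p["vials"] = tuple(
                Vial(tuple(v["center_mm"]), v["radius_mm"], v["label"])
                for v in p.get("vials", ()))
            d["phantom"] = PhantomSpec(**p)
        if "respiration" in d:
            d["respiration"] = RespiratoryModel(**d["respiration"])
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full configuration."""
    dump = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(dump.encode()).hexdigest()[:12]


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
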