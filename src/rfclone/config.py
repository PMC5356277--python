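"""Run configuration: every tunable the simulation depends on, in one
record, loadable from YAML and echoed into reports for reproducibility."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Config:
    """Toolkit configuration with field defaults.

    k: cohesive-end length in nt (policy range 5-8; midpoint default).
    body_target / body_window: primer-body length target and search window.
    tm_model: "nn" (nearest-neighbor) or "gc_fallback".
    min_core: minimum perfect complementary core for strand annealing, nt.
    large_insert_threshold_bp: insert size at which the ligation policy
        switches from vector:insert 1:3 to 6:1.
    anchor_offset_a / anchor_offset_b: which anchor base is the junction
        ("start" or "end") when sites are given as anchors.
    """

    k: int = 6
    relax_k: bool = False
    body_target: int = 25
    body_window: tuple[int, int] = (20, 32)
    tm_model: str = "nn"
    min_core: int = 15
    large_insert_threshold_bp: int = 10_000
    anchor_offset_a: str = "end"
    anchor_offset_b: str = "start"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {f: data[f] for f in cls.__dataclass_fields__ if f in data}
        if "body_window" in known:
            known["body_window"] = tuple(known["body_window"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["body_window"] = list(d["body_window"])
        return d

    def replace(self, **kwargs) -> "Config":
        d = {**asdict(self), **{k: v for k, v in kwargs.items() if v is not None}}
        return Config.from_dict(d)
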