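"""Run configuration: one structured-text (YAML) object drives a full run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .kinematics import G_DEFAULT, MotionLaw
from .observer import CohortSpec
from .optics import ObserverGeometry

_LAW_KEYS = {law.value: law for law in MotionLaw}


@dataclass(frozen=True)
class Seeds:
    """Every source of randomness in a run, explicit."""

    schedule: int = 100
    cohort: int = 10
    responses: int = 200
    bootstrap: int = 300


@dataclass(frozen=True)
class RunConfig:
    gravity: float = G_DEFAULT
    frame_rate: float = 75.0
    observer: ObserverGeometry = field(default_factory=ObserverGeometry)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    replications: int = 15
    rt_max: float = 10.0
    bootstrap_B: int = 1000
    seeds: Seeds = field(default_factory=Seeds)

    def to_dict(self) -> dict:
        d = asdict(self)
        for block in ("jnd_mean", "jnd_sd", "pse_mean", "pse_sd"):
            d["cohort"][block] = {
                law.value: v for law, v in d["cohort"][block].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        obs = ObserverGeometry(**d.pop("observer", {}))
        cd = dict(d.pop("cohort", {}))
        for block in ("jnd_mean", "jnd_sd", "pse_mean", "pse_sd"):
            if block in cd:
                cd[block] = {_LAW_KEYS[k]: float(v) for k, v in cd[block].items()}
        cohort = CohortSpec(**cd)
        seeds = Seeds(**d.pop("seeds", {}))
        return cls(observer=obs, cohort=cohort, seeds=seeds, **d)

    def hash(self) -> str:
        """Short stable digest of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
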