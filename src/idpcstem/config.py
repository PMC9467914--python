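"""Run configuration and provenance records.

A RunConfig captures everything needed to reproduce a simulation: beam,
scan, detector, phantom choice, dose and seed.  It round-trips losslessly
through YAML.  A RunRecord snapshots the config together with the derived
acquisition plan, software version and a timestamp, and is emitted alongside
every output artifact so any stochastic output is reproducible from the
record alone.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field

import yaml

from . import __version__
from .optics import AberrationCoefficients, BeamParameters, ScanGeometry, ScanPlan
from .scan_detector import DetectorGeometry

__all__ = ["RunConfig", "RunRecord"]


@dataclass(frozen=True)
class RunConfig:
    beam: BeamParameters
    scan: ScanGeometry
    detector: DetectorGeometry
    phantom_name: str
    phantom_params: dict = field(default_factory=dict)
    total_dose: float = 35.0  # e−/Å²
    seed: int = 0
    output_prefix: str = "run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        beam = d["beam"]
        ab = AberrationCoefficients(**beam.pop("aberrations", {}))
        return cls(
            beam=BeamParameters(aberrations=ab, **beam),
            scan=ScanGeometry(**d["scan"]),
            detector=DetectorGeometry(**d["detector"]),
            phantom_name=d["phantom_name"],
            phantom_params=d.get("phantom_params", {}),
            total_dose=d.get("total_dose", 35.0),
            seed=d["seed"],
            output_prefix=d.get("output_prefix", "run"),
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class RunRecord:
    config: RunConfig
    plan: ScanPlan
    software_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat())

    def to_json(self, path: str) -> None:
        d = {
            "config": self.config.to_dict(),
            "plan": dataclasses.asdict(self.plan),
            "software_version": self.software_version,
            "timestamp": self.timestamp,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=RunConfig.from_dict(d["config"]),
                   plan=ScanPlan(**d["plan"]),
                   software_version=d["software_version"],
                   timestamp=d["timestamp"])
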