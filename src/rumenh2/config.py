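"""Run configuration: YAML in, YAML out, echoed next to every result set."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .conversions import PhysicalConstants
from .sinks import GwpCoefficients, MicrobialH2Config, NitratePathwayConfig


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the input records."""

    scenario: str = "both"  # "SC1" | "SC2" | "both" (ledgers always carry both)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    gwp: GwpCoefficients = field(default_factory=GwpCoefficients)
    nitrate: NitratePathwayConfig = field(default_factory=NitratePathwayConfig)
    microbial: MicrobialH2Config = field(default_factory=MicrobialH2Config)
    #: treatment -> [2H] sink (mmol/d) for nitrate-dosed treatments
    nitrate_sink: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("SC1", "SC2", "both"):
            raise ValueError(f"scenario must be SC1, SC2 or both, got {self.scenario!r}")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "constants": asdict(self.constants),
            "gwp": dict(self.gwp.gwp),
            "nitrate": asdict(self.nitrate),
            "microbial": asdict(self.microbial),
            "nitrate_sink": dict(self.nitrate_sink),
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            scenario=data.get("scenario", "both"),
            constants=PhysicalConstants(**data.get("constants", {})),
            gwp=GwpCoefficients(data["gwp"]) if "gwp" in data else GwpCoefficients(),
            nitrate=NitratePathwayConfig(**data.get("nitrate", {})),
            microbial=MicrobialH2Config(**data.get("microbial", {})),
            nitrate_sink=dict(data.get("nitrate_sink", {})),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
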