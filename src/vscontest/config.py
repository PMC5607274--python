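"""Pipeline configuration: one structured block per stage.

Every threshold of the cascade lives here with its default, so a run is
fully described by its resolved config file; ``run_pipeline`` writes
that resolved YAML next to its outputs.  Unknown keys are rejected
rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError
from .simulate import SimulationConfig


@dataclass
class ScreeningParams:
    abs_threshold: float = 25.0   # % inhibition floor, first screen
    k_sd: float = 3.0             # plate mean + k_sd * plate SD rule
    second_threshold: float = 50.0  # % inhibition, second screen


@dataclass
class CurationParams:
    ic50_max: float = 10.0
    ki_max: float = 10.0
    kd_max: float = 10.0
    inhibition_min: float = 30.0
    promiscuity_min_targets: int = 5


@dataclass
class DoseResponseParams:
    hit_threshold_uM: float = 10.0
    min_span: float = 30.0
    trend_alpha: float = 0.05
    concentrations_uM: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_replicates: int = 3
    noise_sd: float = 5.0


@dataclass
class EvaluationParams:
    alpha: float = 0.05
    truncation_depth: int = 55


@dataclass
class ChemParams:
    k: int = 3
    hit_threshold: float = 50.0
    n_components: int = 2


@dataclass
class PipelineConfig:
    """Resolved configuration of a full contest run."""

    seed: int = 0
    output_dir: str = "vscontest_out"
    simulation: SimulationConfig = None
    curation: CurationParams = field(default_factory=CurationParams)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    chem: ChemParams = field(default_factory=ChemParams)

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        blocks = {"simulation": SimulationConfig, "curation": CurationParams,
                  "screening": ScreeningParams, "dose_response": DoseResponseParams,
                  "evaluation": EvaluationParams, "chem": ChemParams}
        top_level = {f.name for f in fields(cls)}
        unknown = set(data) - top_level
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for name, klass in blocks.items():
            if name in data:
                block = data.pop(name)
                allowed = {f.name for f in fields(klass)}
                bad = set(block) - allowed
                if bad:
                    raise ConfigurationError(
                        f"unknown key(s) in {name!r} block: {sorted(bad)}"
                    )
                kwargs[name] = klass(**block)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in list(data["simulation"].items()):
            if isinstance(val, tuple):
                data["simulation"][key] = list(val)
        data["dose_response"]["concentrations_uM"] = list(
            data["dose_response"]["concentrations_uM"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
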