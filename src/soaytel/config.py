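"""Run configuration: every pipeline threshold in one YAML-serialisable
object, with the protocol's printed values as defaults.

Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class QPCRConfig:
    threshold_tel: float = 0.222
    threshold_b2m: float = 0.193
    cv_limit: float = 0.05
    eff_dev_limit: float = 0.05
    n_baseline_cycles: int = 6
    baseline_negligible_frac: float = 0.02
    window_min: int = 4
    window_max: int = 6
    plateau_frac: float = 0.95
    qc_enabled: bool = True
    plate_mean_after_sample_qc: bool = False


@dataclass
class DNAQCConfig:
    min_yield_ng_per_ul: float = 20.0
    a260_280_min: float = 1.7
    a260_280_max: float = 2.0
    a260_230_min: float = 1.8
    a260_230_max: float = 2.2
    max_integrity: int = 2
    max_attempts: int = 2


@dataclass
class ModelConfig:
    estimation: str = "ML"  # ML | REML (LRT comparisons always use ML)
    alpha: float = 0.05


@dataclass
class PowerConfig:
    enabled: bool = False
    effect_grid: list = field(default_factory=lambda: [0.0, 0.006, 0.012, 0.018])
    n_reps: int = 200
    alpha: float = 0.05
    which: str = "pac"


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/out"
    population: dict = field(default_factory=dict)  # study_design() overrides
    plate: dict = field(default_factory=dict)  # QPCRPlateSpec overrides
    qpcr: QPCRConfig = field(default_factory=QPCRConfig)
    dna_qc: DNAQCConfig = field(default_factory=DNAQCConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    power: PowerConfig = field(default_factory=PowerConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build(cls, d, "config")

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = source
        d = yaml.safe_load(text) or {}
        return cls.from_dict(d)


def _build(cls, d, where):
    if not isinstance(d, dict):
        raise ParameterError(f"{where}: expected a mapping, got {type(d).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ParameterError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        sub = {"qpcr": QPCRConfig, "dna_qc": DNAQCConfig,
               "model": ModelConfig, "power": PowerConfig}.get(name)
        kwargs[name] = _build(sub, value, f"{where}.{name}") if sub else value
    return cls(**kwargs)
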