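"""Pipeline configuration: defaults, validation, YAML round trip."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import InvalidParameterError


@dataclass
class PipelineConfig:
    """All tunable constants of the end-to-end pipeline.

    Defaults encode the study conditions: blood density 1.06 g/cm^3 and
    viscosity 0.04 Poise, 120/80 mmHg pressure targets with 5% tolerance,
    1:9 proximal:distal resistance ratio, 5% limit-cycle and
    mesh-convergence tolerances with ~10% edge decrements, MTLSA
    thresholds {50, 70, 90}%, and a significance level of 0.1.
    """

    density: float = 1.06
    viscosity: float = 0.04

    mean_flow: float = 4.0
    pulsatility_index: float = 1.0
    heart_rate: float = 60.0

    outlet_areas: list[float] = field(default_factory=lambda: [0.05, 0.03])
    systolic_mmhg: float = 120.0
    diastolic_mmhg: float = 80.0
    pressure_tol: float = 0.05
    proximal_fraction: float = 0.1
    p_ref: float = 0.0
    max_tuning_iter: int = 100

    limit_cycle_tol: float = 0.05
    convergence_tol: float = 0.05
    refinement_factor: float = 0.9
    n_refinements: int = 4

    mtlsa_percents: list[int] = field(default_factory=lambda: [50, 70, 90])
    lsa_sd_multiplier: float = 1.0

    n_pairs: int = 11
    effect_metric: str = "MTLSA_70"
    effect_size: float = 0.0
    noise_sd: float | None = None  # None -> per-metric defaults
    alpha: float = 0.1

    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        for name in ("pressure_tol", "limit_cycle_tol", "convergence_tol", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.refinement_factor < 1.0:
            raise InvalidParameterError("refinement_factor must be in (0, 1)")
        if list(self.mtlsa_percents) != sorted(self.mtlsa_percents):
            raise InvalidParameterError("mtlsa_percents must be sorted ascending")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
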