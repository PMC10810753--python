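"""Pipeline configuration: one YAML-serializable object holding every
constant of the study design and analysis chain."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .gaze import ExtractionParams
from .synthetic import GazeParams


@dataclass
class PipelineConfig:
    """End-to-end settings with defaults mirroring the study dimensions:
    155 MZ / 130 DZ same-sex pairs (~12% incomplete), six 20-s trials at
    120 Hz, five AOIs (chance level 1/5), validity thresholds of 25%
    valid samples / 5 s of data / >= 4 valid trials, a 10-s exploration
    window, and FDR q = 0.05."""

    seed: int = 1
    n_mz: int = 155
    n_dz: int = 130
    incomplete_rate: float = 0.12
    # generating bivariate AE structure (trait 1: orienting, trait 2: preference)
    gen_a11_sq: float = 0.19
    gen_shared_a_sq: float = 0.16
    gen_unique_a_sq: float = 0.29
    gen_unique_e_share: float = 0.97
    gaze: GazeParams = field(default_factory=GazeParams)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    n_aois: int = 5
    fdr_q: float = 0.05
    outcome_beta: float = 0.14
    outcome_pair_corr: float = 0.3
    standardize_phenotypes: bool = False
    out_dir: str = "twinlook_out"

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_aois

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("need at least one pair per zygosity")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        ExtractionParams(**asdict(self.extraction))  # re-runs threshold checks

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "gaze" in payload:
            payload["gaze"] = GazeParams(**payload["gaze"])
        if "extraction" in payload:
            payload["extraction"] = ExtractionParams(**payload["extraction"])
        return cls(**payload)
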