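"""Run configuration: every stage parameter in one serializable object.

All protocol constants and thresholds live here with their standard defaults
(barcode 6 bp, UMI 7 bp, Read 1 20 bp, Read 2 50 bp, transcript window
[5000, 60000], min genes 500, max mito 0.05, specificity call 0.9, 4 PCs,
clustering resolution 1.5, |log2FC| 0.25, alpha 0.05) and can be overridden
from a YAML file or keyword arguments. A copy of the effective configuration
is written into every output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .barnyard import QCThresholds
from .expression import AnalysisParams


@dataclass
class SimulationParams:
    n_genes_per_species: int = 150
    transcript_length: int = 300
    mito_fraction: float = 0.02
    n_cells_per_species: int = 96
    n_negative: int = 32
    n_doublets: int = 0
    conditions: dict[str, int] | list[str] | None = None
    mean_molecules_per_cell: int = 5000
    ambient_fraction: float = 0.05
    dispersion: float = 0.1
    duplication_mean: float = 3.0
    error_rate: float = 0.002
    profile_sigma: float = 1.0
    doublet_ratio: float = 1.0


@dataclass
class PipelineParams:
    barcode_len: int = 6
    umi_len: int = 7
    read1_len: int = 20
    read2_len: int = 50
    index_k: int = 21
    max_mismatches: int = 2


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "platepool_run"
    log_level: str = "INFO"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key, sub in (
            ("simulation", SimulationParams),
            ("pipeline", PipelineParams),
            ("qc", QCThresholds),
            ("analysis", AnalysisParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                valid = {f.name for f in dataclasses.fields(sub)}
                unknown = set(kwargs[key]) - valid
                if unknown:
                    raise ValueError(f"unknown {key} parameters: {sorted(unknown)}")
                kwargs[key] = sub(**kwargs[key])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
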