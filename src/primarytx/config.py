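"""One YAML configuration governing the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .expression_de import DEParams
from .srna_discovery import SrnaParams
from .synthetic_data import SimulationParams
from .transcript_annotation import ReannotationParams, UTRParams
from .tss_core import ClassificationParams, TSSDetectionParams


@dataclass
class LibrarySpec:
    path: str
    library_id: str
    medium: str
    timepoint: str
    tex: bool


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    annotation_gff3: str = ""
    libraries: list[LibrarySpec] = field(default_factory=list)
    operon_table: str | None = None
    known_srnas: str | None = None
    output_dir: str = "out"
    seed: int = 42
    operon_alpha: float = 0.5
    detection: TSSDetectionParams = field(default_factory=TSSDetectionParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    utr: UTRParams = field(default_factory=UTRParams)
    reannotation: ReannotationParams = field(default_factory=ReannotationParams)
    de: DEParams = field(default_factory=DEParams)
    srna: SrnaParams = field(default_factory=SrnaParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("utr", "reannotation"):  # tuples -> lists for clean YAML
            data[key] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        kwargs["libraries"] = [LibrarySpec(**d) for d in data.get("libraries", [])]
        blocks = {
            "detection": TSSDetectionParams,
            "classification": ClassificationParams,
            "utr": UTRParams,
            "reannotation": ReannotationParams,
            "de": DEParams,
            "srna": SrnaParams,
            "simulation": SimulationParams,
        }
        for key, klass in blocks.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                block = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in kwargs[key].items()
                }
                kwargs[key] = klass(**block)
        return cls(**kwargs)
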