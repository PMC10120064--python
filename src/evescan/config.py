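"""Pipeline configuration: one YAML file with per-stage sections.

Defaults equal the values used throughout the modules; unknown keys are
rejected so typos fail loudly. The effective configuration is echoed into
every output directory together with a content hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class ScanConfig:
    min_identity: float = 23.0
    min_aa_len: int = 100
    evalue_max: float = 1e-12
    frameshift_penalty: float = 15.0
    translation_table: int = 1
    overlap_fraction: float = 0.5


@dataclass
class AnnotateConfig:
    flank: int = 30000
    evalue: float = 1e-4
    coverage: float = 0.7
    gc_window: int = 500
    gc_step: int = 100
    gc_threshold: float = 0.05
    gc_min_run: int = 5000
    tir_min_len: int = 20
    tir_min_identity: float = 0.85
    tir_max_pairs: int = 3


@dataclass
class CensusConfig:
    count_mcp_as_viral_gene: bool = True


@dataclass
class ClusterConfig:
    min_identity: float = 0.90
    min_coverage: float = 0.8
    alphabet: str = "nt"


@dataclass
class NetworkConfig:
    evalue_cutoff: float = 1e-4
    min_score: float = 6.0


@dataclass
class PipelineConfig:
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    census: CensusConfig = field(default_factory=CensusConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, values in (data or {}).items():
            if section not in sections:
                raise ValueError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            known = {f.name for f in dataclasses.fields(target)}
            for key, value in (values or {}).items():
                if key not in known:
                    raise ValueError(
                        f"unknown key {key!r} in config section {section!r}")
                if isinstance(getattr(target, key), tuple) and isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
            # re-run validation
            post = getattr(target, "__post_init__", None)
            if post is not None:
                post()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {f.name: dataclasses.asdict(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
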