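"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .synthetic_data import DEFAULT_STAGES

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All paths, thresholds and the seed for one pipeline run.

    Either ``simulate`` holds synthetic-generator overrides (inputs are
    then generated under the output directory) or the six FASTQ paths,
    the genome FASTAs, the annotation tables and the spike FASTA must be
    given and exist at launch.
    """

    outdir: str = "trfscape_out"
    seed: int = 0
    stage_names: tuple[str, ...] = DEFAULT_STAGES

    # inputs (ignored when simulate is set)
    fastq: dict[str, str] = field(default_factory=dict)  # stage -> path
    mito_fasta: str | None = None
    nuclear_fasta: str | None = None
    mito_annotation: str | None = None
    nuclear_annotation: str | None = None
    nuclear_annotation_bacterial: str | None = None
    spike_fasta: str | None = None

    # synthetic-data overrides; None means "use real inputs"
    simulate: dict[str, Any] | None = None

    # filtering thresholds
    min_quality: float = 20.0
    quality_mode: str = "mean"  # mean | min
    min_count: int = 5
    per_stage_abundance: bool = False
    min_length: int = 25
    max_length: int = 45

    # catalog curation
    edge_margin: int = 5
    anticodon_position: int | None = 33  # mature anticodon start hint
    stem_width: int = 5

    # mapping / ambiguity
    mito_other_genomic_filter: bool = False

    # classification
    anchor_tolerance_5p: int = 2
    anchor_tolerance_3p: int = 2
    stem_loop_slack: int = 3
    main_region_fraction: float = 0.25
    top_k_variants: int = 3
    alignment_min_count: int | None = None

    # expression
    trend_rho_threshold: float = 0.8
    trend_egg_share: float = 0.5
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.stage_names = tuple(self.stage_names)
        if len(self.stage_names) != 6:
            raise ConfigError("exactly six stage names are required")
        if self.quality_mode not in ("mean", "min"):
            raise ConfigError(f"unknown quality_mode {self.quality_mode!r}")
        if self.min_length > self.max_length:
            raise ConfigError("min_length > max_length")

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stage_names"] = list(self.stage_names)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the same
        analysis in two directories hashes identically)."""
        d = self.to_dict()
        for key in (
            "outdir", "fastq", "mito_fasta", "nuclear_fasta",
            "mito_annotation", "nuclear_annotation",
            "nuclear_annotation_bacterial", "spike_fasta",
        ):
            d.pop(key, None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def validate_inputs(self) -> None:
        """Check every referenced input path exists (real-data mode)."""
        if self.simulate is not None:
            return
        missing = []
        required = {
            "mito_fasta": self.mito_fasta,
            "nuclear_fasta": self.nuclear_fasta,
            "mito_annotation": self.mito_annotation,
            "nuclear_annotation": self.nuclear_annotation,
            "spike_fasta": self.spike_fasta,
        }
        for stage in self.stage_names:
            required[f"fastq[{stage}]"] = self.fastq.get(stage)
        if self.nuclear_annotation_bacterial is not None:
            required["nuclear_annotation_bacterial"] = self.nuclear_annotation_bacterial
        for name, path in required.items():
            if path is None:
                missing.append(f"{name} (not set)")
            elif not Path(path).exists():
                missing.append(f"{name}: {path}")
        if missing:
            raise ConfigError("missing input path(s): " + "; ".join(missing))
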