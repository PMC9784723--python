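"""Single versioned configuration carrying every pipeline threshold."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one place.

    The filter boundaries preserved from the source protocol: transcripts
    kept at MQ > 30, detection at RPM > 2, homology hits kept at > 80%
    identity and > 80% query coverage.
    """

    schema_version: int = SCHEMA_VERSION
    seed: int = 1
    genome_length: int = 1_000_000
    mq_cutoff: int = 30
    rpm_cutoff: float = 2.0
    copy_identity: float = 0.80
    copy_coverage: float = 0.80
    overlap_threshold: float = 0.80
    flank: int = 1000
    cnv_fold: float = 2.0
    min_orf_aa: int = 80
    min_ltr_identity: float = 0.80
    cluster_k: int = 15
    cluster_sim_threshold: float = 0.04
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known and k != "extra"}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
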