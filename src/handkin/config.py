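"""Pipeline configuration: defaults, YAML/JSON loading, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from typing import Dict, Optional, Tuple

import yaml

from .exceptions import ValidationError

PACKAGE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """All tunables of the simulate -> sync -> kinematics -> agreement pipeline.

    Every default is explicit here and echoed (with a content hash) into the
    metadata of every output file, so a result is reproducible from its own
    provenance record.
    """

    # study shape
    n_subjects: int = 10
    trials_per_subject: int = 2
    static_trials_per_subject: int = 1
    seed: int = 0
    # sensors (None -> module defaults)
    reference_rate_hz: float = 150.0
    test_rate_hz: float = 120.0
    test_jitter_cv: float = 0.1
    reference_noise_mm: float = 0.3
    test_noise_mm: float = 1.2
    test_dropout_prob: float = 0.01
    test_trial_bias_sd_deg: float = 2.0
    test_angular_bias_deg: Optional[Dict[str, float]] = None  # None -> defaults
    # processing
    target_rate_hz: float = 150.0
    n_normalization_points: int = 101
    # agreement
    ba_sign: str = "reference_minus_test"
    alpha: float = 0.05
    rom_pooling: str = "mean"
    measure: str = "rom"   # per-trial BA measure: "rom" | "mean" | "max"

    def __post_init__(self):
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValidationError("n_subjects and trials_per_subject must be >= 1")
        if self.static_trials_per_subject < 0:
            raise ValidationError("static_trials_per_subject must be >= 0")
        for name in ("reference_rate_hz", "test_rate_hz", "target_rate_hz"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be positive")
        if self.n_normalization_points < 2:
            raise ValidationError("n_normalization_points must be >= 2")
        if self.ba_sign not in ("reference_minus_test", "test_minus_reference"):
            raise ValidationError(f"unknown ba_sign {self.ba_sign!r}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.rom_pooling not in ("mean", "median"):
            raise ValidationError("rom_pooling must be 'mean' or 'median'")
        if self.measure not in ("rom", "mean", "max"):
            raise ValidationError("measure must be 'rom', 'mean' or 'max'")

    def to_dict(self) -> Dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def provenance(self) -> Dict:
        return {"config": self.to_dict(), "config_hash": self.config_hash(),
                "package_version": PACKAGE_VERSION}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
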