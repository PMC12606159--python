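"""Pipeline configuration: every analysis threshold in one place.

The defaults are the study's stated values — quality 3 and SNR > 10.5 dB
for measurability, 3 s bout gap, 0.7 correlation-pruning threshold with
aggregate entropy protected, 5-minute hourly windows, the 06:00/18:00
fixed day/night split, and the 8192-point / Hann / 90%-overlap
spectrogram.  Configs load from a YAML key-value document and serialize
back into run manifests so every threshold choice is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "DEFAULT_THRESHOLDS"]

#: Frozen table of the analysis constants the defaults must reproduce.
DEFAULT_THRESHOLDS = {
    "quality_required": 3,
    "snr_threshold_db": 10.5,
    "merge_gap_s": 0.1,
    "bout_gap_s": 3.0,
    "croak_growl_boundary_s": 0.5,
    "min_exemplars": 5,
    "correlation_threshold": 0.7,
    "window_minutes": 5,
    "day_start_hour": 6,
    "night_start_hour": 18,
    "n_dft": 8192,
    "overlap_fraction": 0.90,
    "band_low_hz": 20.0,
    "band_high_hz": 1000.0,
}


@dataclass
class PipelineConfig:
    # spectrogram
    sample_rate: int = 96000
    n_dft: int = 8192
    overlap_fraction: float = 0.90
    window_name: str = "hann"
    band_low_hz: float = 20.0
    band_high_hz: float = 1000.0
    bandpass_order: int = 4
    # screening
    quality_required: int = 3
    snr_threshold_db: float = 10.5
    # taxonomy
    merge_gap_s: float = 0.1
    bout_gap_s: float = 3.0
    croak_growl_boundary_s: float = 0.5
    min_exemplars: int = 5
    # classification
    correlation_threshold: float = 0.7
    always_keep: tuple[str, ...] = ("AE",)
    ridge: float = 1e-8
    # diel
    window_minutes: int = 5
    day_start_hour: int = 6
    night_start_hour: int = 18
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snr_threshold_db", "bout_gap_s", "correlation_threshold",
                     "window_minutes", "n_dft"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "always_keep" in doc:
            doc["always_keep"] = tuple(doc["always_keep"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["always_keep"] = list(d["always_keep"])
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
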