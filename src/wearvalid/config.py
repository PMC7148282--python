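"""Flat analysis configuration shared by every protocol stage.

Defaults follow the protocol's published operating points: EDA compared at
16 Hz with lags -8..+8 and a .80 correlation criterion, cardiac beat
detection at 200 Hz with the 5-15 Hz band-pass, RR/PP intervals kept in
[0.33, 1.5] s, SQI gates of 70 (long blocks) / 80 (beep windows) with a
consecutive 50% coverage requirement, a trough-to-peak SCR threshold of
0.01 uS, and a-priori agreement boundaries equal to 10% of the
biologically plausible range of each parameter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: biologically plausible ranges, in each parameter's own units
DEFAULT_PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "scl": (0.0, 16.0),          # uS
    "scr_rate": (0.0, 25.0),     # responses / min (high-arousal maximum)
    "s_ampl": (0.0, 6.0),        # uS, summed SCR amplitudes
    "hr": (60.0, 110.0),         # bpm, seated task
    "sd_interval": (0.0, 0.56),  # s
    "rmssd": (0.0, 0.71),        # s
}


@dataclass
class ProtocolConfig:
    """All tunable thresholds of the three-level protocol (flat keys)."""

    # sampling targets
    eda_fs: float = 16.0
    cva_fs: float = 200.0
    # signal level
    max_lag: int = 8
    corr_threshold: float = 0.80
    # EDA feature extraction
    scr_threshold: float = 0.01        # uS; exploratory alternative: 0.001
    scr_min_rise: float = 0.5          # s
    scr_max_rise: float = 5.0          # s
    eda_smooth_cutoff: float = 1.0     # Hz
    # cardiac feature extraction
    interval_min: float = 0.33         # s
    interval_max: float = 1.5          # s
    refractory: float = 0.25           # s
    sqi_window_len: float = 10.0       # s
    sqi_long: float = 70.0
    sqi_event: float = 80.0
    min_coverage: float = 0.5
    # parameter level
    boundary_fraction: float = 0.10
    boundary_decimals: int = 2
    log_offset: float = 1e-3
    transform_policy: str = "auto"     # auto | never
    plausible_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_PLAUSIBLE_RANGES)
    )
    # event level
    response_start: float = 1.0        # s after stimulus onset
    response_end: float = 6.0
    se_multiplier: float = 1.0
    event_baseline_len: float = 35.0   # s, duration-matched SSST baseline
    habituation_floor: float = 1e-4    # uS, floor before log
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.plausible_ranges = {
            k: tuple(v) for k, v in cfg.plausible_ranges.items()
        }
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["plausible_ranges"] = {
            k: list(v) for k, v in d["plausible_ranges"].items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        """Stable short hash of the configuration, for provenance."""
        d = asdict(self)
        d["plausible_ranges"] = {
            k: list(v) for k, v in d["plausible_ranges"].items()
        }
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
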