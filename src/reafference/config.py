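"""Analysis configuration with the study's printed parameter set as defaults."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


@dataclass
class AnalysisConfig:
    """Every numeric convention of the pipeline, in one place.

    Defaults are the analysis conventions: 2 s / 10 ms perievent grid,
    r2_adj threshold 0.35, 3x twitch and 5x wake EMG thresholds, 300 ms
    event refractory and wake-movement sustain, +-250 ms / 1 ms lag grid
    with p = 0.01 bands, and +-100 ms artifact masks.
    """

    psth_window: float = 2.0  # s
    psth_bin: float = 0.010  # s
    r2_threshold: float = 0.35
    twitch_mult: float = 3.0
    wake_mult: float = 5.0
    refractory: float = 0.3  # s
    sustain: float = 0.3  # s
    twitch_tau: float = 0.001  # s, EMG smoothing for the twitch path
    wake_tau: float = 0.01  # s, EMG smoothing for the wake path
    lag_half: float = 0.25  # s
    lag_bin: float = 0.001  # s
    band_p: float = 0.01
    mask_half_width: float = 0.1  # s
    ref_window: float = 0.2  # s, reference-spike selection around events
    min_bout: float = 5.0  # s
    baseline_offset: float = 2.0  # s, reliability baseline window start
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
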