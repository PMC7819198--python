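"""Run configuration with the system's published default settings.

Defaults: alarm-corpus minimum support 0.2, non-alarm 0.15, window length
L_e = 12 samples (1 h), shortest retained pattern L_min = L_e / 2 = 6,
thresholds 3.0 / 3.9 / 4.4 mmol/L, full-containment matching, one-window
refractory, 60-min attribution horizon. A plain key-value (YAML) file can
override any field; CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigurationError
from .events import WindowParams


@dataclass
class RunConfig:
    L_e: int = 12
    L_min: int = 6
    sampling_interval: float = 5.0
    minsup_alarm: float = 0.2
    minsup_non_alarm: float = 0.15
    thresholds: tuple[float, ...] = (3.0, 3.9, 4.4)
    match_ratio_min: float = 1.0
    refractory: int | None = None  # None -> L_e samples
    horizon: float = 60.0  # minutes
    overlap_ratio: float = 1.0
    seed: int = 0

    @property
    def window_params(self) -> WindowParams:
        return WindowParams(L_e=self.L_e, L_min=self.L_min,
                            sampling_interval=self.sampling_interval)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
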