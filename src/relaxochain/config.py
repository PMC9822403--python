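"""Run configuration: acquisition defaults, fit and inversion settings.

A :class:`RunConfig` gathers every knob the pipeline exposes and
round-trips losslessly through YAML, so a complete analysis is
reproducible from one small text file plus the input data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or invalid configuration key."""


@dataclass
class RunConfig:
    """All pipeline settings with benchtop-relaxometer defaults.

    Acquisition defaults describe a 23 MHz instrument running CPMG with
    0.3 ms echo time, ~1000 echoes, 16 scans, 250 kHz sampling and a
    10 s repetition delay.
    """

    frequency_mhz: float = 23.0
    echo_time_ms: float = 0.3
    n_echoes: int = 1000
    n_scans: int = 16
    sampling_khz: float = 250.0
    tr_s: float = 10.0
    fit_method: str = "nonlinear"
    grid_size: int = 64
    grid_lo_ms: float = 0.1
    grid_hi_ms: float = 10000.0
    lambda_reg: float = 1e-2
    noise_sigma_rel: float = 0.005
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        """Load a config from a YAML string or file path.

        Unknown keys are rejected with a message naming them and the
        valid alternatives.
        """
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(unknown)}; "
                f"valid keys are: {', '.join(sorted(known))}"
            )
        return cls(**raw)
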