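"""Run configuration: one flat key-value mapping with published defaults.

Every tunable of the pipeline lives here so a run is fully described by a
single small YAML file; CLI flags override file values which override
defaults.  Unknown keys are rejected by name to catch typos.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

CONFIG_VERSION = "1"

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Flat pipeline configuration.  All defaults are the published values."""

    # preprocessing
    channel: str = "B"
    resize_factor: float = 0.3
    std_limit: float = 0.5
    min_area_px: int = 50
    max_area_frac: float = 0.01
    target_dim: int = 64
    mitosis_second_basin_frac: float = 0.30
    mitosis_peak_merge_px: int = 5
    # descriptors
    sigma_divisor: str = "N"  # population std of the radial distances
    # gating rubric (upper bounds of the nested gates; weights are 1..5)
    gate_low: float = 0.1
    gate_mid: float = 0.2
    gate_cv_mid: float = 0.3
    gate_high: float = 0.5
    ds_cutoff: float = 3.0
    # synthetic database
    seed: int = 0
    n_per_template: int = 50
    template_base_size: int = 128
    scale_min: float = 0.5
    scale_max: float = 1.5
    pinch_max: float = 0.15
    twirl_max_deg: float = 25.0
    wave_amp_max: float = 0.06
    ripple_amp_max: float = 0.03
    distort_prob: float = 0.5
    version: str = CONFIG_VERSION

    def validate(self) -> "RunConfig":
        if not 0 < self.resize_factor <= 1:
            raise ValueError("resize_factor must be in (0, 1]")
        if self.sigma_divisor not in ("N", "N-1"):
            raise ValueError("sigma_divisor must be 'N' or 'N-1'")
        if self.min_area_px < 0 or self.max_area_frac <= 0:
            raise ValueError("area limits must be positive")
        if self.target_dim < 8:
            raise ValueError("target_dim too small")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a config file (YAML, flat mapping), apply overrides, validate.

    Missing keys fall back to defaults; an empty or absent file yields
    pure defaults; unknown keys raise with the offending name.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a key-value mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return RunConfig(**data).validate()


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the config as YAML; load_config round-trips it losslessly."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
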