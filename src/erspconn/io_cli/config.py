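"""Run configuration: YAML-backed, validated, hashable.

Every stage parameter defaults to the study's stated value: 0.5–48 Hz
band-pass, 200 µV frontal rejection, α/β/γ bands, 1000 ms multitaper
window with 100 ms step and 5 tapers, 1000 permutations.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..errors import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash"]

_DEFAULT_BANDS = {"alpha": [8.0, 14.0], "beta": [15.0, 35.0], "gamma": [35.0, 45.0]}


@dataclass
class RunConfig:
    """All stage parameters plus input/output paths."""

    out_dir: str = "results"
    seed: int = 0
    input_vhdr: list[str] = field(default_factory=list)  # empty → simulate

    # synth
    fs: float = 250.0
    n_subjects: int = 16
    n_trials_per_condition: int = 30
    noise_exponent: float = 1.0
    noise_sd_uv: float = 10.0
    white_sd_uv: float = 1.0
    effects: list[dict] = field(default_factory=list)

    # preprocess
    filter_lo_hz: float = 0.5
    filter_hi_hz: float = 48.0
    reject_threshold_uv: float = 200.0
    reject_channels: list[str] = field(
        default_factory=lambda: ["AFp1", "AFp2", "AFF5h", "AFF6h"]
    )
    reject_mode: str = "mean_deviation"
    ica_enabled: bool = False
    ica_max_iter: int = 200

    # ersp
    ersp_f_min: float = 1.0
    ersp_f_max: float = 45.0
    ersp_freq_step: float = 0.48
    ersp_time_step_ms: float = 100.0 / 3.0
    baseline_window_ms: list[float] = field(default_factory=lambda: [-4000.0, -2000.0])
    bands: dict = field(default_factory=lambda: dict(_DEFAULT_BANDS))

    # connectivity
    seeds: list[str] = field(default_factory=lambda: ["POO1", "POO2"])
    mt_window_ms: float = 1000.0
    mt_step_ms: float = 100.0
    mt_bandwidth: float = 3.0
    window_pooling: bool = False
    fisher_before_contrast: bool = False
    toi_window_ms: list[float] = field(default_factory=lambda: [1000.0, 2000.0])
    conn_baseline_window_ms: list[float] = field(
        default_factory=lambda: [-3000.0, -2000.0]
    )
    er_cicoh_eps: float = 1e-3

    # clusterstats
    n_perm: int = 1000
    alpha_cluster: float = 0.05
    alpha: float = 0.05
    neighbor_threshold: float | None = None
    neighbor_method: str = "distance"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be ≥ 1 (permutation test disabled otherwise)")
        if not 0 < self.filter_lo_hz < self.filter_hi_hz < self.fs / 2:
            raise ConfigError(
                "filter corners must satisfy 0 < lo < hi < fs/2; got "
                f"{self.filter_lo_hz}-{self.filter_hi_hz} at fs={self.fs}"
            )
        if self.reject_threshold_uv <= 0:
            raise ConfigError("rejection threshold must be positive")
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects for the paired test")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi < self.fs / 2:
                raise ConfigError(f"band {name} {lo}-{hi} Hz invalid at fs={self.fs}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full parameter set; changes with any parameter."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**payload)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
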