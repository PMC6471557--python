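"""Configuration objects for the simulation and analysis pipeline.

All tunable parameters of every stage live here, with the defaults the
analysis assumes: a six-channel dry-electrode montage sampled at 500 Hz,
two ~500-s load conditions, a 320-stimulus auditory oddball (25% targets,
inter-trial interval 2000 ms with a uniform ±1000 ms jitter) and a 30-s
artifact-free calibration lead-in used to calibrate the artifact-subspace
reconstruction stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Fixed channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz", "P3", "P4")

#: Canonical frequency bands (Hz, half-open edges ascending).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "low_beta": (12.0, 16.0),
}

#: Centre frequency (Hz) of the simulated oscillator for each band.
BAND_CENTERS: dict[str, float] = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 10.0,
    "low_beta": 14.0,
}

CONDITIONS: tuple[str, str] = ("low", "high")
STIMULI: tuple[str, str] = ("target", "standard")


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


def default_band_power_map() -> dict[str, dict[str, dict[str, float]]]:
    """Per-condition, per-band, per-channel oscillator amplitudes (µV).

    The load effect is carried by parieto-occipital oscillations: alpha at
    Pz and theta at Oz are stronger under low load (monitoring) than under
    high load (actively flying); all other amplitudes are load-invariant.
    """
    base = {
        "delta": 2.0,
        "theta": 1.5,
        "alpha": 2.0,
        "low_beta": 1.0,
    }
    bp = {
        cond: {band: {ch: amp for ch in CHANNELS} for band, amp in base.items()}
        for cond in CONDITIONS
    }
    bp["low"]["alpha"]["Pz"] = 5.0
    bp["high"]["alpha"]["Pz"] = 2.0
    bp["low"]["theta"]["Oz"] = 3.5
    bp["high"]["theta"]["Oz"] = 1.5
    return bp


def default_p300_channel_weights() -> dict[str, float]:
    """Relative P300 topography: parietal sites dominate frontal ones."""
    return {"Pz": 1.0, "P3": 0.9, "P4": 0.9, "Oz": 0.8, "Cz": 0.5, "Fz": 0.3}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic oddball flight-EEG generator.

    ``n_stimuli`` is the per-session total over both load conditions; each
    condition receives ``n_stimuli // 2`` stimuli with the exact target
    fraction applied per condition (320 stimuli → 80 targets / 240
    standards per session).
    """

    fs: float = 500.0
    channel_names: tuple[str, ...] = CHANNELS
    duration_per_condition: float = 500.0
    n_stimuli: int = 320
    target_fraction: float = 0.25
    iti_mean: float = 2000.0  # ms
    iti_jitter: float = 1000.0  # ms, half-range of uniform jitter
    band_power_map: dict = field(default_factory=default_band_power_map)
    p300_amplitude: dict = field(default_factory=lambda: {"low": 8.0, "high": 4.0})
    p300_latency: float = 0.45  # s, inside the 350-600 ms analysis window
    p300_width: float = 0.06  # s, Gaussian SD of the simulated deflection
    p300_channel_weights: dict = field(default_factory=default_p300_channel_weights)
    noise_exponent: float = 1.0  # PSD ∝ 1/f^exponent
    noise_rms: float = 10.0  # µV per channel, gives single-trial ERP SNR < 1
    spatial_correlation: float = 0.95  # inter-channel background correlation
    # (volume conduction makes scalp channels strongly correlated)
    artifact_rates: dict = field(default_factory=lambda: {"blink": 8.0, "burst": 1.0})
    blink_amplitude: float = 150.0  # µV peak at Fz
    burst_amplitude: float = 500.0  # µV peak
    calibration_duration: float = 30.0  # s of artifact-free lead-in
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.fs <= 0:
            raise ConfigError(f"fs must be > 0, got {self.fs}")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigError(
                f"target_fraction must be in [0, 1], got {self.target_fraction}"
            )
        if self.iti_jitter > self.iti_mean:
            raise ConfigError(
                f"iti_jitter ({self.iti_jitter}) must not exceed iti_mean "
                f"({self.iti_mean})"
            )
        if self.calibration_duration < 0:
            raise ConfigError("calibration_duration must be >= 0")
        if self.n_stimuli < 0:
            raise ConfigError("n_stimuli must be >= 0")
        for name in ("blink_amplitude", "burst_amplitude", "noise_rms"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for rate in self.artifact_rates.values():
            if rate < 0:
                raise ConfigError("artifact rates must be >= 0")
        for cond in self.band_power_map:
            for band in self.band_power_map[cond]:
                for ch, amp in self.band_power_map[cond][band].items():
                    if amp < 0:
                        raise ConfigError(
                            f"band amplitude < 0 for {cond}/{band}/{ch}"
                        )
        return self


@dataclass
class CleanRawParams:
    """Thresholds of the clean-raw-data artifact rejection stage.

    Defaults follow the lenient setting used for in-flight EEG: a burst
    criterion of 70 SD keeps ASR reconstruction conservative so that only
    gross artifacts are touched.
    """

    flatline_s: float = 5.0
    highpass_band: tuple[float, float] = (0.25, 0.75)  # Hz transition band
    channel_correlation: float = 0.85
    line_noise_z: float = 4.0
    burst_k: float = 70.0
    window_bad_fraction: float = 0.10
    window_len: float = 0.5  # s, ASR sliding-window length

    def validate(self) -> "CleanRawParams":
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise ConfigError("channel_correlation must be in [0, 1]")
        if not 0.0 <= self.window_bad_fraction <= 1.0:
            raise ConfigError("window_bad_fraction must be in [0, 1]")
        for name in ("flatline_s", "line_noise_z", "burst_k", "window_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        lo, hi = self.highpass_band
        if not 0 <= lo < hi:
            raise ConfigError("highpass_band must be an ascending pair")
        return self


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clean_raw: CleanRawParams = field(default_factory=CleanRawParams)
    asr_variant: str = "riemannian"
    pipeline: str = "freq"  # one of erp, freq, fused, continuous
    n_folds: int = 5
    n_csp_pairs: int = 2
    mrmr_k: int = 20
    erp_band: tuple[float, float] = (1.0, 15.0)
    fir_order: int = 250
    erp_window: tuple[float, float] = (0.0, 0.6)
    erp_fs: float = 50.0
    continuous_window_s: float = 2.0
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.simulation.validate()
        self.clean_raw.validate()
        if self.pipeline not in ("erp", "freq", "fused", "continuous"):
            raise ConfigError(f"unknown pipeline {self.pipeline!r}")
        if self.asr_variant not in ("classic", "riemannian"):
            raise ConfigError(f"unknown ASR variant {self.asr_variant!r}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        return self


def _update_dataclass(obj, values: Mapping):
    for key, val in values.items():
        if not hasattr(obj, key):
            raise ConfigError(f"unknown configuration key {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, Mapping):
            _update_dataclass(current, val)
        elif isinstance(current, tuple) and isinstance(val, Sequence):
            setattr(obj, key, tuple(val))
        else:
            setattr(obj, key, val)
    return obj


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = _update_dataclass(RunConfig(), raw)
    return cfg.validate()


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = _update_dataclass(SimulationConfig(), raw)
    return cfg.validate()
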