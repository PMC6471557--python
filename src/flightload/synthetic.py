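"""Synthetic oddball flight-EEG generator.

Emulates the statistical structure the downstream analysis assumes, so
every stage is testable without recorded data: a 1/f background, per-band
sinusoidal oscillators whose amplitudes differ between load conditions
(alpha at Pz and theta at Oz stronger under low load), a Gaussian-windowed
P300 positivity added at target onsets with a parietal-dominant topography
and a larger amplitude under low load, plus blink and motion-burst
artifacts injected only after the artifact-free calibration lead-in.

Everything is deterministic given the configuration seed: events, noise
and artifacts draw from independent child streams of one seed sequence, so
e.g. switching artifacts off does not shift the background noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    BAND_CENTERS,
    CONDITIONS,
    ConfigError,
    SimulationConfig,
)
from .recording_io import EventStream, Recording

__all__ = [
    "ArtifactEvent",
    "ArtifactLog",
    "generate_events",
    "erp_kernel",
    "generate_recording",
    "inject_artifacts",
    "simulate_session",
]

# stream ids for per-purpose child RNGs
_STREAM_EVENTS = 0
_STREAM_NOISE = 1
_STREAM_OSC = 2
_STREAM_ARTIFACTS = 3

_BLINK_TOPOGRAPHY = {"Fz": 1.0, "Cz": 0.45, "Pz": 0.15, "Oz": 0.05, "P3": 0.12, "P4": 0.12}


@dataclass
class ArtifactEvent:
    onset: float  # s
    duration: float  # s
    kind: str  # 'blink' | 'burst'
    channels: tuple[str, ...]
    peak_amplitude: float  # µV


class ArtifactLog(list):
    """Ground-truth list of injected :class:`ArtifactEvent` records."""

    def intervals(self) -> list[tuple[float, float]]:
        return [(ev.onset, ev.onset + ev.duration) for ev in self]


def _rng(config: SimulationConfig, condition: str, stream: int) -> np.random.Generator:
    cond_idx = CONDITIONS.index(condition) if condition in CONDITIONS else 7
    return np.random.default_rng([int(config.seed), cond_idx, stream])


def generate_events(
    config: SimulationConfig,
    condition: str,
    n_stimuli: int | None = None,
) -> EventStream:
    """Generate one condition's oddball stimulus stream.

    ``n_stimuli`` defaults to half the per-session total (one condition of
    two).  Exactly ``round(n · target_fraction)`` targets are placed by
    shuffled assignment; inter-onset intervals are uniform on
    ``iti_mean ± iti_jitter`` (ms); the first onset starts one mean
    interval after the calibration lead-in.
    """
    config.validate()
    if n_stimuli is None:
        n_stimuli = config.n_stimuli // 2
    rng = _rng(config, condition, _STREAM_EVENTS)

    n_targets = int(round(n_stimuli * config.target_fraction))
    labels = np.array(
        ["target"] * n_targets + ["standard"] * (n_stimuli - n_targets), dtype=object
    )
    rng.shuffle(labels)

    iti = rng.uniform(
        config.iti_mean - config.iti_jitter,
        config.iti_mean + config.iti_jitter,
        size=n_stimuli,
    ) / 1000.0
    onsets = config.calibration_duration + np.cumsum(iti)
    if n_stimuli and onsets[-1] + 1.0 > config.duration_per_condition:
        raise ConfigError(
            f"{n_stimuli} stimuli spanning {onsets[-1]:.1f} s (plus a 1-s epoch "
            f"tail) do not fit in duration_per_condition="
            f"{config.duration_per_condition} s after the "
            f"{config.calibration_duration}-s calibration lead-in"
        )
    return EventStream(
        onsets, labels, np.array([condition] * n_stimuli, dtype=object)
    )


def erp_kernel(amplitude: float, latency: float, width: float, fs: float) -> np.ndarray:
    """Gaussian-windowed positive deflection, peak ``amplitude`` at ``latency``.

    Returns samples from t = 0 to latency + 3·width; support is truncated
    at latency ± 3·width (exact zeros outside).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if latency < 0:
        raise ValueError("latency must be >= 0")
    n = int(round((latency + 3 * width) * fs)) + 1
    t = np.arange(n) / fs
    kernel = amplitude * np.exp(-0.5 * ((t - latency) / width) ** 2)
    kernel[np.abs(t - latency) > 3 * width] = 0.0
    return kernel


def _background_noise(
    rng: np.random.Generator,
    n_ch: int,
    n: int,
    fs: float,
    exponent: float,
    rms: float,
    spatial_correlation: float = 0.0,
) -> np.ndarray:
    """1/f^exponent (PSD) Gaussian background scaled to ``rms`` µV/channel.

    Channels share a common source with weight √ρ (volume-conduction-like
    spatial correlation ρ) plus an independent stream with weight √(1−ρ).
    """
    if rms <= 0:
        return np.zeros((n_ch, n))
    white = rng.standard_normal((n_ch + 1, n))
    if exponent == 0:
        streams = white
    else:
        spectrum = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-exponent / 2.0)
        streams = np.fft.irfft(spectrum * shaping, n=n, axis=1)
    rho = float(spatial_correlation)
    out = np.sqrt(rho) * streams[:1] + np.sqrt(1.0 - rho) * streams[1:]
    current = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    current[current == 0] = 1.0
    return out * (rms / current)


def _oscillations(
    rng: np.random.Generator,
    config: SimulationConfig,
    condition: str,
    n: int,
) -> np.ndarray:
    """Band-centre sinusoids, amplitude-fixed, random phase per 1-s block."""
    fs = config.fs
    channels = config.channel_names
    t = np.arange(n) / fs
    block = (t // 1.0).astype(int)  # 1-s phase blocks
    n_blocks = int(block[-1]) + 1 if n else 0
    out = np.zeros((len(channels), n))
    band_map = config.band_power_map.get(condition, {})
    for band, per_channel in band_map.items():
        f0 = BAND_CENTERS[band]
        # one phase per band and 1-s block, shared across channels: the
        # oscillator acts as a single source seen by all electrodes
        phases = rng.uniform(0, 2 * np.pi, size=n_blocks)
        phase_t = phases[block]
        amps = np.array([per_channel.get(ch, 0.0) for ch in channels])
        out += amps[:, None] * np.sin(2 * np.pi * f0 * t + phase_t)[None, :]
    return out


def generate_recording(
    config: SimulationConfig,
    events: EventStream,
    condition: str,
    with_artifacts: bool = True,
) -> tuple[Recording, ArtifactLog]:
    """Synthesize one condition's continuous recording.

    The pre-injection (clean) signal is kept in ``meta['pre_artifact_data']``
    as ground truth for artifact-removal tests.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration_per_condition * fs))
    channels = config.channel_names
    if len(events) and events.onset[-1] + 1.0 > config.duration_per_condition:
        raise ConfigError("events extend beyond the recording duration")

    noise = _background_noise(
        _rng(config, condition, _STREAM_NOISE),
        len(channels), n, fs, config.noise_exponent, config.noise_rms,
        config.spatial_correlation,
    )
    osc = _oscillations(_rng(config, condition, _STREAM_OSC), config, condition, n)
    signal = noise + osc

    amp = config.p300_amplitude.get(condition, 0.0)
    if amp > 0:
        kernel = erp_kernel(amp, config.p300_latency, config.p300_width, fs)
        weights = np.array(
            [config.p300_channel_weights.get(ch, 0.0) for ch in channels]
        )
        for onset in events.select("target").onset:
            start = int(round(onset * fs))
            stop = min(start + len(kernel), n)
            if start >= n:
                continue
            signal[:, start:stop] += weights[:, None] * kernel[: stop - start]

    recording = Recording(
        signal, fs, channels,
        meta={"condition": condition, "seed": int(config.seed)},
    )
    recording.meta["pre_artifact_data"] = recording.data.copy()
    if with_artifacts:
        recording, log = inject_artifacts(recording, config, condition=condition)
    else:
        log = ArtifactLog()
    return recording, log


def inject_artifacts(
    recording: Recording,
    config: SimulationConfig,
    condition: str = "low",
) -> tuple[Recording, ArtifactLog]:
    """Add blink and motion-burst artifacts outside the calibration lead-in.

    Blinks are low-frequency biphasic pulses with a frontal-dominant
    topography (Fz ≫ Pz); bursts are broadband high-amplitude noise on a
    random channel subset.  Every injected interval is logged.
    """
    rng = _rng(config, condition, _STREAM_ARTIFACTS)
    out = recording.copy()
    log = ArtifactLog()
    fs = recording.fs
    n = recording.n_samples
    t_start = config.calibration_duration
    t_end = recording.duration
    active_minutes = max(0.0, (t_end - t_start)) / 60.0

    specs = [
        ("blink", config.artifact_rates.get("blink", 0.0), 0.40, config.blink_amplitude),
        ("burst", config.artifact_rates.get("burst", 0.0), 0.50, config.burst_amplitude),
    ]
    for kind, rate, dur, amp in specs:
        n_events = rng.poisson(rate * active_minutes) if rate > 0 else 0
        if t_end - dur <= t_start:
            n_events = 0
        onsets = np.sort(rng.uniform(t_start, t_end - dur, size=n_events))
        if kind == "burst" and len(onsets) > 1:
            # motion events are distinct: enforce a refractory separation
            kept = [onsets[0]]
            for t0 in onsets[1:]:
                if t0 - kept[-1] >= 2.0 * dur:
                    kept.append(t0)
            onsets = np.asarray(kept)
        for onset in onsets:
            i0 = int(round(onset * fs))
            i1 = min(i0 + int(round(dur * fs)), n)
            m = i1 - i0
            tt = np.arange(m) / fs
            if kind == "blink":
                wave = amp * (
                    np.exp(-0.5 * ((tt - 0.12) / 0.045) ** 2)
                    - 0.35 * np.exp(-0.5 * ((tt - 0.27) / 0.07) ** 2)
                )
                weights = np.array(
                    [_BLINK_TOPOGRAPHY.get(ch, 0.1) for ch in recording.channel_names]
                )
                out.data[:, i0:i1] += weights[:, None] * wave[None, :]
                affected = tuple(recording.channel_names)
            else:
                n_aff = int(rng.integers(3, recording.n_channels + 1))
                picks = np.zeros(recording.n_channels, dtype=bool)
                picks[rng.choice(recording.n_channels, n_aff, replace=False)] = True
                # motion bursts are spatially coherent: one broadband
                # (< 35 Hz dominant) waveform projected with per-channel
                # gains (rank-1), so the artifact occupies a low-rank
                # subspace like real cable/electrode motion
                from scipy.signal import firwin
                from scipy.signal.windows import tukey

                wave = np.convolve(
                    rng.standard_normal(m), firwin(61, 28.0, fs=fs), "same"
                )
                wave *= tukey(m, 0.15)
                wave *= (amp / 3.0) / max(wave.std(), 1e-12)
                n_sel = int(picks.sum())
                gains = rng.uniform(0.85, 1.0, n_sel)
                # electrode-dependent polarity, balanced so the artifact
                # pattern is far from the common (all-positive) mode
                signs = np.ones(n_sel)
                signs[: n_sel // 2] = -1.0
                rng.shuffle(signs)
                gains *= signs
                out.data[picks, i0:i1] += gains[:, None] * wave[None, :]
                affected = tuple(
                    ch for ch, p in zip(recording.channel_names, picks) if p
                )
            log.append(ArtifactEvent(onset, m / fs, kind, affected, float(amp)))
    return out, log


def simulate_session(
    config: SimulationConfig, with_artifacts: bool = True
) -> dict[str, tuple[Recording, EventStream, ArtifactLog]]:
    """Generate the full two-condition session (low then high load)."""
    session = {}
    for condition in CONDITIONS:
        events = generate_events(config, condition)
        recording, log = generate_recording(
            config, events, condition, with_artifacts=with_artifacts
        )
        session[condition] = (recording, events, log)
    return session
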