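"""FIR filtering, epoch extraction, baseline correction and segmentation.

The filters are linear-phase Hamming-windowed sincs of even order (default
250 → 251 symmetric taps), applied in a single pass with exact group-delay
compensation (shift by order/2 samples) and reflection padding at the
edges.  The epoch sample grid is half-open ``[tmin, tmax)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

from .recording_io import EpochSet, EventStream, Recording

__all__ = [
    "FilterKernel",
    "design_fir",
    "apply_filter",
    "filter_array",
    "extract_epochs",
    "baseline_correct",
    "crop_epochs",
    "downsample",
    "segment_continuous",
]


@dataclass
class FilterKernel:
    """Linear-phase windowed-sinc FIR kernel."""

    coefficients: np.ndarray
    order: int
    band: tuple[float | None, float | None]
    fs: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.order + 1:
            raise ValueError("kernel length must equal order + 1")
        if self.order % 2 != 0:
            raise ValueError("order must be even (integral group delay)")
        if not np.allclose(self.coefficients, self.coefficients[::-1], atol=1e-12):
            raise ValueError("kernel must be symmetric (linear phase)")

    @property
    def group_delay(self) -> int:
        return self.order // 2


def design_fir(
    band: tuple[float | None, float | None], order: int = 250, fs: float = 500.0
) -> FilterKernel:
    """Design a Hamming-windowed sinc FIR filter.

    ``band`` is (low, high); ``None`` (or 0) on one side yields a one-sided
    filter.  High-pass kernels are built as spectral complements of a
    DC-normalized low-pass (δ − LP), so their DC gain is an exact null.
    """
    low, high = band
    low = None if low in (None, 0, 0.0) else float(low)
    high = None if high is None else float(high)
    if order % 2 != 0:
        raise ValueError("order must be even")
    nyq = fs / 2.0
    if low is not None and not 0 < low < nyq:
        raise ValueError(f"low edge {low} outside (0, {nyq})")
    if high is not None and not 0 < high <= nyq:
        raise ValueError(f"high edge {high} outside (0, {nyq}]")
    if low is not None and high is not None and low >= high:
        raise ValueError(f"band edges must ascend, got {band}")

    numtaps = order + 1

    def lowpass(cut: float) -> np.ndarray:
        return firwin(numtaps, cut, window="hamming", fs=fs)  # unity DC gain

    if low is None and high is None:
        raise ValueError("at least one band edge is required")
    if low is None:
        coeffs = lowpass(high)
    elif high is None:
        coeffs = -lowpass(low)
        coeffs[order // 2] += 1.0  # δ − LP: exact DC null
    else:
        coeffs = firwin(numtaps, [low, high], window="hamming",
                        pass_zero=False, fs=fs)  # unity gain at band centre
    return FilterKernel(coeffs, order, (low, high), fs)


def filter_array(data: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Filter along the last axis with group-delay compensation.

    Single-pass convolution; the output is shifted left by order/2 samples
    and the edges are reflection-padded, so output length equals input
    length and a steady-state sinusoid comes out with zero phase lag.
    """
    n = data.shape[-1]
    if n <= 3 * (kernel.order + 1):
        raise ValueError(
            f"signal length {n} must exceed 3× kernel length "
            f"{3 * (kernel.order + 1)}"
        )
    d = kernel.group_delay
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(d, d)], mode="reflect")
    h = kernel.coefficients.reshape((1,) * (data.ndim - 1) + (-1,))
    full = fftconvolve(padded, h, axes=-1)
    return full[..., 2 * d : 2 * d + n]


def apply_filter(recording: Recording, kernel: FilterKernel) -> Recording:
    out = recording.copy()
    out.data = filter_array(recording.data, kernel)
    return out


def extract_epochs(
    recording: Recording,
    events: EventStream,
    tmin: float,
    tmax: float,
    lock: str | None = None,
) -> EpochSet:
    """Cut one epoch per selected event; boundary events are dropped and counted.

    ``lock`` optionally restricts to one stimulus label.  The epoch holds
    ``round((tmax − tmin)·fs)`` samples starting at ``round((onset+tmin)·fs)``.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    ev = events.select(lock)
    fs = recording.fs
    n_samp = int(round((tmax - tmin) * fs))
    rows, slabs = [], []
    n_dropped = 0
    for onset, stim, cond in zip(ev.onset, ev.stimulus, ev.condition):
        start = int(round((onset + tmin) * fs))
        if start < 0 or start + n_samp > recording.n_samples:
            n_dropped += 1
            continue
        slabs.append(recording.data[:, start : start + n_samp])
        rows.append({"onset": onset, "stimulus": stim, "condition": cond})
    data = (
        np.stack(slabs)
        if slabs
        else np.empty((0, recording.n_channels, n_samp))
    )
    metadata = pd.DataFrame(rows, columns=["onset", "stimulus", "condition"])
    return EpochSet(data, tmin, fs, recording.channel_names, metadata, n_dropped)


def _window_slice(epochs: EpochSet, window: tuple[float, float]) -> slice:
    i0 = int(round((window[0] - epochs.tmin) * epochs.fs))
    i1 = int(round((window[1] - epochs.tmin) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_samples or i0 >= i1:
        raise ValueError(
            f"window {window} outside epoch span "
            f"[{epochs.tmin}, {epochs.tmax})"
        )
    return slice(i0, i1)


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-0.2, 0.0)
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    sl = _window_slice(epochs, window)
    out = epochs.copy()
    out.data = epochs.data - epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def crop_epochs(epochs: EpochSet, tmin: float, tmax: float) -> EpochSet:
    """Re-window epochs to the half-open span [tmin, tmax)."""
    sl = _window_slice(epochs, (tmin, tmax))
    out = epochs.copy()
    out.data = epochs.data[:, :, sl]
    out.tmin = tmin
    return out


def downsample(epochs: EpochSet, target_fs: float = 50.0) -> EpochSet:
    """Decimate by keeping every (fs/target_fs)-th sample, first phase.

    Relies on a prior band-limiting filter (the pipeline's [1, 15] Hz
    stage) instead of an extra anti-alias stage.
    """
    factor = epochs.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs {epochs.fs} is not an integer multiple of target {target_fs}"
        )
    factor = int(round(factor))
    out = epochs.copy()
    out.data = epochs.data[:, :, ::factor]
    out.fs = target_fs
    return out


def segment_continuous(
    recording: Recording, window_s: float = 2.0, condition: str | None = None
) -> EpochSet:
    """Cut successive non-overlapping windows regardless of stimulus onsets.

    The trailing remainder shorter than ``window_s`` is discarded; the
    condition label is inherited from the recording metadata unless given.
    """
    fs = recording.fs
    n_samp = int(round(window_s * fs))
    n_ep = recording.n_samples // n_samp
    data = recording.data[:, : n_ep * n_samp]
    data = data.reshape(recording.n_channels, n_ep, n_samp).transpose(1, 0, 2)
    cond = condition if condition is not None else recording.meta.get("condition", "")
    metadata = pd.DataFrame(
        {
            "onset": np.arange(n_ep) * window_s,
            "stimulus": ["continuous"] * n_ep,
            "condition": [cond] * n_ep,
        }
    )
    return EpochSet(data.copy(), 0.0, fs, recording.channel_names, metadata, 0)
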