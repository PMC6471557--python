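"""Feature construction: ERP sample vectors, CSP log band power, Morlet power.

Two single-trial feature families are built here.  ERP features are the
raw pre-processed sample amplitudes of the 0–0.6 s post-stimulus window of
every channel concatenated into one vector (6 channels × 30 samples at
50 Hz → 180 features).  Frequency features are the log-variance of each
of four canonical bands (delta, theta, alpha, low beta) after spatial
filtering with that band's Common Spatial Patterns filters (4 filters ×
4 bands → 16 features).  Morlet wavelet band power supports the
group-level spectral statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BANDS
from .recording_io import EpochSet, Recording
from .preprocessing import design_fir, filter_array, _window_slice

__all__ = [
    "FeatureMatrix",
    "erp_features",
    "bandpower_features",
    "band_covariances",
    "BandCovariances",
    "morlet_bandpower",
]


@dataclass
class FeatureMatrix:
    """Epochs × features with provenance-encoding column names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs × features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal len(feature_names)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal epoch count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("features contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        if self.groups is not None:
            df["group"] = self.groups
        return df

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not np.array_equal(self.labels, other.labels):
            raise ValueError("cannot stack feature matrices with different labels")
        return FeatureMatrix(
            np.hstack([self.values, other.values]),
            list(self.feature_names) + list(other.feature_names),
            self.labels,
            self.groups,
        )


def erp_features(
    epochs: EpochSet, window: tuple[float, float] = (0.0, 0.6)
) -> FeatureMatrix:
    """Concatenate the window's samples of all channels per epoch.

    Pure bookkeeping: feature ``erp:Pz:t0.200`` is exactly the Pz sample
    at 0.200 s of the (already filtered, baseline-corrected, downsampled)
    epoch.  Channel-major order follows the fixed montage order.
    """
    sl = _window_slice(epochs, window)
    data = epochs.data[:, :, sl]  # epochs × channels × samples
    n_ep, n_ch, n_t = data.shape
    times = epochs.tmin + np.arange(sl.start, sl.stop) / epochs.fs
    names = [
        f"erp:{ch}:t{t:.3f}" for ch in epochs.channel_names for t in times
    ]
    values = data.reshape(n_ep, n_ch * n_t)
    return FeatureMatrix(values, names, epochs.metadata["condition"].to_numpy(object))


@dataclass
class BandCovariances:
    """Per-band, per-epoch covariances over a fixed analysis window.

    ``shrunk`` feeds CSP fitting (Ledoit–Wolf regularized), ``empirical``
    feeds the log-power features: the mean squared output of a spatial
    filter w over the window equals wᵀ·C_empirical·w, so band power needs
    no re-filtering once the covariances are cached.
    """

    bands: dict  # band -> (low, high)
    shrunk: dict  # band -> (n_epochs, ch, ch)
    empirical: dict  # band -> (n_epochs, ch, ch)
    labels: np.ndarray
    channel_names: tuple[str, ...]
    shrinkages: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


def band_covariances(
    epochs: EpochSet,
    bands: dict | None = None,
    window: tuple[float, float] | None = None,
    fir_order: int = 250,
) -> BandCovariances:
    """Band-pass each epoch (order-250 windowed sinc) and cache covariances."""
    from .classification import shrink_covariance  # local: avoid import cycle

    bands = dict(bands or BANDS)
    sl = (
        _window_slice(epochs, window)
        if window is not None
        else slice(0, epochs.n_samples)
    )
    shrunk, empirical, lams = {}, {}, {}
    for band, edges in bands.items():
        kernel = design_fir(edges, order=fir_order, fs=epochs.fs)
        filt = filter_array(epochs.data, kernel)[:, :, sl]
        emp = np.einsum("ecs,eds->ecd", filt, filt) / filt.shape[2]
        sh = np.empty_like(emp)
        lam = np.empty(epochs.n_epochs)
        for i in range(epochs.n_epochs):
            sh[i], lam[i] = shrink_covariance(filt[i].T)
        shrunk[band] = sh
        empirical[band] = emp
        lams[band] = lam
    return BandCovariances(
        bands, shrunk, empirical,
        epochs.metadata["condition"].to_numpy(object),
        epochs.channel_names, lams,
    )


def bandpower_features(
    epochs: EpochSet,
    csp_bank: dict,
    window: tuple[float, float] | None = None,
    fir_order: int = 250,
) -> FeatureMatrix:
    """Log band power after per-band CSP spatial filtering.

    Per band: band-pass filter (windowed sinc), apply the band's CSP
    filters, square, average over the analysis window, natural-log
    transform.  With 4 bands × 4 filters this yields 16 features.
    """
    blocks, names = [], []
    for band, model in csp_bank.items():
        if getattr(model, "filters", None) is None:
            raise ValueError(f"CSP model for band {band!r} is not fitted")
        kernel = design_fir(BANDS.get(band, model.band_edges), order=fir_order,
                            fs=epochs.fs)
        filt = filter_array(epochs.data, kernel)
        sl = (
            _window_slice(epochs, window)
            if window is not None
            else slice(0, epochs.n_samples)
        )
        filt = filt[:, :, sl]
        projected = np.einsum("cf,ecs->efs", model.filters, filt)
        power = np.mean(projected**2, axis=2)
        blocks.append(np.log(np.maximum(power, 1e-300)))
        names.extend(f"pow:{band}:csp{i + 1}" for i in range(model.filters.shape[1]))
    values = np.hstack(blocks) if blocks else np.empty((epochs.n_epochs, 0))
    return FeatureMatrix(values, names, epochs.metadata["condition"].to_numpy(object))


def morlet_bandpower(
    data: Recording | EpochSet,
    bands: dict | None = None,
    n_cycles: float = 7.0,
) -> pd.DataFrame:
    """Morlet-wavelet band power per band, channel (and epoch).

    Continuous wavelet transform with a 7-cycle Morlet mother wavelet
    (chosen for enough spectral localization that a pure tone's power stays
    an order of magnitude inside its own 4-Hz band);
    band power is the time-averaged squared magnitude integrated (summed
    over the 1-Hz scale grid) across the scales whose centre frequencies
    fall inside the band, so a flat spectrum yields band power
    proportional to bandwidth.  Returns a tidy frame with columns epoch,
    channel, band, power.
    """
    from mne.time_frequency import tfr_array_morlet

    bands = dict(bands or BANDS)
    if isinstance(data, Recording):
        arr = data.data[np.newaxis]
        fs = data.fs
        channels = data.channel_names
    else:
        arr = data.data
        fs = data.fs
        channels = data.channel_names
    top = max(high for _, high in bands.values())
    if fs < 2 * top:
        raise ValueError(f"fs {fs} below twice the highest band edge {top}")
    freqs = np.concatenate(
        [np.arange(low + 0.5, high + 0.5, 1.0) for low, high in bands.values()]
    )
    power = tfr_array_morlet(
        arr, sfreq=fs, freqs=freqs, n_cycles=n_cycles, output="power", zero_mean=True
    )  # (epochs, channels, freqs, times)
    rows = []
    for bi, (band, (low, high)) in enumerate(bands.items()):
        in_band = (freqs >= low) & (freqs < high)
        bp = power[:, :, in_band, :].mean(axis=3).sum(axis=2)
        for e in range(arr.shape[0]):
            for c, ch in enumerate(channels):
                rows.append(
                    {"epoch": e, "channel": ch, "band": band, "power": bp[e, c]}
                )
    return pd.DataFrame(rows)
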