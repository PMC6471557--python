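"""Artifact Subspace Reconstruction (classic and Riemannian variants).

ASR learns the component-amplitude statistics of clean calibration EEG and
then, window by window, detects directions of the signal whose variance
exceeds the calibrated thresholds and reconstructs them from the retained
clean subspace through the calibration mixing matrix.  The Riemannian
variant (rASR) replaces the arithmetic mean of calibration window
covariances with the geometric (Karcher) mean on the SPD manifold, which
is robust to residual outlier windows in the calibration data.

Calibration statistic: for each principal component of the calibration
covariance, the RMS amplitude is measured in sliding windows and the
rejection threshold is μ + k·σ of those window RMS values, with k the
burst criterion (70 by default — a deliberately lenient setting for noisy
in-flight recordings).

The module also provides the accompanying continuous-data quality
criteria: flatline channel removal, leave-one-out channel-correlation and
line-noise window flagging, and fraction-based window rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, pinv

from .config import CleanRawParams
from .recording_io import EpochSet, Recording
from .preprocessing import design_fir, filter_array

__all__ = [
    "ASRModel",
    "riemannian_mean",
    "asr_calibrate",
    "asr_process",
    "asr_process_epochs",
    "remove_flatlines",
    "reject_bad_windows",
]


@dataclass
class ASRModel:
    """Calibration statistics for artifact subspace reconstruction."""

    mixing: np.ndarray  # principal square root of the calibration covariance
    components: np.ndarray  # eigenvectors of the calibration covariance (columns)
    thresholds: np.ndarray  # per-component RMS cutoffs, µV
    cutoff_k: float
    window_len: float  # s
    calibration_fs: float
    variant: str
    channel_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be strictly positive")
        if self.cutoff_k <= 0:
            raise ValueError("cutoff_k must be > 0")
        if np.linalg.matrix_rank(self.mixing) < self.mixing.shape[0]:
            raise ValueError("mixing matrix must be full rank")

    @property
    def threshold_operator(self) -> np.ndarray:
        """diag(thresholds) · Vᵀ — maps sensor directions to RMS bounds."""
        return np.diag(self.thresholds) @ self.components.T


def _sliding_windows(n: int, win: int, hop: int) -> list[slice]:
    starts = range(0, max(n - win, 0) + 1, hop)
    wins = [slice(s, s + win) for s in starts]
    if not wins:
        wins = [slice(0, n)]
    elif wins[-1].stop < n:
        wins.append(slice(n - win, n))
    return wins


def _window_covariances(data: np.ndarray, win: int, hop: int) -> np.ndarray:
    return np.stack(
        [data[:, sl] @ data[:, sl].T / (sl.stop - sl.start)
         for sl in _sliding_windows(data.shape[1], win, hop)]
    )


def riemannian_mean(
    covs: np.ndarray, tol: float = 1e-6, max_iter: int = 50
) -> np.ndarray:
    """Geometric (Karcher) mean of SPD matrices by fixed-point iteration.

    Warm-started at the arithmetic mean; converged when the Frobenius norm
    of the tangent-space mean drops below ``tol``.
    """
    covs = np.asarray(covs, dtype=float)
    mean = covs.mean(axis=0)
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(mean)
        vals = np.clip(vals, 1e-12, None)
        isqrt = (vecs * (vals**-0.5)) @ vecs.T
        sqrt = (vecs * (vals**0.5)) @ vecs.T
        logs = []
        for c in covs:
            w = isqrt @ c @ isqrt
            lv, lu = np.linalg.eigh(w)
            lv = np.clip(lv, 1e-12, None)
            logs.append((lu * np.log(lv)) @ lu.T)
        tangent = np.mean(logs, axis=0)
        ev, eu = np.linalg.eigh(tangent)
        mean = sqrt @ ((eu * np.exp(ev)) @ eu.T) @ sqrt
        if np.linalg.norm(tangent) < tol:
            break
    return mean


def asr_calibrate(
    calibration: Recording,
    params: CleanRawParams | None = None,
    variant: str = "riemannian",
) -> ASRModel:
    """Estimate the ASR model from an artifact-free calibration recording."""
    params = (params or CleanRawParams()).validate()
    if variant not in ("classic", "riemannian"):
        raise ValueError(f"unknown ASR variant {variant!r}")
    X = calibration.data
    fs = calibration.fs
    win = int(round(params.window_len * fs))
    if X.shape[1] < 10 * win:
        raise ValueError(
            f"calibration must span at least 10 windows "
            f"({10 * params.window_len:.1f} s), got {X.shape[1] / fs:.1f} s"
        )
    if np.any(X.std(axis=1) == 0):
        flat = [
            ch for ch, s in zip(calibration.channel_names, X.std(axis=1)) if s == 0
        ]
        raise ValueError(f"flat calibration channels: {flat}")

    covs = _window_covariances(X, win, win // 2)
    C = covs.mean(axis=0) if variant == "classic" else riemannian_mean(covs)
    vals, vecs = np.linalg.eigh(C)
    if vals[0] <= 1e-10 * vals[-1]:
        raise ValueError(
            "rank-deficient calibration covariance — check for duplicated "
            "or bridged channels"
        )
    mixing = (vecs * np.sqrt(vals)) @ vecs.T

    comps = vecs.T @ X  # component signals
    rms = np.stack(
        [np.sqrt(np.mean(comps[:, sl] ** 2, axis=1))
         for sl in _sliding_windows(X.shape[1], win, win // 2)]
    )
    thresholds = rms.mean(axis=0) + params.burst_k * rms.std(axis=0)
    return ASRModel(
        mixing=mixing,
        components=vecs,
        thresholds=thresholds,
        cutoff_k=params.burst_k,
        window_len=params.window_len,
        calibration_fs=fs,
        variant=variant,
        channel_names=calibration.channel_names,
    )


def _process_array(X: np.ndarray, model: ASRModel, fs: float):
    """Sliding-window detection/reconstruction with raised-cosine overlap-add."""
    n_ch, n = X.shape
    win = int(round(model.window_len * fs))
    win = min(win, n)
    hop = max(win // 4, 1)  # 75% overlap: dense detection grid
    T = model.threshold_operator
    M = model.mixing

    wins = _sliding_windows(n, win, hop)
    eigs, keeps = [], []
    for sl in wins:
        seg = X[:, sl]
        C = seg @ seg.T / seg.shape[1]
        vals, vecs = eigh(C)
        bounds = np.sum((T @ vecs) ** 2, axis=0)  # squared RMS bound per direction
        eigs.append((vals, vecs, bounds))
        keeps.append(vals <= bounds)
    flags = np.array([not k.all() for k in keeps])

    # dilate detections: a window adjacent to a flagged one re-tests at a
    # relaxed bound, so artifact tails straddling window borders (whose
    # partial energy sits just under threshold) are reconstructed too; the
    # relaxed bound still sits far above clean-background eigenvalues
    dilated = flags.copy()
    dilated[:-1] |= flags[1:]
    dilated[1:] |= flags[:-1]
    relax = 0.25

    out = np.zeros_like(X)
    weight = np.zeros(n)
    for i, sl in enumerate(wins):
        seg = X[:, sl]
        m = seg.shape[1]
        vals, vecs, bounds = eigs[i]
        keep = keeps[i]
        if dilated[i] and not flags[i]:
            keep = vals <= relax * bounds
        if keep.all():
            clean = seg
        else:
            VM = vecs.T @ M
            VM_kept = VM * keep[:, None]
            R = M @ pinv(VM_kept) @ vecs.T
            clean = R @ seg
        taper = np.maximum(np.hanning(m), 1e-3)
        out[:, sl] += clean * taper[None, :]
        weight[sl] += taper
    out /= weight[None, :]
    return out, flags


def asr_process(
    signal: Recording, model: ASRModel
) -> tuple[Recording, np.ndarray]:
    """Clean a continuous recording; returns per-window reconstruction flags.

    Windows of the model's length with 50% overlap are detected and, where
    flagged, reconstructed; unflagged windows pass through bit-identically
    up to the raised-cosine overlap-add blend.  Output length equals input
    length.
    """
    if tuple(signal.channel_names) != tuple(model.channel_names):
        raise ValueError(
            f"channel mismatch: model {model.channel_names}, "
            f"signal {signal.channel_names}"
        )
    cleaned, flags = _process_array(signal.data, model, signal.fs)
    out = signal.copy()
    out.data = cleaned
    out.meta["asr_windows_flagged"] = int(flags.sum())
    return out, flags


def asr_process_epochs(epochs: EpochSet, model: ASRModel) -> tuple[EpochSet, np.ndarray]:
    """Apply :func:`asr_process` independently to each epoch.

    Returns the cleaned epochs and the per-epoch count of flagged windows.
    """
    if tuple(epochs.channel_names) != tuple(model.channel_names):
        raise ValueError("channel mismatch between epochs and ASR model")
    out = epochs.copy()
    counts = np.zeros(epochs.n_epochs, dtype=int)
    for i in range(epochs.n_epochs):
        out.data[i], flags = _process_array(epochs.data[i], model, epochs.fs)
        counts[i] = int(flags.sum())
    return out, counts


# --------------------------------------------------------------------------
# clean-raw-data channel and window criteria


def remove_flatlines(
    recording: Recording, flatline_s: float = 5.0
) -> tuple[Recording, dict]:
    """Drop channels with any near-constant run of at least ``flatline_s`` s."""
    fs = recording.fs
    min_run = int(round(flatline_s * fs))
    dropped = []
    for i, ch in enumerate(recording.channel_names):
        d = np.abs(np.diff(recording.data[i])) < 1e-10
        if not d.any():
            continue
        # longest run of True in d (d[j] means samples j and j+1 are equal)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], d.view(np.int8), [0]))))
        runs = edges[1::2] - edges[::2]
        if runs.size and runs.max() + 1 >= min_run:
            dropped.append(ch)
    if len(dropped) == recording.n_channels:
        raise ValueError("all channels are flat — nothing left to analyze")
    keep = [ch not in dropped for ch in recording.channel_names]
    out = Recording(
        recording.data[np.asarray(keep)],
        fs,
        tuple(ch for ch in recording.channel_names if ch not in dropped),
        dict(recording.meta),
    )
    return out, {"dropped_channels": dropped}


def reject_bad_windows(
    recording: Recording, params: CleanRawParams | None = None
) -> tuple[np.ndarray, dict]:
    """Flag 1-s windows with uncorrelated or line-noise-dominated channels.

    Per window and channel the signal is predicted from the other channels
    by least squares (leave-one-out linear prediction; with six channels a
    RANSAC subsample adds nothing); a channel is flagged when that
    correlation falls below ``channel_correlation`` or when its high-band
    (>45 Hz) to low-band RMS ratio is a robust-z outlier beyond
    ``line_noise_z``.  A window is rejected when more than
    ``window_bad_fraction`` of channels are flagged.

    Returns (retained mask over windows, report dict).
    """
    params = (params or CleanRawParams()).validate()
    fs = recording.fs
    win = int(round(fs))  # 1-s windows
    n_win = recording.n_samples // win
    n_ch = recording.n_channels

    lowpass = design_fir((None, 45.0), order=100, fs=fs)
    smooth = filter_array(recording.data, lowpass)
    resid = recording.data - smooth

    corr = np.ones((n_win, n_ch))
    ratio = np.zeros((n_win, n_ch))
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        seg = smooth[:, sl]
        seg = seg - seg.mean(axis=1, keepdims=True)
        res = resid[:, sl]
        for c in range(n_ch):
            others = np.delete(seg, c, axis=0)
            coef, *_ = np.linalg.lstsq(others.T, seg[c], rcond=None)
            pred = others.T @ coef
            denom = np.linalg.norm(seg[c]) * np.linalg.norm(pred)
            corr[w, c] = (seg[c] @ pred) / denom if denom > 0 else 0.0
            low_rms = np.sqrt(np.mean(seg[c] ** 2))
            ratio[w, c] = np.sqrt(np.mean(res[c] ** 2)) / max(low_rms, 1e-12)

    med = np.median(ratio, axis=0, keepdims=True)
    mad = np.median(np.abs(ratio - med), axis=0, keepdims=True)
    z = (ratio - med) / np.maximum(1.4826 * mad, 1e-12)

    flagged = (corr < params.channel_correlation) | (z > params.line_noise_z)
    frac = flagged.mean(axis=1)
    retained = frac <= params.window_bad_fraction
    report = {
        "n_windows": int(n_win),
        "n_rejected": int((~retained).sum()),
        "flagged_fraction": frac,
        "channel_flags": flagged,
    }
    return retained, report
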