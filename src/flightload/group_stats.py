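"""Group-level bootstrap condition contrasts.

Paired (within-subject) contrasts are tested with a sign-flip resampling
scheme: the observed statistic is the mean over subjects of the
per-subject condition difference; the null distribution is built by
randomly flipping the sign of each subject's difference (valid exactly
under the exchangeability of paired differences, with no normality or
homoscedasticity assumption).  Two-sided p-values use the add-one
estimator ``(1 + #{|null| ≥ |observed|}) / (n_boot + 1)``, which is valid
(conservative) by construction.  Default 10,000 resamples at α = 0.01,
pointwise with no cluster correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .recording_io import EpochSet

__all__ = [
    "ContrastResult",
    "bootstrap_paired_contrast",
    "erp_condition_waveforms",
    "CohortWaveforms",
]


@dataclass
class ContrastResult:
    statistic: np.ndarray  # mean difference per point
    p_values: np.ndarray
    n_boot: int
    alpha: float

    def __post_init__(self):
        self.statistic = np.atleast_1d(np.asarray(self.statistic, dtype=float))
        self.p_values = np.atleast_1d(np.asarray(self.p_values, dtype=float))

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha


def bootstrap_paired_contrast(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_boot: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> ContrastResult:
    """Sign-flip bootstrap test of paired condition differences.

    ``values_a`` and ``values_b`` are (subjects × points) matrices with the
    same subjects in the same rows.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.ndim == 2 and A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < 5:
        raise ValueError(f"need at least 5 subjects, got {A.shape[0]}")
    D = A - B
    n_subj = D.shape[0]
    observed = D.mean(axis=0)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_boot, n_subj))
    null = flips @ D / n_subj  # (n_boot × points)
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_boot + 1.0)
    return ContrastResult(observed, p, n_boot, alpha)


@dataclass
class CohortWaveforms:
    """Per-subject condition × stimulus mean waveforms and P300 window means."""

    waveforms: dict  # (condition, stimulus) -> (subjects × channels × times)
    p300: dict  # (condition, stimulus) -> (subjects × channels)
    subjects: list
    channel_names: tuple[str, ...]
    times: np.ndarray
    window: tuple[float, float]


def erp_condition_waveforms(
    epochs_by_subject: dict[object, EpochSet],
    window: tuple[float, float] = (0.35, 0.60),
) -> CohortWaveforms:
    """Average baseline-corrected epochs per subject, condition and stimulus.

    The scalar P300 amplitude is the mean over the ``window`` (default
    350–600 ms).  Subjects with zero retained target epochs in any present
    condition are excluded with a warning.
    """
    subjects, skipped = [], []
    cells: dict[tuple[str, str], list] = {}
    first = next(iter(epochs_by_subject.values()))
    keys = sorted(
        {
            (str(c), str(s))
            for ep in epochs_by_subject.values()
            for c, s in zip(ep.metadata["condition"], ep.metadata["stimulus"])
        }
    )
    for subject, ep in epochs_by_subject.items():
        means = {}
        ok = True
        for cond, stim in keys:
            mask = (
                (ep.metadata["condition"].astype(str) == cond)
                & (ep.metadata["stimulus"].astype(str) == stim)
                & ep.metadata["retained"]
            ).to_numpy()
            if not mask.any():
                ok = False
                break
            means[(cond, stim)] = ep.data[mask].mean(axis=0)
        if not ok:
            skipped.append(subject)
            continue
        subjects.append(subject)
        for key, m in means.items():
            cells.setdefault(key, []).append(m)
    if skipped:
        warnings.warn(
            f"excluded subjects with empty condition cells: {skipped}",
            stacklevel=2,
        )
    if not subjects:
        raise ValueError("no subject has epochs in every condition cell")

    times = first.times
    i0 = int(round((window[0] - first.tmin) * first.fs))
    i1 = int(round((window[1] - first.tmin) * first.fs))
    if i0 < 0 or i1 > first.n_samples:
        raise ValueError(f"window {window} outside epoch span")
    waveforms = {k: np.stack(v) for k, v in cells.items()}
    p300 = {k: w[:, :, i0:i1].mean(axis=2) for k, w in waveforms.items()}
    return CohortWaveforms(
        waveforms, p300, subjects, first.channel_names, times, window
    )
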