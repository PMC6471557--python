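"""Forward-model (activation-pattern) interpretation of fitted decoders.

The weights of a linear backward model (decoder) are not directly
interpretable as sources; the corresponding forward model is the
activation pattern a = Σ·w, where Σ is the covariance of the decoder's
input.  Applied at two levels: the sLDA weight vector against the
training-fold feature covariance (which feature — i.e. which band × CSP
filter — carries the decision), and the winning CSP filter against the
composite class covariance Σ_A + Σ_B (which channel expresses that
filter).  Tallying the argmax over folds yields the most-informative
band/channel ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ClassificationReport, CSPModel, LDAModel

__all__ = [
    "ActivationPattern",
    "InformativeTally",
    "lda_activation",
    "csp_activation",
    "tally_informative",
]


@dataclass
class ActivationPattern:
    level: str  # 'lda' | 'csp'
    pattern: np.ndarray
    source: object = None

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=float)


def lda_activation(
    model: LDAModel, feature_covariance: np.ndarray
) -> ActivationPattern:
    """Haufe transform of an LDA weight vector: pattern = Σ·w.

    No normalization — downstream use only needs the rank order of
    |pattern|.
    """
    sigma = np.atleast_2d(np.asarray(feature_covariance, dtype=float))
    if sigma.shape[0] != len(model.weights):
        raise ValueError(
            f"covariance dimension {sigma.shape[0]} != "
            f"weight length {len(model.weights)}"
        )
    return ActivationPattern("lda", sigma @ model.weights, model)


def csp_activation(
    model: CSPModel | np.ndarray,
    composite_covariance: np.ndarray,
    filter_index: int | None = None,
) -> ActivationPattern:
    """Channel-level pattern of a CSP filter: pattern = (Σ_A + Σ_B)·w."""
    if isinstance(model, CSPModel):
        w = (
            model.filters[:, filter_index]
            if filter_index is not None
            else model.filters
        )
    else:
        w = np.asarray(model, dtype=float)
    sigma = np.asarray(composite_covariance, dtype=float)
    if sigma.shape[0] != w.shape[0]:
        raise ValueError(
            f"covariance dimension {sigma.shape[0]} != filter length {w.shape[0]}"
        )
    return ActivationPattern("csp", sigma @ w, model)


@dataclass
class InformativeTally:
    """Counts of (band, channel) most-informative pairs over folds."""

    counts: dict  # (band, channel) -> count
    band_ranking: list[str]
    channel_ranking: list[str]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"band": band, "channel": ch, "count": c}
            for (band, ch), c in sorted(
                self.counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["band", "channel", "count"])


def _parse_pow_name(name: str) -> tuple[str, int]:
    parts = name.split(":")
    if len(parts) != 3 or parts[0] != "pow" or not parts[2].startswith("csp"):
        raise ValueError(f"not a band-power feature name: {name!r}")
    return parts[1], int(parts[2][3:]) - 1


def tally_informative(
    reports: ClassificationReport | list[ClassificationReport],
) -> InformativeTally:
    """Tally the most informative (band, channel) pair per fold.

    Per fold: the feature with the largest |sLDA activation| identifies a
    (band, CSP filter); the channel with the largest |activation| of that
    filter is credited.  Ties break toward the lowest index (np.argmax).
    """
    if isinstance(reports, ClassificationReport):
        reports = [reports]
    counts: dict[tuple[str, str], int] = {}
    for report in reports:
        for fold in report.folds:
            if not fold.csp_bank:
                raise ValueError(
                    "report folds lack stored CSP models — tally requires "
                    "frequency-feature reports"
                )
            pattern = lda_activation(fold.lda, fold.feature_covariance).pattern
            names = [fold.feature_names[j] for j in fold.selected]
            pow_positions = [
                k for k, nm in enumerate(names) if nm.startswith("pow:")
            ]
            if not pow_positions:
                raise ValueError("no band-power features among selected features")
            sub = np.abs(pattern[pow_positions])
            best = pow_positions[int(np.argmax(sub))]
            band, filt_idx = _parse_pow_name(names[best])
            csp = fold.csp_bank[band]
            chan_pattern = csp_activation(
                csp, csp.composite_covariance, filter_index=filt_idx
            ).pattern
            # channel names come from the csp_data the report was built on
            channels = fold.csp_bank[band].filters.shape[0]
            ch_names = report.meta.get("channel_names") or [
                f"ch{i}" for i in range(channels)
            ]
            ch = ch_names[int(np.argmax(np.abs(chan_pattern)))]
            key = (band, ch)
            counts[key] = counts.get(key, 0) + 1

    def ranking(axis: int) -> list[str]:
        agg: dict[str, int] = {}
        for key, c in counts.items():
            agg[key[axis]] = agg.get(key[axis], 0) + c
        return [k for k, _ in sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))]

    return InformativeTally(counts, ranking(0), ranking(1))
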