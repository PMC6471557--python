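"""End-to-end pipeline orchestration.

Two single-trial classification pipelines discriminate the low-load
(monitoring) from the high-load (flying) condition:

* Pipeline 1 is stimulus-locked: epochs of −1 to +1 s around every
  oddball stimulus are cleaned per epoch with the rASR model calibrated
  on the first 30 s of the recording, then feed an ERP branch (1–15 Hz,
  baseline −0.2–0 s, re-windowed to 0–0.6 s, downsampled to 50 Hz → 180
  sample features) and/or a frequency branch (4 bands × 4 CSP filters →
  16 log band-power features over 0–0.6 s), optionally fused by
  mRMR top-20 selection.
* Pipeline 2 ignores stimulus onsets: successive non-overlapping 2-s
  windows, per-epoch rASR, 16 log band-power features over the full
  window.

Both end in a stratified five-fold cross-validated shrinkage LDA.
Every run carries a manifest (config hash, seed, drop counts) so reruns
with identical manifests reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging

import numpy as np
import pandas as pd

from .asr import asr_calibrate, asr_process_epochs
from .classification import ClassificationReport, crossvalidate
from .config import BANDS, CONDITIONS, RunConfig, SimulationConfig
from .features import band_covariances, erp_features
from .preprocessing import (
    baseline_correct,
    crop_epochs,
    design_fir,
    downsample,
    extract_epochs,
    filter_array,
    segment_continuous,
)
from .recording_io import EpochSet, EventStream, Recording
from .synthetic import simulate_session

__all__ = [
    "config_hash",
    "concat_epochs",
    "calibration_segment",
    "run_pipeline1",
    "run_pipeline2",
    "simulate_cohort",
    "subject_seeds",
]

logger = logging.getLogger("flightload")


def config_hash(config: RunConfig | SimulationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets sharing grid and montage."""
    first = parts[0]
    for p in parts[1:]:
        if (
            p.channel_names != first.channel_names
            or p.fs != first.fs
            or abs(p.tmin - first.tmin) > 1e-9
            or p.n_samples != first.n_samples
        ):
            raise ValueError("epoch sets are not concatenable")
    return EpochSet(
        np.concatenate([p.data for p in parts]),
        first.tmin,
        first.fs,
        first.channel_names,
        pd.concat([p.metadata for p in parts], ignore_index=True),
        sum(p.n_dropped for p in parts),
    )


def calibration_segment(recording: Recording, duration: float = 30.0) -> Recording:
    """First ``duration`` seconds of a recording (the clean ground segment)."""
    n = int(round(duration * recording.fs))
    if n > recording.n_samples:
        raise ValueError("recording shorter than the calibration duration")
    return Recording(
        recording.data[:, :n].copy(), recording.fs, recording.channel_names,
        {**recording.meta, "segment": "calibration"},
    )


SessionData = dict  # condition -> (Recording, EventStream | None)


def _resolve_session(config: RunConfig, session: SessionData | None) -> SessionData:
    if session is not None:
        return session
    sim = simulate_session(config.simulation)
    return {cond: (rec, ev) for cond, (rec, ev, _log) in sim.items()}


def _broadband_filter(config: RunConfig, session: SessionData) -> SessionData:
    """0.5–30 Hz windowed-sinc FIR on the continuous data, before cleaning.

    Removes slow drifts ahead of rASR so calibration amplitude statistics
    are not dominated by sub-band wander.
    """
    out = {}
    for cond, (rec, events) in session.items():
        kernel = design_fir((0.5, 30.0), config.fir_order, rec.fs)
        filtered = rec.copy()
        filtered.data = filter_array(rec.data, kernel)
        out[cond] = (filtered, events)
    return out


def _fit_asr(config: RunConfig, session: SessionData):
    first_rec = session[CONDITIONS[0]][0]
    calib = calibration_segment(
        first_rec, config.simulation.calibration_duration
    )
    model = asr_calibrate(calib, config.clean_raw, variant=config.asr_variant)
    logger.info(
        "ASR calibrated (%s) on %.0f s, thresholds %.1f–%.1f µV",
        config.asr_variant, calib.duration,
        model.thresholds.min(), model.thresholds.max(),
    )
    return model


def _manifest(config: RunConfig, stage_log: dict) -> dict:
    return {
        "config_hash": config_hash(config),
        "seed": int(config.seed),
        "stages": stage_log,
    }


def run_pipeline1(
    config: RunConfig, session: SessionData | None = None
) -> ClassificationReport:
    """Stimulus-locked pipeline: ERP and/or event-related frequency features."""
    config.validate()
    if config.pipeline not in ("erp", "freq", "fused"):
        raise ValueError(
            f"pipeline 1 runs erp/freq/fused, not {config.pipeline!r}"
        )
    session = _broadband_filter(config, _resolve_session(config, session))
    asr_model = _fit_asr(config, session)
    stage_log: dict = {"asr_variant": config.asr_variant}

    parts = []
    for cond in CONDITIONS:
        rec, events = session[cond]
        if events is None or len(events) == 0:
            raise ValueError(f"pipeline 1 requires events for condition {cond!r}")
        ep = extract_epochs(rec, events, tmin=-1.0, tmax=1.0)
        stage_log[f"epochs_{cond}"] = ep.n_epochs
        stage_log[f"boundary_dropped_{cond}"] = ep.n_dropped
        parts.append(ep)
    epochs = concat_epochs(parts)
    logger.info("pipeline 1: %d epochs (%d boundary-dropped)",
                epochs.n_epochs, epochs.n_dropped)

    epochs, flagged = asr_process_epochs(epochs, asr_model)
    stage_log["asr_flagged_windows"] = int(flagged.sum())

    static_features = None
    if config.pipeline in ("erp", "fused"):
        kernel = design_fir(config.erp_band, config.fir_order, epochs.fs)
        erp_ep = epochs.copy()
        erp_ep.data = filter_array(erp_ep.data, kernel)
        erp_ep = baseline_correct(erp_ep, (-0.2, 0.0))
        erp_ep = crop_epochs(erp_ep, -0.2, config.erp_window[1])
        erp_ep = downsample(erp_ep, config.erp_fs)
        static_features = erp_features(erp_ep, config.erp_window)
        stage_log["erp_features"] = static_features.n_features

    csp_data = None
    if config.pipeline in ("freq", "fused"):
        csp_data = band_covariances(
            epochs, BANDS, window=config.erp_window, fir_order=config.fir_order
        )
        stage_log["frequency_features"] = 2 * config.n_csp_pairs * len(BANDS)

    fusion = config.mrmr_k if config.pipeline == "fused" else None
    report = crossvalidate(
        features=static_features,
        csp_data=csp_data,
        labels=epochs.metadata["condition"].to_numpy(object),
        n_folds=config.n_folds,
        fusion=fusion,
        seed=config.seed,
        n_pairs=config.n_csp_pairs,
        positive="high",
    )
    report.meta["pipeline"] = config.pipeline
    report.meta["manifest"] = _manifest(config, stage_log)
    logger.info("pipeline 1 (%s): balanced accuracy %.1f%%",
                config.pipeline, 100 * report.balanced_accuracy)
    return report


def run_pipeline2(
    config: RunConfig, session: SessionData | None = None
) -> ClassificationReport:
    """Continuous pipeline: frequency features on non-overlapping 2-s windows."""
    config.validate()
    session = _broadband_filter(config, _resolve_session(config, session))
    asr_model = _fit_asr(config, session)
    stage_log: dict = {"asr_variant": config.asr_variant,
                       "window_s": config.continuous_window_s}

    parts = []
    for cond in CONDITIONS:
        rec, _events = session[cond]
        ep = segment_continuous(rec, config.continuous_window_s, condition=cond)
        stage_log[f"epochs_{cond}"] = ep.n_epochs
        parts.append(ep)
    epochs = concat_epochs(parts)
    logger.info("pipeline 2: %d continuous epochs", epochs.n_epochs)

    epochs, flagged = asr_process_epochs(epochs, asr_model)
    stage_log["asr_flagged_windows"] = int(flagged.sum())

    csp_data = band_covariances(epochs, BANDS, window=None,
                                fir_order=config.fir_order)
    report = crossvalidate(
        csp_data=csp_data,
        labels=epochs.metadata["condition"].to_numpy(object),
        n_folds=config.n_folds,
        seed=config.seed,
        n_pairs=config.n_csp_pairs,
        positive="high",
    )
    report.meta["pipeline"] = "continuous"
    report.meta["manifest"] = _manifest(config, stage_log)
    logger.info("pipeline 2: balanced accuracy %.1f%%",
                100 * report.balanced_accuracy)
    return report


def subject_seeds(base_seed: int, n_subjects: int) -> list[int]:
    """Derive independent per-subject generator seeds from one cohort seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in
            ss.spawn(n_subjects)]


def simulate_cohort(
    config: SimulationConfig, n_subjects: int, base_seed: int = 0,
    with_artifacts: bool = True,
):
    """Yield (subject id, session dict) for a cohort of simulated pilots."""
    for i, seed in enumerate(subject_seeds(base_seed, n_subjects)):
        cfg = dataclasses.replace(config, seed=seed)
        cfg.band_power_map = config.band_power_map
        yield i, simulate_session(cfg, with_artifacts=with_artifacts)
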