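"""LFP-band filtering, epoching, trial rejection and P1/N1 extraction.

The LFP path applies a 4th-order Butterworth band-pass (0.5-100 Hz) and a
60 Hz notch, both forward-reverse so evoked latencies are not shifted,
then downsamples to 1 kHz.  Epochs span -50..250 ms around each flash
onset; the -50..0 ms mean is subtracted per trial and contact.  Trials
whose samples leave the across-trial mean +- 5 SD envelope are flagged as
artifacts.  P1 is the maximum in 55-90 ms, N1 the minimum in 100-140 ms.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .io import AnalysisConfig, EpochSet, RecordingSession, ValidationError

logger = logging.getLogger("lamstim")


def filter_lfp(session: RecordingSession, config: Optional[AnalysisConfig] = None) -> RecordingSession:
    """Band-pass, notch and downsample the LFP stream to 1 kHz.

    Zero-phase (forward-reverse) application of a 4th-order Butterworth
    0.5-100 Hz band-pass plus a 60 Hz notch; the output rate is exactly
    ``config.target_fs_hz``.
    """
    cfg = config or AnalysisConfig()
    fs = session.fs_lfp
    target = cfg.target_fs_hz
    if fs < 2 * target:
        raise ValidationError(f"fs_lfp {fs} Hz too low; need >= {2 * target} Hz")
    factor = fs / target
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError(
            f"fs_lfp {fs} is not an integer multiple of {target} Hz; "
            "resample the recording to a multiple of the target rate first")
    factor = int(round(factor))

    sos = signal.butter(cfg.lfp_filter_order, cfg.lfp_band_hz, btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, session.lfp_signals, axis=1)
    b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=fs)
    x = signal.filtfilt(b, a, x, axis=1)
    x = x[:, ::factor]
    return session.replace(lfp_signals=x, fs_lfp=target)


def epoch_and_baseline(session: RecordingSession, config: Optional[AnalysisConfig] = None) -> EpochSet:
    """Segment -50..250 ms epochs around each onset and baseline-correct.

    Onsets too close to the record edge for a full window are dropped with
    a warning rather than raising.
    """
    cfg = config or AnalysisConfig()
    t0, t1 = cfg.epoch_window_ms
    fs = session.fs_lfp
    n_pre = int(round(-t0 / 1000.0 * fs))
    n_post = int(round(t1 / 1000.0 * fs))
    t_ms = (np.arange(-n_pre, n_post + 1) / fs) * 1000.0

    trials = []
    dropped = 0
    for onset in session.stim_onsets_s:
        i = int(round(onset * fs))
        lo, hi = i - n_pre, i + n_post + 1
        if lo < 0 or hi > session.n_samples:
            dropped += 1
            continue
        trials.append(session.lfp_signals[:, lo:hi])
    if dropped:
        warnings.warn(f"dropped {dropped} onsets too close to the record edge")
    if not trials:
        raise ValidationError("no onset leaves room for a full epoch window")
    data = np.stack(trials)

    b0, b1 = cfg.baseline_window_ms
    bmask = (t_ms >= b0) & (t_ms < b1)
    data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(data=data, t_ms=t_ms, condition=session.condition,
                    baseline_corrected=True)


def reject_trials(epochs: EpochSet, sd: float = 5.0,
                  pooling: str = "per_contact") -> EpochSet:
    """Flag artifact trials that leave the across-trial mean +- ``sd``*SD envelope.

    ``pooling='per_contact'`` (default) computes the envelope per contact and
    timepoint over all trials; ``pooling='trial_rms'`` instead rejects on the
    per-trial RMS distribution.  Data are retained; only ``keep_mask`` changes.
    """
    if epochs.n_trials < 2:
        raise ValidationError("need at least 2 trials to estimate the envelope")
    x = epochs.data
    if pooling == "per_contact":
        mu = x.mean(axis=0)
        sigma = x.std(axis=0, ddof=0)
        bad = np.any(np.abs(x - mu[None]) > sd * sigma[None], axis=(1, 2))
    elif pooling == "trial_rms":
        rms = np.sqrt((x ** 2).mean(axis=(1, 2)))
        bad = np.abs(rms - rms.mean()) > sd * rms.std(ddof=0)
    else:
        raise ValueError("pooling must be 'per_contact' or 'trial_rms'")
    keep = epochs.keep_mask & ~bad
    logger.info("trial rejection: %d/%d kept", keep.sum(), keep.size)
    return EpochSet(data=x, t_ms=epochs.t_ms, condition=epochs.condition,
                    baseline_corrected=epochs.baseline_corrected, keep_mask=keep)


def _peak_in_window(data: np.ndarray, t_ms: np.ndarray, window, mode: str):
    lo, hi = window
    mask = (t_ms >= lo) & (t_ms <= hi)
    if not mask.any():
        raise ValidationError(f"component window {window} outside epoch time axis")
    seg = data[..., mask]
    t_seg = t_ms[mask]
    # argmax/argmin take the earliest sample on ties
    idx = seg.argmax(axis=-1) if mode == "max" else seg.argmin(axis=-1)
    amp = np.take_along_axis(seg, idx[..., None], axis=-1)[..., 0]
    return amp, t_seg[idx]


def extract_components(epochs: EpochSet, config: Optional[AnalysisConfig] = None,
                       channel_names=None) -> pd.DataFrame:
    """Per-trial P1/N1 amplitudes and latencies for every channel (or layer).

    Returns a table with columns trial, channel, p1_amp, p1_lat_ms, n1_amp,
    n1_lat_ms, kept.  N1 amplitudes are signed (negative for a real trough).
    """
    if not epochs.baseline_corrected:
        raise ValidationError("extract_components requires baseline-corrected epochs")
    cfg = config or AnalysisConfig()
    p1_amp, p1_lat = _peak_in_window(epochs.data, epochs.t_ms, cfg.p1_window_ms, "max")
    n1_amp, n1_lat = _peak_in_window(epochs.data, epochs.t_ms, cfg.n1_window_ms, "min")
    n_tr, n_ch = p1_amp.shape
    if channel_names is None:
        channel_names = [str(c) for c in range(n_ch)]
    rows = {
        "trial": np.repeat(np.arange(n_tr), n_ch),
        "channel": np.tile(np.asarray(channel_names, dtype=object), n_tr),
        "p1_amp": p1_amp.ravel(),
        "p1_lat_ms": p1_lat.ravel(),
        "n1_amp": n1_amp.ravel(),
        "n1_lat_ms": n1_lat.ravel(),
        "kept": np.repeat(epochs.keep_mask, n_ch),
    }
    return pd.DataFrame(rows)
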