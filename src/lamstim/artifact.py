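"""Stimulation-artifact removal: SOBI unmixing plus sinusoid subtraction.

The 1.5 Hz AC artifact is far larger than the LFP but temporally highly
structured, which makes second-order blind identification (SOBI) a good
fit: whiten the multichannel record, then find the orthogonal rotation
that jointly diagonalizes a set of time-lagged covariance matrices.
Sources dominated by the stimulation frequency are identified from their
FFT spectrum, the stationary sinusoid at that frequency is estimated by a
least-squares (DFT-filter) fit and subtracted from those sources only,
and the result is back-projected to the contact level.  Subtracting only
the fitted sinusoid, rather than zeroing whole components, preserves any
genuine neural signal the flagged components carry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import AnalysisConfig, FLASH_AC, RecordingSession, ValidationError

logger = logging.getLogger("lamstim")


@dataclass
class UnmixingModel:
    mixing: np.ndarray          # contacts x sources
    unmixing: np.ndarray        # sources x contacts
    sources: np.ndarray         # sources x samples
    lags: np.ndarray
    ac_flags: np.ndarray = field(default=None)
    harmonic_ratios: Optional[np.ndarray] = None
    power_ratios: Optional[np.ndarray] = None
    off_diagonal_fraction: float = np.nan
    rank_retained: int = 0

    def __post_init__(self):
        if self.ac_flags is None:
            self.ac_flags = np.zeros(self.sources.shape[0], dtype=bool)

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]


def joint_diagonalize(matrices: Sequence[np.ndarray], tol: float = 1e-10,
                      max_sweeps: int = 100) -> np.ndarray:
    """Orthogonal joint diagonalizer of symmetric matrices (Jacobi sweeps).

    Returns the rotation ``V`` minimizing the summed off-diagonal energy of
    ``V.T @ M @ V`` over the stack; for a single matrix this reduces to its
    eigenvector rotation.  Sweeps stop when every Givens angle falls below
    ``tol``.
    """
    mats = [np.array(m, dtype=np.float64, copy=True) for m in matrices]
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all matrices must share one dimension")
    V = np.eye(n)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                # closed-form Givens angle minimizing sum of squared
                # off-diagonal (p, q) entries across the stack
                u = np.array([0.5 * (m[p, p] - m[q, q]) for m in mats])
                v = np.array([m[p, q] for m in mats])
                num = 2.0 * np.dot(u, v)
                den = np.dot(u, u) - np.dot(v, v)
                theta = 0.25 * np.arctan2(num, den)
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= tol:
                    continue
                biggest = max(biggest, abs(s))
                G = np.array([[c, -s], [s, c]])
                for m in mats:
                    rows = m[[p, q], :]
                    m[[p, q], :] = G.T @ rows
                    cols = m[:, [p, q]]
                    m[:, [p, q]] = cols @ G
                V[:, [p, q]] = V[:, [p, q]] @ G
        if biggest <= tol:
            break
    return V


def _lag_set(fs: float, n_lags: int = 50, max_lag_ms: float = 500.0) -> np.ndarray:
    """Log-spaced sample lags over 1 ms .. max_lag_ms."""
    max_lag = max(int(round(max_lag_ms / 1000.0 * fs)), 2)
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_lags)).astype(int))
    return lags[lags >= 1]


def _lagged_cov(x: np.ndarray, lag: int) -> np.ndarray:
    a = x[:, :-lag] if lag else x
    b = x[:, lag:] if lag else x
    c = a @ b.T / a.shape[1]
    return 0.5 * (c + c.T)


def sobi_unmix(data: np.ndarray, lags: Optional[Sequence[int]] = None,
               fs: float = 1000.0, var_retained: float = 0.99999) -> UnmixingModel:
    """Second-order blind identification of temporally structured sources.

    Whitens ``data`` (channels x samples), retaining components covering
    ``var_retained`` of the variance (the artifact dominates variance and
    must not be discarded), then jointly diagonalizes whitened lagged
    covariance matrices.
    """
    x = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in input")
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a channels x samples matrix with >= 2 channels")
    lags = np.asarray(lags if lags is not None else _lag_set(fs), dtype=int)
    if x.shape[1] <= 10 * lags.max():
        raise ValidationError("record too short for the requested lag set")

    x = x - x.mean(axis=1, keepdims=True)
    c0 = _lagged_cov(x, 0)
    evals, evecs = np.linalg.eigh(c0)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    total = evals.sum()
    keep = int(np.searchsorted(np.cumsum(evals) / total, var_retained) + 1)
    numeric_rank = int((evals > 1e-12 * evals[0]).sum())
    if numeric_rank < x.shape[0]:
        warnings.warn(f"rank-deficient covariance: retaining {numeric_rank} of "
                      f"{x.shape[0]} dimensions")
    keep = min(keep, numeric_rank)
    logger.info("whitening retains %d of %d dimensions", keep, x.shape[0])
    d = evals[:keep]
    E = evecs[:, :keep]
    whitener = (E / np.sqrt(d)).T            # keep x channels
    dewhiten = E * np.sqrt(d)                # channels x keep
    z = whitener @ x

    covs = [_lagged_cov(z, int(lag)) for lag in lags]
    V = joint_diagonalize(covs)

    sources = V.T @ z
    mixing = dewhiten @ V
    unmixing = V.T @ whitener

    diag_mats = [V.T @ c @ V for c in covs]
    off = sum(np.sum(m ** 2) - np.sum(np.diag(m) ** 2) for m in diag_mats)
    tot = sum(np.sum(m ** 2) for m in diag_mats)
    return UnmixingModel(mixing=mixing, unmixing=unmixing, sources=sources,
                         lags=lags, off_diagonal_fraction=float(off / max(tot, 1e-300)),
                         rank_retained=keep)


def identify_ac_components(model: UnmixingModel, fs: float, f0: float,
                           ratio_threshold: float = 50.0,
                           band_halfwidth_hz: float = 0.1) -> UnmixingModel:
    """Flag sources whose FFT power concentrates at the stimulation frequency.

    A source is flagged when its summed power in ``f0 +- 0.1 Hz`` exceeds
    ``ratio_threshold`` times its median power over 0.5-40 Hz.  Power ratios
    in the harmonic bands (2*f0, 3*f0) are reported for QC but do not drive
    the flags.
    """
    if f0 <= 0 or f0 >= fs / 2:
        raise ValidationError("f0 must lie in (0, Nyquist)")
    n = model.sources.shape[1]
    if n < 10 * fs / f0:
        raise ValidationError("source length must cover >= 10 cycles of f0")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.abs(np.fft.rfft(model.sources, axis=1)) ** 2 / n
    ref = (freqs >= 0.5) & (freqs <= 40.0)

    def band_ratio(center):
        band = np.abs(freqs - center) <= band_halfwidth_hz
        bandpow = psd[:, band].sum(axis=1)
        med = np.median(psd[:, ref], axis=1) * band.sum()
        return bandpow / np.maximum(med, 1e-300)

    ratios = band_ratio(f0)
    model.power_ratios = ratios
    model.harmonic_ratios = np.stack([band_ratio(2 * f0), band_ratio(3 * f0)], axis=1)
    model.ac_flags = ratios > ratio_threshold
    logger.info("flagged %d/%d sources at %.2f Hz", model.ac_flags.sum(),
                model.n_sources, f0)
    return model


def dft_subtract(signal_ts: np.ndarray, fs: float, f0: float,
                 exclude: Sequence[Tuple[float, float]] = ()) -> np.ndarray:
    """Subtract the least-squares sinusoid at ``f0`` from a time series.

    The cos/sin pair is fitted on the samples outside the ``exclude`` time
    ranges (seconds) -- e.g. the stimulation ramps, where the artifact is
    not stationary -- and subtracted everywhere.
    """
    if f0 <= 0:
        raise ValidationError("f0 must be positive")
    x = np.asarray(signal_ts, dtype=np.float64)
    n = x.size
    t = np.arange(n) / fs
    fit_mask = np.ones(n, dtype=bool)
    for lo, hi in exclude:
        fit_mask &= ~((t >= lo) & (t < hi))
    if fit_mask.sum() < 2 * fs / f0:
        raise ValidationError("fewer than 2 cycles of f0 outside excluded ranges")
    basis = np.stack([np.cos(2 * np.pi * f0 * t), np.sin(2 * np.pi * f0 * t)], axis=1)
    coef, *_ = np.linalg.lstsq(basis[fit_mask], x[fit_mask], rcond=None)
    return x - basis @ coef


def band_power(x: np.ndarray, fs: float, f0: float, halfwidth: float = 0.05) -> float:
    """Summed periodogram power in ``f0 +- halfwidth`` Hz (QC helper)."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.abs(np.fft.rfft(x, axis=-1)) ** 2 / n
    band = np.abs(freqs - f0) <= halfwidth
    return float(np.atleast_2d(psd)[:, band].sum())


def plateau_band_power(session: RecordingSession, f0: float,
                       halfwidth: float = 0.05) -> float:
    """Band power on the ramp-free plateau, where the artifact is stationary.

    The sinusoid fit excludes the ramps, so attenuation is meaningful (and
    epochs are taken) only on the plateau.
    """
    fs = session.fs_lfp
    i0 = int(round(session.ramp_s * fs))
    i1 = session.n_samples - i0
    return band_power(session.lfp_signals[:, i0:i1], fs, f0, halfwidth)


def remove_ac_artifact(session: RecordingSession,
                       config: Optional[AnalysisConfig] = None,
                       lags: Optional[Sequence[int]] = None):
    """Remove the AC stimulation artifact from a Flash+AC session.

    Composition: SOBI unmixing -> FFT identification of stimulation-frequency
    sources -> DFT-filter subtraction on flagged sources (fit excluding the
    ramps) -> back-projection.  Returns ``(cleaned_session, model)``; when no
    source is flagged the input is returned unchanged with a warning.
    """
    if session.condition != FLASH_AC:
        raise ValidationError("artifact removal applies to the FLASH_AC condition")
    cfg = config or AnalysisConfig()
    fs = session.fs_lfp
    f0 = session.ac_frequency_hz
    x = session.lfp_signals
    model = sobi_unmix(x, lags=lags if lags is not None else
                       _lag_set(fs, cfg.sobi_n_lags, cfg.sobi_max_lag_ms), fs=fs)
    model = identify_ac_components(model, fs, f0, cfg.ac_ratio_threshold)
    if not model.ac_flags.any():
        warnings.warn("no stimulation-frequency component found; "
                      "returning the input unchanged")
        return session, model

    duration = session.n_samples / fs
    exclude = [(0.0, session.ramp_s), (duration - session.ramp_s, duration)]
    removed = np.zeros_like(x)
    for i in np.flatnonzero(model.ac_flags):
        src = model.sources[i]
        fitted = src - dft_subtract(src, fs, f0, exclude=exclude)
        removed += np.outer(model.mixing[:, i], fitted)
    cleaned = x - removed
    out = session.replace(lfp_signals=cleaned)
    att = 10 * np.log10(max(plateau_band_power(out, f0), 1e-300)
                        / max(plateau_band_power(session, f0), 1e-300))
    logger.info("AC artifact plateau power change at %.2f Hz: %.1f dB", f0, att)
    return out, model
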