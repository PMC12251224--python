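"""Stimulation voltage/field profiles along the probe and AC phase labels.

The stimulation potential at each contact is the 0.5-2 Hz narrowband
content of the raw record (4th-order, zero-phase Butterworth), divided by
the acquisition gain to recover physical millivolts.  The radial electric
field is the numerical gradient of the potential amplitude along the
probe; with potentials in mV and spacing in mm, mV/mm equals V/m.

Phase labels follow a cosine convention throughout the package: 0 deg at
the artifact peak, +-180 deg at the trough, -90 deg on the rising
zero-crossing.  Labels come from the analytic (Hilbert) phase of the
narrowband signal at each stimulus onset; a virtual-AC mode labels the
no-stimulation condition against a fictitious cosine starting at record
time zero, providing the negative control for phase-dependence tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .io import AnalysisConfig, FLASH, FLASH_AC, RecordingSession, ValidationError
from .synth import wrap_deg


@dataclass
class FieldProfile:
    voltage_amplitude_mV: np.ndarray
    efield_V_per_m: np.ndarray
    phase_deg: np.ndarray
    dominant_frequency_hz: float

    def to_frame(self, spacing_mm: float) -> pd.DataFrame:
        n = self.voltage_amplitude_mV.size
        return pd.DataFrame({
            "contact": np.arange(n),
            "depth_mm": np.arange(n) * spacing_mm,
            "voltage_mV": self.voltage_amplitude_mV,
            "efield_V_per_m": self.efield_V_per_m,
            "phase_deg": self.phase_deg,
        })


@dataclass
class PhaseLabels:
    phase_deg: np.ndarray     # per trial, in (-180, 180]
    valid: np.ndarray         # False where the onset fell inside the edge guard
    method: str               # hilbert | fft | virtual

    def __post_init__(self):
        self.phase_deg = np.asarray(self.phase_deg, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phase_deg.size != self.valid.size:
            raise ValidationError("phase/valid length mismatch")

    @property
    def n_trials(self) -> int:
        return self.phase_deg.size


def extract_ac_waveform(session: RecordingSession,
                        config: Optional[AnalysisConfig] = None,
                        virtual: bool = False) -> np.ndarray:
    """Per-contact 0.5-2 Hz narrowband signal in physical mV at 1 kHz."""
    if session.condition != FLASH_AC and not virtual:
        raise ValidationError("AC waveform extraction expects the FLASH_AC condition")
    cfg = config or AnalysisConfig()
    f0 = session.ac_frequency_hz
    if session.duration_s < 10.0 / f0:
        raise ValidationError("record shorter than 10 cycles of the AC frequency")
    fs = session.fs_lfp
    sos = signal.butter(4, cfg.ac_band_hz, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, session.lfp_signals, axis=1)
    factor = fs / cfg.target_fs_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError("fs_lfp must be an integer multiple of the target rate")
    return x[:, ::int(round(factor))] / session.gain


def compute_efield(voltage_profile_mV: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Numerical gradient of the potential along the probe, in V/m.

    Central differences at interior contacts, one-sided at the ends.
    """
    v = np.asarray(voltage_profile_mV, dtype=np.float64)
    if v.size < 3:
        raise ValidationError("need at least 3 contacts")
    if spacing_mm <= 0:
        raise ValidationError("spacing must be positive")
    return np.gradient(v, spacing_mm)   # mV/mm == V/m


def extract_amp_phase(signal_ts: np.ndarray, fs: float):
    """Amplitude, cosine-convention phase and frequency of the dominant tone.

    The peak-power frequency is found on the full-length FFT, then amplitude
    and phase are re-estimated over an integer number of its cycles so the
    tone falls on an exact DFT bin.
    """
    x = np.asarray(signal_ts, dtype=np.float64)
    if not np.any(x):
        raise ValidationError("all-zero signal has undefined phase")
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    f_peak = float(freqs[np.argmax(spec)])
    if f_peak <= 0:
        raise ValidationError("no nonzero dominant frequency found")
    if n < 4 * fs / f_peak:
        raise ValidationError("need >= 4 cycles of the dominant frequency")
    n_cyc = int(np.floor(n * f_peak / fs))
    n_crop = int(round(n_cyc * fs / f_peak))
    xc = x[:n_crop]
    k = int(round(f_peak * n_crop / fs))
    coef = np.fft.rfft(xc)[k]
    amplitude = 2.0 * np.abs(coef) / n_crop
    phase = float(np.rad2deg(np.angle(coef)))
    return amplitude, wrap_deg(phase).item(), f_peak


def field_profile(session: RecordingSession,
                  config: Optional[AnalysisConfig] = None) -> FieldProfile:
    """Voltage amplitude, phase and E-field at the dominant AC frequency."""
    ac = extract_ac_waveform(session, config)
    cfg = config or AnalysisConfig()
    amps = np.empty(ac.shape[0])
    phases = np.empty(ac.shape[0])
    fpeaks = np.empty(ac.shape[0])
    for c in range(ac.shape[0]):
        amps[c], phases[c], fpeaks[c] = extract_amp_phase(ac[c], cfg.target_fs_hz)
    efield = compute_efield(amps, session.contact_spacing_mm)
    return FieldProfile(voltage_amplitude_mV=amps, efield_V_per_m=efield,
                        phase_deg=phases,
                        dominant_frequency_hz=float(np.median(fpeaks)))


def phase_at_onsets(ac_single: np.ndarray, fs: float, onsets_s: np.ndarray,
                    f0: float = 1.5, method: str = "hilbert") -> PhaseLabels:
    """AC phase (cosine convention) at each stimulus onset.

    Uses the analytic-signal angle of the narrowband trace.  Onsets closer
    than one AC cycle to either record edge are marked invalid rather than
    dropped, so trial indexing stays aligned with the epoch set.
    """
    x = np.asarray(ac_single, dtype=np.float64)
    onsets = np.asarray(onsets_s, dtype=np.float64)
    guard = 1.0 / f0
    duration = x.size / fs
    analytic = signal.hilbert(x)
    idx = np.round(onsets * fs).astype(int)
    idx = np.clip(idx, 0, x.size - 1)
    phases = wrap_deg(np.rad2deg(np.angle(analytic[idx])))
    valid = (onsets >= guard) & (onsets <= duration - guard)
    return PhaseLabels(phase_deg=phases, valid=valid, method=method)


def virtual_ac_labels(session: RecordingSession, f0: float = 1.5) -> PhaseLabels:
    """Phase labels against a fictitious cosine at ``f0`` starting at t = 0.

    Negative control for the no-stimulation condition: with no physical
    artifact, phase-dependence statistics against these labels should sit
    at the nominal false-positive level.
    """
    if session.condition != FLASH:
        raise ValidationError("virtual labels apply to the FLASH condition")
    phases = wrap_deg(360.0 * f0 * session.stim_onsets_s)
    return PhaseLabels(phase_deg=phases,
                       valid=np.ones(session.stim_onsets_s.size, dtype=bool),
                       method="virtual")
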