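"""Synthetic laminar-session generator with known ground truth.

Emulates a 23-contact linear probe (0.1 mm spacing) in primary visual
cortex during flash stimulation at 2.3 Hz, with and without concurrent
1.5 Hz sinusoidal transcranial AC stimulation:

* flash-evoked LFPs with a P1 (~75 ms) and N1 (~120 ms) component whose
  amplitude grows with cortical depth;
* an AC artifact far larger than the LFP, with a depth profile whose
  spatial gradient (the electric field) peaks in layers 2/3;
* optional unimodal or axial phase-dependent modulation of the evoked
  amplitude in selected layers;
* pink noise (independent per contact plus a 20% common-mode term),
  60 Hz line noise, acquisition gain x10;
* an optional >= 20 kHz wideband stream carrying Poisson multi-unit
  spikes with higher deep-layer rates.

Because 2.3 Hz flashes and 1.5 Hz AC are non-harmonic, the true AC phase
at stimulus onset is close to uniformly distributed over trials, which is
what makes phase-binned analyses possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as sp_signal

from .io import FLASH, FLASH_AC, RecordingSession

LAYER_ORDER = ("OUTSIDE", "L1", "L23", "L4AB", "L4C", "L56", "WM")

#: default ground-truth contact labels for a 23-contact probe, pial to deep
DEFAULT_LAYER_LABELS = (
    ["OUTSIDE"] * 3 + ["L1"] * 2 + ["L23"] * 6 + ["L4AB"] * 2
    + ["L4C"] * 4 + ["L56"] * 4 + ["WM"] * 2
)


def wrap_deg(phi: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to (-180, 180]."""
    phi = np.asarray(phi, dtype=np.float64)
    out = -np.mod(-phi + 180.0, 360.0) + 180.0
    return out


@dataclass
class SynthConfig:
    n_contacts: int = 23
    spacing_mm: float = 0.1
    fs_lfp: float = 2000.0
    fs_wideband: float = 20000.0
    duration_s: float = 160.0
    flash_rate_hz: float = 2.3
    ac_hz: float = 1.5
    #: artifact-to-LFP amplitude ratio at the probe is not constrained by the
    #: study; 50 mV against a ~1 mV evoked response (50:1) is the default.
    ac_scalp_amplitude_mV: float = 50.0
    ramp_s: float = 30.0
    gain: float = 10.0
    # evoked components (physical mV, deepest cortical contact)
    p1_amp_mV: float = 1.0
    n1_amp_mV: float = 1.5
    p1_latency_ms: float = 75.0
    n1_latency_ms: float = 120.0
    # early thalamic-input deflection, spatially confined to layer 4C; gives
    # the CSD profile its earliest post-stimulus sink, as in real recordings
    early_sink_amp_mV: float = 0.8
    early_sink_latency_ms: float = 45.0
    early_sink_sigma_ms: float = 6.0
    early_sink_depth_sigma: float = 1.0
    # phase-dependent modulation
    modulation_mode: str = "none"  # none | unimodal | axial
    modulation_depth: float = 0.0
    preferred_phase_deg: float = -90.0
    modulated_layers: Tuple[str, ...] = ("L4AB", "L4C", "L56")
    # noise
    noise_sd_mV: float = 0.1
    line_60hz_mV: float = 0.05
    common_mode_frac: float = 0.2
    # multi-unit stream
    include_wideband: bool = False
    wb_noise_sd_mV: float = 0.005
    spike_amp_mV: float = 0.04
    mua_baseline_hz: Dict[str, float] = field(default_factory=lambda: {
        "OUTSIDE": 0.0, "L1": 1.0, "L23": 5.0, "L4AB": 8.0,
        "L4C": 10.0, "L56": 15.0, "WM": 0.5})
    mua_evoked_hz: Dict[str, float] = field(default_factory=lambda: {
        "OUTSIDE": 0.0, "L1": 2.0, "L23": 20.0, "L4AB": 40.0,
        "L4C": 60.0, "L56": 60.0, "WM": 0.0})
    mua_evoked_window_ms: Tuple[float, float] = (20.0, 150.0)
    layer_labels: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation depth must be in [0, 1)")
        if self.modulation_mode not in ("none", "unimodal", "axial"):
            raise ValueError("modulation_mode must be none|unimodal|axial")
        if self.ac_scalp_amplitude_mV < 0 or self.p1_amp_mV < 0 or self.n1_amp_mV < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.layer_labels is None:
            if self.n_contacts == 23:
                self.layer_labels = tuple(DEFAULT_LAYER_LABELS)
            else:
                raise ValueError("layer_labels required when n_contacts != 23")
        if len(self.layer_labels) != self.n_contacts:
            raise ValueError("layer_labels length must equal n_contacts")


@dataclass
class GroundTruth:
    """Injected parameters and per-trial truths of one generated pair."""

    config: SynthConfig
    onsets_s: np.ndarray
    phases_deg: np.ndarray            # true AC phase at each onset (cosine convention)
    modulation_factor: np.ndarray     # per-trial evoked gain in modulated layers
    p1_amp_profile_mV: np.ndarray     # per-contact pre-noise P1 amplitude
    n1_amp_profile_mV: np.ndarray
    potential_profile_mV: np.ndarray  # per-contact AC potential amplitude
    efield_profile_V_per_m: np.ndarray
    layer_labels: Tuple[str, ...]
    clean_evoked_mV: np.ndarray       # contacts x time, noise-free trial-average kernel
    clean_evoked_t_ms: np.ndarray


# ---------------------------------------------------------------------------


def evoked_kernel(t_ms: np.ndarray, p1_amp: float, n1_amp: float,
                  p1_latency_ms: float = 75.0, n1_latency_ms: float = 120.0,
                  p1_sigma_ms: float = 8.0, n1_sigma_ms: float = 12.0) -> np.ndarray:
    """Flash-evoked waveform: positive P1 minus negative N1 Gaussian lobes.

    Peaks at ``p1_latency_ms`` (maximum ``p1_amp``) and ``n1_latency_ms``
    (minimum ``-n1_amp``); identically zero before stimulus onset.
    """
    if not (np.isfinite(p1_amp) and np.isfinite(n1_amp)):
        raise ValueError("amplitudes must be finite")
    t = np.asarray(t_ms, dtype=np.float64)
    w = (p1_amp * np.exp(-0.5 * ((t - p1_latency_ms) / p1_sigma_ms) ** 2)
         - n1_amp * np.exp(-0.5 * ((t - n1_latency_ms) / n1_sigma_ms) ** 2))
    w[t < 0] = 0.0
    return w


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD pink (1/f amplitude) noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * np.exp(2j * np.pi * rng.random(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _amp_profiles(cfg: SynthConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-contact evoked P1/N1 amplitudes and AC potential amplitudes (mV)."""
    labels = np.array(cfg.layer_labels)
    n = cfg.n_contacts
    cortical = np.isin(labels, ("L1", "L23", "L4AB", "L4C", "L56"))
    idx = np.arange(n, dtype=float)
    p1 = np.full(n, 0.05 * cfg.p1_amp_mV)
    n1 = np.full(n, 0.05 * cfg.n1_amp_mV)
    if cortical.any():
        ci = idx[cortical]
        ramp = 0.2 + 0.8 * (ci - ci[0]) / max(ci[-1] - ci[0], 1.0)
        p1[cortical] = cfg.p1_amp_mV * ramp
        n1[cortical] = cfg.n1_amp_mV * ramp
        p1[labels == "WM"] = 0.3 * cfg.p1_amp_mV
        n1[labels == "WM"] = 0.3 * cfg.n1_amp_mV
    # AC potential: monotone sigmoid in depth, steepest (max E-field) at the
    # centre of layers 2/3, nearly flat above the cortex.
    l23 = np.flatnonzero(labels == "L23")
    centre = l23.mean() if l23.size else n / 2.0
    sig = 1.0 / (1.0 + np.exp(-(idx - centre) / 1.5))
    pot = cfg.ac_scalp_amplitude_mV * (0.3 + 0.7 * sig)
    return p1, n1, pot


def _onset_schedule(cfg: SynthConfig) -> np.ndarray:
    """Stimulus onsets at the flash rate, inside the ramp-free plateau."""
    start = cfg.ramp_s + 0.5
    stop = cfg.duration_s - cfg.ramp_s - 0.5
    if stop - start < 1.0 / cfg.flash_rate_hz:
        raise ValueError("duration too short for at least one trial after ramps")
    return np.arange(start, stop, 1.0 / cfg.flash_rate_hz)


def _modulation_factor(cfg: SynthConfig, phases_deg: np.ndarray) -> np.ndarray:
    phi = np.deg2rad(phases_deg - cfg.preferred_phase_deg)
    m = cfg.modulation_depth
    if cfg.modulation_mode == "unimodal":
        return 1.0 + m * np.cos(phi)
    if cfg.modulation_mode == "axial":
        return 1.0 + m * np.cos(2.0 * phi)
    return np.ones_like(phases_deg)


def _ac_envelope(t_s: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Cosine ramp-up / plateau / cosine ramp-down amplitude envelope."""
    env = np.ones_like(t_s)
    up = t_s < cfg.ramp_s
    env[up] = 0.5 * (1.0 - np.cos(np.pi * t_s[up] / cfg.ramp_s))
    t_end = t_s[-1]
    down = t_s > t_end - cfg.ramp_s
    env[down] = 0.5 * (1.0 - np.cos(np.pi * (t_end - t_s[down]) / cfg.ramp_s))
    return env


def _spike_template(fs: float) -> np.ndarray:
    """1 ms biphasic spike shape, unit positive peak followed by a trough."""
    n = max(int(round(1e-3 * fs)), 4)
    t = np.arange(n) / n
    w = np.sin(np.pi * t) * np.cos(np.pi * (t - 0.25))
    return w / w.max()


def _early_sink_kernels(cfg: SynthConfig, t_ms: np.ndarray) -> np.ndarray:
    """Depth-localized early negative deflection centred on layer 4C."""
    labels = np.array(cfg.layer_labels)
    l4c = np.flatnonzero(labels == "L4C")
    if cfg.early_sink_amp_mV == 0 or l4c.size == 0:
        return np.zeros((cfg.n_contacts, t_ms.size))
    centre = l4c.mean()
    depth = np.exp(-0.5 * ((np.arange(cfg.n_contacts) - centre)
                           / cfg.early_sink_depth_sigma) ** 2)
    tcourse = -np.exp(-0.5 * ((t_ms - cfg.early_sink_latency_ms)
                              / cfg.early_sink_sigma_ms) ** 2)
    tcourse[t_ms < 0] = 0.0
    return cfg.early_sink_amp_mV * depth[:, None] * tcourse[None, :]


def _build_lfp(cfg: SynthConfig, with_ac: bool, factors: np.ndarray,
               onsets: np.ndarray, p1: np.ndarray, n1: np.ndarray,
               pot: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Compose the physical-mV LFP stream (contacts x samples)."""
    n_samp = int(round(cfg.duration_s * cfg.fs_lfp))
    t_s = np.arange(n_samp) / cfg.fs_lfp
    sig = np.zeros((cfg.n_contacts, n_samp))
    labels = np.array(cfg.layer_labels)
    modulated = np.isin(labels, cfg.modulated_layers)

    kern_t = np.arange(0.0, 300.0, 1000.0 / cfg.fs_lfp)
    kernels = np.stack([
        evoked_kernel(kern_t, p1[c], n1[c], cfg.p1_latency_ms, cfg.n1_latency_ms)
        for c in range(cfg.n_contacts)])
    kernels += _early_sink_kernels(cfg, kern_t)
    for k, t0 in enumerate(onsets):
        i0 = int(round(t0 * cfg.fs_lfp))
        sl = slice(i0, min(i0 + kern_t.size, n_samp))
        span = sl.stop - sl.start
        gains = np.where(modulated, factors[k], 1.0)
        sig[:, sl] += gains[:, None] * kernels[:, :span]

    if with_ac and cfg.ac_scalp_amplitude_mV > 0:
        carrier = np.cos(2.0 * np.pi * cfg.ac_hz * t_s) * _ac_envelope(t_s, cfg)
        sig += pot[:, None] * carrier[None, :]

    if cfg.noise_sd_mV > 0:
        common = _pink_noise(rng, n_samp)
        for c in range(cfg.n_contacts):
            sig[c] += cfg.noise_sd_mV * (
                _pink_noise(rng, n_samp) + cfg.common_mode_frac * common)
    if cfg.line_60hz_mV > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        sig += cfg.line_60hz_mV * np.cos(2 * np.pi * 60.0 * t_s + phase0)[None, :]
    return sig


def _build_wideband(cfg: SynthConfig, lfp_mV: np.ndarray, onsets: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Wideband stream: interpolated LFP + white noise + Poisson spikes."""
    n_wb = int(round(cfg.duration_s * cfg.fs_wideband))
    up = cfg.fs_wideband / cfg.fs_lfp
    if abs(up - round(up)) > 1e-9:
        raise ValueError("fs_wideband must be an integer multiple of fs_lfp")
    labels = np.array(cfg.layer_labels)
    tmpl = _spike_template(cfg.fs_wideband)
    w0, w1 = cfg.mua_evoked_window_ms
    # the wideband stream carries only the LFP-band portion of the slow
    # signal; broadband pink noise would otherwise dominate the spike band
    sos = sp_signal.butter(4, 150.0, btype="lowpass", fs=cfg.fs_lfp, output="sos")
    slow = sp_signal.sosfiltfilt(sos, lfp_mV, axis=1)
    wb = np.empty((cfg.n_contacts, n_wb), dtype=np.float64)
    for c in range(cfg.n_contacts):
        # polyphase upsampling: no spectral images of the LFP grid leak into
        # the spike band
        trace = sp_signal.resample_poly(slow[c], int(round(up)), 1)[:n_wb]
        if trace.size < n_wb:
            trace = np.pad(trace, (0, n_wb - trace.size))
        trace += cfg.wb_noise_sd_mV * rng.standard_normal(n_wb)
        lab = labels[c]
        times = []
        r0 = cfg.mua_baseline_hz.get(lab, 0.0)
        if r0 > 0:
            n_base = rng.poisson(r0 * cfg.duration_s)
            times.append(rng.uniform(0, cfg.duration_s, n_base))
        r1 = cfg.mua_evoked_hz.get(lab, 0.0)
        if r1 > 0:
            dur = (w1 - w0) / 1000.0
            for t0 in onsets:
                n_ev = rng.poisson(r1 * dur)
                times.append(t0 + rng.uniform(w0, w1, n_ev) / 1000.0)
        if times:
            spikes = np.sort(np.concatenate(times))
            for ts in spikes:
                i0 = int(round(ts * cfg.fs_wideband))
                sl = slice(i0, min(i0 + tmpl.size, n_wb))
                trace[sl] += cfg.spike_amp_mV * tmpl[:sl.stop - sl.start]
        wb[c] = trace
    return wb


def generate_session(cfg: SynthConfig) -> Tuple[RecordingSession, RecordingSession, GroundTruth]:
    """Generate a paired Flash / Flash+AC session with known ground truth.

    The two conditions share the stimulus schedule and injected profiles but
    use independent noise streams spawned from the master seed (stream order:
    flash LFP noise, flash+AC LFP noise, flash wideband, flash+AC wideband).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_f, rng_a, rng_fw, rng_aw = (np.random.default_rng(s) for s in ss.spawn(4))

    onsets = _onset_schedule(cfg)
    phases = wrap_deg(360.0 * cfg.ac_hz * onsets)
    factors = _modulation_factor(cfg, phases)
    p1, n1, pot = _amp_profiles(cfg)

    flash_mV = _build_lfp(cfg, False, np.ones_like(factors), onsets, p1, n1, pot, rng_f)
    ac_mV = _build_lfp(cfg, True, factors, onsets, p1, n1, pot, rng_a)

    def _mk(sig_mV, cond, rng_wb):
        wb = None
        if cfg.include_wideband:
            wb = cfg.gain * _build_wideband(cfg, sig_mV, onsets, rng_wb)
        return RecordingSession(
            lfp_signals=cfg.gain * sig_mV, fs_lfp=cfg.fs_lfp,
            stim_onsets_s=onsets, condition=cond,
            contact_spacing_mm=cfg.spacing_mm, gain=cfg.gain,
            ac_frequency_hz=cfg.ac_hz, ramp_s=cfg.ramp_s,
            wideband_signals=wb,
            fs_wideband=cfg.fs_wideband if wb is not None else None)

    flash = _mk(flash_mV, FLASH, rng_fw)
    flash_ac = _mk(ac_mV, FLASH_AC, rng_aw)

    kern_t = np.arange(-50.0, 250.0 + 0.5, 1.0)
    clean = np.stack([
        evoked_kernel(kern_t, p1[c], n1[c], cfg.p1_latency_ms, cfg.n1_latency_ms)
        for c in range(cfg.n_contacts)])
    clean += _early_sink_kernels(cfg, kern_t)
    spacing = cfg.spacing_mm
    truth = GroundTruth(
        config=cfg, onsets_s=onsets, phases_deg=phases,
        modulation_factor=factors,
        p1_amp_profile_mV=p1, n1_amp_profile_mV=n1,
        potential_profile_mV=pot,
        efield_profile_V_per_m=np.gradient(pot, spacing),
        layer_labels=cfg.layer_labels,
        clean_evoked_mV=clean, clean_evoked_t_ms=kern_t)
    return flash, flash_ac, truth
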