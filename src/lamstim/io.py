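"""Session/epoch data model, HDF5 container I/O, CSV export and configuration.

The package stores continuous laminar recordings in a small HDF5 layout::

    /lfp/data        float32 [n_contacts, n_samples]   (acquisition units)
    /lfp  @fs_hz     float64 sampling rate
    /wideband/data   optional float32 [n_contacts, n_samples_wb]
    /wideband @fs_hz float64
    /onsets/stim_onsets_s  float64 ascending stimulus onset times (s)
    /meta @contact_spacing_mm @gain @condition @ac_frequency_hz @ramp_s

Signals are stored exactly as acquired, i.e. multiplied by the headstage
gain; analyses that need physical millivolts divide the gain out explicitly.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lamstim")

FLASH = "FLASH"
FLASH_AC = "FLASH_AC"
_CONDITIONS = (FLASH, FLASH_AC)

#: epoch window, closed at both ends, sampled at 1 kHz -> 301 samples
EPOCH_START_MS = -50
EPOCH_STOP_MS = 250
EPOCH_FS_HZ = 1000.0


class FormatError(ValueError):
    """Raised when a container file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a structural invariant."""


@dataclass
class RecordingSession:
    """One continuous laminar recording with its stimulus schedule.

    ``lfp_signals`` holds the LFP-band stream (contacts x samples) in
    acquisition units (physical mV times ``gain``).  ``wideband_signals``
    optionally holds a high-rate stream for multi-unit analysis.
    """

    lfp_signals: np.ndarray
    fs_lfp: float
    stim_onsets_s: np.ndarray
    condition: str
    contact_spacing_mm: float = 0.1
    gain: float = 10.0
    ac_frequency_hz: float = 1.5
    ramp_s: float = 30.0
    wideband_signals: Optional[np.ndarray] = None
    fs_wideband: Optional[float] = None

    def __post_init__(self) -> None:
        self.lfp_signals = np.asarray(self.lfp_signals, dtype=np.float64)
        self.stim_onsets_s = np.asarray(self.stim_onsets_s, dtype=np.float64)
        self.validate()

    @property
    def n_contacts(self) -> int:
        return self.lfp_signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp_signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_lfp

    def validate(self) -> None:
        if self.lfp_signals.ndim != 2:
            raise ValidationError("lfp_signals must be 2-D (contacts x samples)")
        if self.n_contacts < 3:
            raise ValidationError("need at least 3 contacts")
        if self.gain <= 0:
            raise ValidationError("gain must be positive")
        if self.condition not in _CONDITIONS:
            raise ValidationError(f"condition must be one of {_CONDITIONS}")
        onsets = self.stim_onsets_s
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValidationError("stim_onsets_s must be strictly increasing")
        if onsets.size and (onsets[0] < 0 or onsets[-1] > self.duration_s):
            raise ValidationError("stimulus onset outside the recording")
        if self.wideband_signals is not None:
            if self.fs_wideband is None:
                raise ValidationError("wideband present but fs_wideband missing")
            # Nyquist headroom for the 5 kHz upper MUA band edge
            if self.fs_wideband < 4 * 5000.0:
                raise ValidationError("fs_wideband must be >= 20 kHz")

    def replace(self, **kw) -> "RecordingSession":
        return dataclasses.replace(self, **kw)


@dataclass
class EpochSet:
    """Trials x contacts x time array in a fixed peri-stimulus window."""

    data: np.ndarray
    t_ms: np.ndarray
    condition: str
    baseline_corrected: bool = False
    keep_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be trials x contacts x time")
        if self.data.shape[2] != self.t_ms.size:
            raise ValidationError("time axis does not match data")
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.keep_mask = np.asarray(self.keep_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.data.shape[1]

    def kept(self) -> np.ndarray:
        return self.data[self.keep_mask]


def default_epoch_axis() -> np.ndarray:
    n = int(round((EPOCH_STOP_MS - EPOCH_START_MS) / 1000.0 * EPOCH_FS_HZ)) + 1
    return EPOCH_START_MS + np.arange(n) * 1000.0 / EPOCH_FS_HZ


@dataclass
class AnalysisConfig:
    """All stage parameters with study defaults.

    Defaults follow the recording/analysis protocol: LFP band 0.5-100 Hz
    (4th-order Butterworth, zero-phase) with a 60 Hz notch, downsampling to
    1 kHz, -50..250 ms epochs with a -50..0 ms baseline, +-5 SD trial
    rejection, P1 in 55-90 ms, N1 in 100-140 ms, 20 phase bins of 18 deg,
    5000 phase shuffles at the 95% criterion, 2000 cluster permutations at
    critical value 0.01, MUA band 300-5000 Hz with threshold factor 3.5.
    """

    lfp_band_hz: tuple = (0.5, 100.0)
    lfp_filter_order: int = 4
    notch_hz: float = 60.0
    notch_q: float = 35.0
    target_fs_hz: float = 1000.0
    epoch_window_ms: tuple = (EPOCH_START_MS, EPOCH_STOP_MS)
    baseline_window_ms: tuple = (-50.0, 0.0)
    reject_sd: float = 5.0
    p1_window_ms: tuple = (55.0, 90.0)
    n1_window_ms: tuple = (100.0, 140.0)
    ac_band_hz: tuple = (0.5, 2.0)
    sobi_n_lags: int = 50
    sobi_max_lag_ms: float = 500.0
    ac_ratio_threshold: float = 50.0
    n_phase_bins: int = 20
    n_perm_phase: int = 5000
    phase_sig_percentile: float = 95.0
    n_perm_cluster: int = 2000
    cluster_alpha: float = 0.01
    cluster_forming_alpha: float = 0.05
    cluster_adjacency: str = "spatiotemporal"
    mua_band_hz: tuple = (300.0, 5000.0)
    mua_alpha: float = 3.5
    psth_bin_ms: float = 10.0
    phase_lock_window_deg: float = 45.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lfp_band_hz", "epoch_window_ms", "baseline_window_ms",
                    "p1_window_ms", "n1_window_ms", "ac_band_hz", "mua_band_hz"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# HDF5 container


def write_session(session: RecordingSession, path: str, force: bool = False) -> None:
    """Write a session to the HDF5 container; refuses to overwrite by default."""
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    with h5py.File(path, "w") as h5:
        g = h5.create_group("lfp")
        g.create_dataset("data", data=session.lfp_signals.astype(np.float32))
        g.attrs["fs_hz"] = float(session.fs_lfp)
        if session.wideband_signals is not None:
            w = h5.create_group("wideband")
            w.create_dataset("data", data=session.wideband_signals.astype(np.float32))
            w.attrs["fs_hz"] = float(session.fs_wideband)
        o = h5.create_group("onsets")
        o.create_dataset("stim_onsets_s", data=session.stim_onsets_s.astype(np.float64))
        m = h5.create_group("meta")
        m.attrs["contact_spacing_mm"] = float(session.contact_spacing_mm)
        m.attrs["gain"] = float(session.gain)
        m.attrs["condition"] = session.condition
        m.attrs["ac_frequency_hz"] = float(session.ac_frequency_hz)
        m.attrs["ramp_s"] = float(session.ramp_s)


def read_session(path: str) -> RecordingSession:
    """Read and validate a session from the HDF5 container."""
    with h5py.File(path, "r") as h5:
        for group in ("lfp", "onsets", "meta"):
            if group not in h5:
                raise FormatError(f"container missing required group '{group}'")
        if "data" not in h5["lfp"] or "fs_hz" not in h5["lfp"].attrs:
            raise FormatError("container missing /lfp/data or fs_hz attribute")
        if "stim_onsets_s" not in h5["onsets"]:
            raise FormatError("container missing /onsets/stim_onsets_s")
        meta = h5["meta"].attrs
        for key in ("contact_spacing_mm", "gain", "condition",
                    "ac_frequency_hz", "ramp_s"):
            if key not in meta:
                raise FormatError(f"container missing /meta attribute '{key}'")
        wb = None
        fs_wb = None
        if "wideband" in h5:
            wb = np.asarray(h5["wideband/data"], dtype=np.float64)
            fs_wb = float(h5["wideband"].attrs["fs_hz"])
        condition = meta["condition"]
        if isinstance(condition, bytes):
            condition = condition.decode()
        return RecordingSession(
            lfp_signals=np.asarray(h5["lfp/data"], dtype=np.float64),
            fs_lfp=float(h5["lfp"].attrs["fs_hz"]),
            stim_onsets_s=np.asarray(h5["onsets/stim_onsets_s"], dtype=np.float64),
            condition=str(condition),
            contact_spacing_mm=float(meta["contact_spacing_mm"]),
            gain=float(meta["gain"]),
            ac_frequency_hz=float(meta["ac_frequency_hz"]),
            ramp_s=float(meta["ramp_s"]),
            wideband_signals=wb,
            fs_wideband=fs_wb,
        )


# ---------------------------------------------------------------------------
# CSV export

#: result-family -> filename; every value in a bundle must be a DataFrame
_RESULT_FILES = {
    "components": "components.csv",
    "circular": "phase_results.csv",
    "clusters": "clusters.csv",
    "psth": "psth.csv",
    "field_profile": "field_profile.csv",
    "layers": "layers.csv",
    "rate_tests": "rate_tests.csv",
    "qc": "qc.csv",
}


def export_results(bundle: dict, out_dir: str) -> list:
    """Write one CSV per result family; returns the list of paths written.

    Files are UTF-8 with a header row and '.' decimal separator, and are
    byte-identical across re-exports of identical inputs.
    """
    if not bundle:
        raise ValueError("empty result bundle")
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for family, table in bundle.items():
        fname = _RESULT_FILES.get(family, f"{family}.csv")
        path = os.path.join(out_dir, fname)
        df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
        written.append(path)
        logger.info("exported %s (%d rows)", path, len(df))
    return written
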