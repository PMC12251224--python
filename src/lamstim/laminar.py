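"""Current source density, layer assignment, layer averaging, normalization.

CSD is the plain second spatial difference of the laminar LFP profile
(no spline smoothing, unit conductivity), signed so that current sinks
are negative.  Contacts are assigned to cortical layers by combining the
stimulation-field rise (layer 1 boundary), the earliest post-stimulus CSD
sink (layer 4C), and prior layer extents in contacts; this codifies a
procedure that in practice also draws on anatomical references.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io import EpochSet, ValidationError
from .biophys import FieldProfile

logger = logging.getLogger("lamstim")

CORTICAL_LAYERS = ("L1", "L23", "L4AB", "L4C", "L56")

#: prior layer extents, in contacts, pial to deep
DEFAULT_PRIORS: Dict[str, int] = {"L1": 2, "L23": 6, "L4AB": 2, "L4C": 4, "L56": 4}


@dataclass
class CSDProfile:
    csd: np.ndarray            # interior contacts x time
    spacing_mm: float
    sign_convention: str = "sinks_negative"
    contact_offset: int = 1    # csd row i maps to contact i + offset


@dataclass
class LayerMap:
    labels: Tuple[str, ...]    # per contact
    provenance: str            # csd+field | prior | manual

    def contacts(self, layer: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.labels) == layer)

    def present_layers(self) -> Tuple[str, ...]:
        seen = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def to_frame(self, spacing_mm: float = 0.1) -> pd.DataFrame:
        n = len(self.labels)
        return pd.DataFrame({
            "contact": np.arange(n),
            "depth_mm": np.arange(n) * spacing_mm,
            "label": list(self.labels),
            "provenance": self.provenance,
        })


def compute_csd(evoked_avg: np.ndarray, spacing_mm: float) -> CSDProfile:
    """Second spatial derivative of the laminar LFP, sinks negative.

    ``csd_i(t) = -(phi_{i-1} - 2 phi_i + phi_{i+1}) / spacing^2`` at interior
    contacts; under this sign a local extracellular potential maximum (a
    current source) maps to positive CSD.
    """
    phi = np.atleast_2d(np.asarray(evoked_avg, dtype=np.float64))
    if phi.shape[0] < 3:
        raise ValidationError("CSD needs at least 3 contacts")
    if spacing_mm <= 0:
        raise ValidationError("spacing must be positive")
    second = phi[:-2] - 2.0 * phi[1:-1] + phi[2:]
    return CSDProfile(csd=-second / spacing_mm ** 2, spacing_mm=spacing_mm)


def _field_rise_contact(field: FieldProfile, n_ref: int = 3, k: float = 2.0):
    """First contact where |E| exceeds the outside-cortex mean + k*SD."""
    e = np.abs(field.efield_V_per_m)
    ref = e[:n_ref]
    thresh = ref.mean() + k * ref.std(ddof=0)
    above = np.flatnonzero(e > thresh)
    above = above[above >= 1]  # the very first contact cannot define a rise
    return int(above[0]) if above.size else None


def _earliest_sink_contact(csd: CSDProfile, t_ms: np.ndarray,
                           window_ms=(30.0, 90.0)) -> Optional[int]:
    """Interior contact with the earliest strong post-stimulus sink."""
    mask = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    seg = csd.csd[:, mask]
    gmin = seg.min()
    if gmin >= 0:
        return None
    thresh = 0.5 * gmin
    onset = np.full(seg.shape[0], np.inf)
    for i in range(seg.shape[0]):
        below = np.flatnonzero(seg[i] < thresh)
        if below.size:
            onset[i] = below[0]
    if not np.isfinite(onset).any():
        return None
    earliest = onset.min()
    cands = np.flatnonzero(onset == earliest)
    # break ties toward the strongest sink
    best = cands[np.argmin(seg[cands].min(axis=1))]
    return int(best + csd.contact_offset)


def assign_layers(csd: CSDProfile, field_prof: FieldProfile, t_ms: np.ndarray,
                  priors: Optional[Dict[str, int]] = None) -> LayerMap:
    """Assign every contact a layer label from CSD, field and priors.

    Layer 1 starts where the stimulation field rises above the
    outside-cortex level; layer 4C is centred on the earliest post-stimulus
    CSD sink; the remaining boundaries are filled in from the prior extents.
    Falls back to a pure-prior stack (with a warning) when neither landmark
    is found.  Deterministic given its inputs.
    """
    pri = dict(DEFAULT_PRIORS)
    if priors:
        pri.update(priors)
    n = field_prof.efield_V_per_m.size
    if csd.csd.shape[0] + 2 != n:
        raise ValidationError("CSD and field profiles cover different contacts")

    l1_start = _field_rise_contact(field_prof)
    sink = _earliest_sink_contact(csd, t_ms)
    provenance = "csd+field"
    if l1_start is None:
        warnings.warn("no field rise found; falling back to prior layer extents")
        provenance = "prior"
        l1_start = 3 if n >= 20 else 1
    if sink is None:
        provenance = "prior" if provenance == "prior" else "field+prior"
        sink = l1_start + pri["L1"] + pri["L23"] + pri["L4AB"] + pri["L4C"] // 2

    # stack layers downward from L1; anchor 4C on the sink when consistent
    l4c_start = sink - pri["L4C"] // 2 + 1
    min_l4c = l1_start + pri["L1"] + 2 + pri["L4AB"]   # >= 2 contacts of L2/3
    if l4c_start < min_l4c:
        l4c_start = l1_start + pri["L1"] + pri["L23"] + pri["L4AB"]
    l4ab_start = l4c_start - pri["L4AB"]
    l23_start = l1_start + pri["L1"]
    l56_start = l4c_start + pri["L4C"]

    labels = ["OUTSIDE"] * n
    spans = [("L1", l1_start, l23_start), ("L23", l23_start, l4ab_start),
             ("L4AB", l4ab_start, l4c_start), ("L4C", l4c_start, l56_start),
             ("L56", l56_start, l56_start + pri["L56"])]
    for lab, lo, hi in spans:
        for c in range(max(lo, 0), min(hi, n)):
            labels[c] = lab
    for c in range(min(l56_start + pri["L56"], n), n):
        labels[c] = "WM"
    logger.info("layer map (%s): L1@%d, 4C sink@%s", provenance, l1_start, sink)
    return LayerMap(labels=tuple(labels), provenance=provenance)


def layer_average(epochs: EpochSet, layers: LayerMap) -> Tuple[EpochSet, Tuple[str, ...]]:
    """Average epochs over the contacts of each layer.

    Returns an epoch set whose channel axis enumerates the layers present
    (probe order) plus the layer-name tuple.  Layers with no contacts are
    omitted with a warning.  The trial axis and keep mask are unchanged.
    """
    if len(layers.labels) != epochs.n_contacts:
        raise ValidationError("layer map does not cover the epoch contacts")
    names = []
    traces = []
    for lab in layers.present_layers():
        idx = layers.contacts(lab)
        if idx.size == 0:
            warnings.warn(f"layer {lab} has no contacts; omitted")
            continue
        names.append(lab)
        traces.append(epochs.data[:, idx, :].mean(axis=1))
    data = np.stack(traces, axis=1)
    out = EpochSet(data=data, t_ms=epochs.t_ms, condition=epochs.condition,
                   baseline_corrected=epochs.baseline_corrected,
                   keep_mask=epochs.keep_mask.copy())
    return out, tuple(names)


def normalize_lfp(traces: np.ndarray, layer_names, ref_layer: str = "L56") -> np.ndarray:
    """Scale traces by the largest absolute value of the reference layer.

    After normalization the reference (deep-layer) trace has peak magnitude
    one; the operation is idempotent and scale-invariant.
    """
    names = list(layer_names)
    if ref_layer not in names:
        raise ValidationError(f"reference layer {ref_layer} not present")
    ref = traces[names.index(ref_layer)]
    denom = np.abs(ref).max()
    if denom == 0:
        raise ValidationError("reference-layer trace is all zero")
    return np.asarray(traces, dtype=np.float64) / denom
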