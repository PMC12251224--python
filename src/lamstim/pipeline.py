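"""End-to-end analysis pipeline for a Flash / Flash+AC session pair.

Stages, in order: AC phase labelling from the raw stimulation-condition
record (the narrowband artifact itself defines phase, so labels are taken
before cleaning removes it); LFP filtering of both conditions; artifact
removal from the stimulation condition; epoching, baseline correction and
trial rejection; stimulation field profile; CSD and layer assignment from
the no-stimulation condition; layer-averaged P1/N1 components; circular
phase statistics per layer with the virtual-AC negative control; the
cluster-based condition comparison; and, when a wideband stream is
present, the multi-unit analyses.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import artifact as _artifact
from . import biophys as _biophys
from . import clusterstat as _cluster
from . import laminar as _laminar
from . import mua as _mua
from . import phasedep as _phase
from . import preprocess as _pre
from .io import AnalysisConfig, FLASH, FLASH_AC, RecordingSession, ValidationError

logger = logging.getLogger("lamstim")

ANALYSIS_LAYERS = ("L23", "L4AB", "L4C", "L56")


@dataclass
class RunReport:
    config: Dict
    seed: int
    tables: Dict[str, pd.DataFrame]
    qc: Dict[str, float]

    def to_csvs(self, out_dir: str):
        from .io import export_results
        bundle = dict(self.tables)
        bundle["qc"] = pd.DataFrame([self.qc])
        return export_results(bundle, out_dir)


def _phase_table(amp_table: pd.DataFrame, labels, layer_names, cfg,
                 seed: int, control: str) -> pd.DataFrame:
    rows = []
    valid = labels.valid
    for lab in layer_names:
        if lab not in ANALYSIS_LAYERS:
            continue
        sub = amp_table[amp_table["channel"] == lab]
        kept = sub["kept"].to_numpy() & valid
        for comp, col in (("P1", "p1_amp"), ("N1", "n1_amp")):
            amps = np.abs(sub[col].to_numpy()[kept])
            phis = labels.phase_deg[kept]
            for mode in ("unimodal", "axial"):
                res = _phase.permutation_test_phase(
                    amps, phis, mode=mode, n_perm=cfg.n_perm_phase,
                    seed=seed, n_bins=cfg.n_phase_bins,
                    sig_percentile=cfg.phase_sig_percentile)
                rows.append({
                    "layer": lab, "component": comp, "mode": mode,
                    "control": control,
                    "direction_deg": res.mean_direction_deg,
                    "R": res.vector_length, "z": res.z_score,
                    "p": res.p_value, "n_perm": res.n_perm,
                    "n_trials": int(kept.sum()),
                    "significant": res.significant,
                })
    return pd.DataFrame(rows)


def run_all(flash: RecordingSession, flash_ac: RecordingSession,
            config: Optional[AnalysisConfig] = None) -> RunReport:
    """Run the full laminar phase-dependence analysis on a session pair."""
    cfg = config or AnalysisConfig()
    seed = cfg.seed
    if flash.condition != FLASH or flash_ac.condition != FLASH_AC:
        raise ValidationError("condition labels are swapped or invalid")
    qc: Dict[str, float] = {}
    tables: Dict[str, pd.DataFrame] = {}

    # --- phase labels from the raw stimulation record ---------------------
    ac_raw = _biophys.extract_ac_waveform(flash_ac, cfg)
    ref_contact = int(np.argmax(np.abs(ac_raw).max(axis=1)))
    labels_ac = _biophys.phase_at_onsets(ac_raw[ref_contact], cfg.target_fs_hz,
                                         flash_ac.stim_onsets_s,
                                         f0=flash_ac.ac_frequency_hz)
    qc["rayleigh_p"] = _phase.rayleigh_test(labels_ac)
    qc["phase_reference_contact"] = ref_contact

    # --- field profile ----------------------------------------------------
    prof = _biophys.field_profile(flash_ac, cfg)
    tables["field_profile"] = prof.to_frame(flash_ac.contact_spacing_mm)

    # --- filter, clean, epoch ---------------------------------------------
    flash_f = _pre.filter_lfp(flash, cfg)
    ac_f = _pre.filter_lfp(flash_ac, cfg)
    f0 = flash_ac.ac_frequency_hz
    before = _artifact.plateau_band_power(ac_f, f0)
    ac_clean, model = _artifact.remove_ac_artifact(ac_f, cfg)
    after = _artifact.plateau_band_power(ac_clean, f0)
    qc["artifact_attenuation_db"] = 10 * np.log10(before / max(after, 1e-300))
    qc["n_sources_flagged"] = int(model.ac_flags.sum())

    ep_flash = _pre.reject_trials(_pre.epoch_and_baseline(flash_f, cfg), cfg.reject_sd)
    ep_ac = _pre.reject_trials(_pre.epoch_and_baseline(ac_clean, cfg), cfg.reject_sd)
    if ep_ac.n_trials != labels_ac.n_trials:
        # epoching only drops onsets at the record tail; keep labels aligned
        labels_ac.phase_deg = labels_ac.phase_deg[:ep_ac.n_trials]
        labels_ac.valid = labels_ac.valid[:ep_ac.n_trials]
    qc["flash_trials_kept"] = int(ep_flash.keep_mask.sum())
    qc["flash_ac_trials_kept"] = int(ep_ac.keep_mask.sum())

    # --- layers -----------------------------------------------------------
    evoked = ep_flash.kept().mean(axis=0)
    csd = _laminar.compute_csd(evoked, flash.contact_spacing_mm)
    layer_map = _laminar.assign_layers(csd, prof, ep_flash.t_ms)
    tables["layers"] = layer_map.to_frame(flash.contact_spacing_mm)

    lay_flash, names_f = _laminar.layer_average(ep_flash, layer_map)
    lay_ac, names_a = _laminar.layer_average(ep_ac, layer_map)

    comp_ac = _pre.extract_components(lay_ac, cfg, channel_names=names_a)
    comp_flash = _pre.extract_components(lay_flash, cfg, channel_names=names_f)
    comp_ac["condition"] = FLASH_AC
    comp_flash["condition"] = FLASH
    tables["components"] = pd.concat([comp_flash, comp_ac], ignore_index=True)

    # --- phase dependence + virtual-AC control ----------------------------
    circ_ac = _phase_table(comp_ac, labels_ac, names_a, cfg, seed, control="ac")
    labels_virtual = _biophys.virtual_ac_labels(flash, f0=f0)
    n_virtual = min(labels_virtual.n_trials, ep_flash.n_trials)
    labels_virtual.phase_deg = labels_virtual.phase_deg[:n_virtual]
    labels_virtual.valid = labels_virtual.valid[:n_virtual]
    circ_virtual = _phase_table(comp_flash, labels_virtual, names_f, cfg,
                                seed + 1, control="virtual")
    tables["circular"] = pd.concat([circ_ac, circ_virtual], ignore_index=True)

    # --- cluster comparison ----------------------------------------------
    cres = _cluster.cluster_permutation_test(
        ep_ac, ep_flash, n_perm=cfg.n_perm_cluster, alpha=cfg.cluster_alpha,
        forming_alpha=cfg.cluster_forming_alpha,
        adjacency=cfg.cluster_adjacency, seed=seed + 2)
    tables["clusters"] = cres.to_frame(ep_flash.t_ms)
    qc["n_significant_clusters"] = len(cres.significant_clusters())

    # --- multi-unit activity ---------------------------------------------
    if flash.wideband_signals is not None and flash_ac.wideband_signals is not None:
        tables.update(_mua_stage(flash, flash_ac, labels_ac, layer_map, cfg))
        qc["mua_skipped"] = 0
    else:
        logger.warning("no wideband stream; MUA stage skipped")
        qc["mua_skipped"] = 1

    return RunReport(config=dataclasses.asdict(cfg), seed=seed,
                     tables=tables, qc=qc)


def _mua_stage(flash, flash_ac, labels_ac, layer_map, cfg):
    out = {}
    psths = {}
    for sess, tag in ((flash, FLASH), (flash_ac, FLASH_AC)):
        filt = _mua.filter_mua(sess, cfg)
        spikes = _mua.detect_spikes(filt, sess.fs_wideband, cfg.mua_alpha)
        psths[tag] = _mua.compute_psth(spikes, sess.stim_onsets_s, layer_map,
                                       cfg.psth_bin_ms)
    frames = []
    for tag, p in psths.items():
        f = p.to_frame()
        f["condition"] = tag
        frames.append(f)
    out["psth"] = pd.concat(frames, ignore_index=True)

    rows = []

    def _rates(p, lab):
        return p.trial_rates[:, p.layer_names.index(lab)]

    for tag, p in psths.items():
        if "L23" in p.layer_names and "L56" in p.layer_names:
            t, pv = _mua.compare_firing(_rates(p, "L23"), _rates(p, "L56"), "paired")
            rows.append({"comparison": f"L23_vs_L56_{tag}", "design": "paired",
                         "t": t, "p": pv})
    for lab in psths[FLASH].layer_names:
        if lab in psths[FLASH_AC].layer_names:
            t, pv = _mua.compare_firing(_rates(psths[FLASH], lab),
                                        _rates(psths[FLASH_AC], lab), "unpaired")
            rows.append({"comparison": f"{lab}_flash_vs_ac", "design": "unpaired",
                         "t": t, "p": pv})
    peak = _mua.select_phase_locked_trials(labels_ac, "peak", cfg.phase_lock_window_deg)
    trough = _mua.select_phase_locked_trials(labels_ac, "trough", cfg.phase_lock_window_deg)
    p_ac = psths[FLASH_AC]
    for lab in p_ac.layer_names:
        if lab not in ANALYSIS_LAYERS:
            continue
        r = p_ac.trial_rates[:, p_ac.layer_names.index(lab)]
        if peak.size >= 2 and trough.size >= 2:
            t, pv = _mua.compare_firing(r[peak], r[trough], "unpaired")
            rows.append({"comparison": f"{lab}_peak_vs_trough", "design": "unpaired",
                         "t": t, "p": pv})
    out["rate_tests"] = pd.DataFrame(rows)
    return out
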