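"""Multi-unit activity: detection, PSTHs, and layer-rate comparisons.

Spikes are threshold crossings of the 300-5,000 Hz band at
3.5 x median(|x|)/0.6745, binned into 10 ms peristimulus histograms.
The generator injects higher firing in deeper layers.
"""

import numpy as np

from lamstim import (SynthConfig, compare_firing, compute_psth, detect_spikes,
                     filter_mua, generate_session)
from lamstim.laminar import LayerMap

cfg = SynthConfig(seed=8, duration_s=30.0, ramp_s=3.0, include_wideband=True)
flash, _, truth = generate_session(cfg)

filt = filter_mua(flash)
spikes = detect_spikes(filt, flash.fs_wideband, alpha=3.5)
print(f"threshold at deepest cortical contact: {spikes.thresholds[20]:.3f} "
      "(acquisition units, = 3.5 robust noise SDs)")

lmap = LayerMap(labels=truth.layer_labels, provenance="manual")
psth = compute_psth(spikes, flash.stim_onsets_s, lmap)
for lab in ("L23", "L4C", "L56"):
    li = psth.layer_names.index(lab)
    print(f"{lab}: peak PSTH {psth.rates[li].max():6.1f} Hz, "
          f"mean trial rate {psth.trial_rates[:, li].mean():6.1f} Hz")

r23 = psth.trial_rates[:, psth.layer_names.index("L23")]
r56 = psth.trial_rates[:, psth.layer_names.index("L56")]
t, p = compare_firing(r23, r56, design="paired")
print(f"paired t, layers 2/3 vs 5/6: t = {t:.1f}, p = {p:.2e} "
      "(deep layers fire more, as injected)")
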