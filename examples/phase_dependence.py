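"""Phase-binned circular statistics of evoked-component amplitudes.

Trials are sorted into 20 bins of 18 degrees by their AC phase at flash
onset; the circular resultant of the per-bin mean amplitudes gives the
preferred phase and its strength (vector length R), and shuffling the
phase-amplitude pairing 5,000 times gives the significance.
"""

import numpy as np

from lamstim import bin_by_phase, circular_stats, permutation_test_phase

rng = np.random.default_rng(0)
phases = rng.uniform(-180, 180, 400)

# unimodal modulation: stronger responses on the falling zero-crossing
amps = 1.0 + 0.4 * np.cos(np.deg2rad(phases - (-90.0)))
amps = np.abs(amps + 0.25 * rng.standard_normal(400))
res = permutation_test_phase(amps, phases, mode="unimodal", n_perm=5000, seed=1)
print(f"unimodal: preferred phase {res.mean_direction_deg:+.1f} deg "
      f"(injected -90), R = {res.vector_length:.3f}, z = {res.z_score:.1f}, "
      f"p = {res.p_value:.4f}, significant = {res.significant}")

# axial (bimodal) modulation: two opposite preferred phases
amps2 = 1.0 + 0.4 * np.cos(2 * np.deg2rad(phases - 45.0))
amps2 = np.abs(amps2 + 0.25 * rng.standard_normal(400))
d_uni, r_uni = circular_stats(bin_by_phase(amps2, phases), "unimodal")
res2 = permutation_test_phase(amps2, phases, mode="axial", n_perm=5000, seed=2)
print(f"axial:    preferred axis {res2.mean_direction_deg:+.1f} deg "
      f"(injected 45, mod 180), axial R = {res2.vector_length:.3f}, "
      f"p = {res2.p_value:.4f}")
print(f"          unimodal R on the same data collapses to {r_uni:.3f} - "
      "opposite lobes cancel, which is why the axial variant exists")
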