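# Methods

## Data model and conventions

A recording session is a contacts × samples matrix in acquisition units
(physical millivolts times the headstage gain, default 10), with a
strictly increasing stimulus-onset list, a condition tag (FLASH or
FLASH_AC), the AC frequency (1.5 Hz) and the ramp duration (30 s).
Epochs span −50..250 ms at 1 kHz with both endpoints included — 301
samples — and are baseline-corrected over [−50, 0) ms. All angles are
degrees in outputs and radians internally, under a fixed cosine
convention: 0° at the artifact peak, ±180° at the trough, −90° on the
rising zero-crossing.

## Synthetic sessions and what they do (not) emulate

The generator is the package's test bed: every downstream stage is
validated against its known ground truth.

* **Evoked response.** Difference of two Gaussians — P1 (σ = 8 ms) at
  75 ms, N1 (σ = 12 ms) at 120 ms — zero before onset. Only the peak
  windows are constrained by the protocol; the Gaussian shape is our
  choice for smoothness and parameter transparency. Component
  amplitudes ramp linearly with depth across the cortical contacts
  (0.2→1.0 mV for P1, 1.5× that for N1), drop in white matter, and are
  near zero outside the cortex.
* **Early layer-4C input.** A depth-localized (σ = 1 contact) negative
  deflection at 45 ms gives the CSD its earliest post-stimulus sink;
  a purely linear depth profile would have zero CSD and leave layer
  assignment without its physiological landmark.
* **Artifact.** A 1.5 Hz cosine with 30 s cosine ramps, scaled per
  contact by a monotone sigmoid whose steepest slope sits at the centre
  of layers 2/3 — so the field (spatial gradient) peaks there and stays
  flat above the cortex. The artifact-to-evoked amplitude ratio at the
  probe is not constrained by the protocol; the default is 50:1.
* **Phase-dependent modulation.** Per-trial evoked gain
  a(φ) = a₀(1 + m·cos(φ − φ_pref)) (unimodal) or with doubled angle
  (axial), applied in a configurable layer set (default the deep
  layers), with m < 1 and φ the true AC phase at onset. The true phase
  is exactly 360°·f₀·t_k since the artifact starts as cos at t = 0.
* **Noise.** Pink (1/f amplitude, random phase) noise per contact, plus
  a shared common-mode pink term at 20 % SD emulating volume conduction;
  60 Hz line noise; defaults 0.1 mV and 0.05 mV against a 0.2–1 mV
  evoked response.
* **Wideband stream (optional).** The LFP-band content is low-passed at
  150 Hz and polyphase-upsampled to 20 kHz (plain interpolation would
  fold images of the 2 kHz grid into the spike band), plus white noise
  (5 µV) and 1 ms biphasic spikes (0.04 mV, positive lobe leading) at
  layer-dependent Poisson rates: baseline 5→15 Hz and evoked 20→60 Hz
  from layers 2/3 to 5/6, evoked spikes uniform over 20–150 ms
  post-flash. Spikes deliberately leak nothing into the LFP stream so
  LFP and MUA tests stay orthogonal.
* **Seeds.** Flash and Flash+AC use independent noise streams spawned
  from one master seed (order: flash LFP, flash+AC LFP, flash wideband,
  flash+AC wideband); everything is reproducible from the seed alone.

What the generator does **not** emulate: volume conduction beyond the
common-mode term, spontaneous oscillations and their intrinsic phase
coupling, spike waveform diversity, electrode drift, or the absolute
microvolt scales of any particular animal. Passing tests therefore show
the *estimators* are correct and calibrated, not that real recordings
will show the effect.

## Preprocessing

Band-pass 0.5–100 Hz, 4th-order Butterworth, applied forward–reverse
(`sosfiltfilt`): the protocol states the order but not phase handling;
latency analysis requires zero phase, at the cost of a doubled effective
roll-off. Notch: 2nd-order IIR at 60 Hz, Q = 35, also forward–reverse.
Downsampling is a plain stride after filtering (content above 100 Hz is
already gone); non-integer ratios are refused rather than silently
resampled. Trial rejection computes the across-trial mean ± 5 SD
envelope per contact and timepoint (the pooling axis is ambiguous in
prose; a per-trial-RMS alternative is exposed via `pooling=`), flags
any trial with a sample outside it, and keeps the data with a mask.
Zero SD rejects nothing. Peak searches break ties toward the earliest
sample.

## Artifact removal

SOBI: centre the record, whiten by eigendecomposition retaining
99.999 % of variance (the artifact dominates variance and must not be
truncated; a true rank deficiency warns and proceeds on the retained
rank), then jointly diagonalize symmetrized lagged covariance matrices
with Jacobi sweeps. The closed-form Givens angle for a pair (p,q) is
θ = ¼·atan2(2Σuᵥ, Σu² − Σv²) with u = (m_pp − m_qq)/2, v = m_pq — the
off-diagonal objective depends on 4θ, and this angle attains its
minimum (a single matrix reduces exactly to the eigenvector rotation).
Fifty log-spaced lags over 1–500 ms see both the slow artifact and
LFP-band structure.

Identification: a source is flagged when its power in f₀ ± 0.1 Hz
exceeds 50× its median power over 0.5–40 Hz. The threshold separates
artifact sources (ratios > 10⁶ on defaults) from the 1/f background,
whose ratio at 1.5 Hz is already ~15–35 because pink spectra
concentrate low-frequency power; harmonic bands (2f₀, 3f₀) are reported
but do not drive flags. Cleaning subtracts only the least-squares
cos/sin pair at f₀ from each flagged source — fitted excluding the
ramps, where the artifact is non-stationary — and back-projects, so
cleaned + removed reconstructions sum exactly to the input and any
neural signal riding on a flagged component survives. Attenuation QC is
measured on the ramp-free plateau for the same reason; epochs are drawn
only from the plateau.

## Field, phase and layers

The stimulation potential is the 0.5–2 Hz zero-phase narrowband of the
raw record divided by the gain; amplitude and phase at the dominant
frequency are read from an FFT cropped to an integer cycle count so the
tone sits on an exact bin. The field is the numerical gradient along
the probe (central differences inside, one-sided at the ends); mV over
mm is V/m. Phase labels use the analytic-signal angle at each onset
with a one-cycle edge guard; the reference contact is the one with the
largest artifact amplitude. Virtual-AC labels are the closed-form
phases of a fictitious cosine starting at record time zero.

CSD is the plain second spatial difference (no spline/iCSD, no spatial
smoothing, unit conductivity), signed so sinks are negative. Layer
assignment is deterministic: layer 1 starts at the first contact whose
|E| exceeds the outside-cortex mean + 2 SD (first three contacts as
reference); layer 4C is centred on the interior contact whose CSD first
crosses half the window minimum within 30–90 ms — the window ends
before N1 so boundary curvature at the white-matter edge cannot
masquerade as the earliest sink; the other boundaries follow prior
extents (L1 2, L2/3 6, L4AB 2, L4C 4, L5/6 4 contacts). Missing
landmarks fall back to the priors with a warning. On default synthetic
sessions boundaries are recovered within ±1 contact; a one-contact
error can leak a modulated contact into a neighbouring layer's average,
which is visible in end-to-end runs as a weak spurious preference in
the adjacent layer.

## Phase statistics

Binning: bin k covers [−180 + 18k, −180 + 18(k+1)) with the last bin
closed at +180; empty bins are recorded as missing. The circular
statistics weight the **bin means** (invariant to unequal bin counts;
bin sums would not be), using magnitudes — P1 as is, |N1| for the
negative component, since signed weights have no standard circular
interpretation; a signed mode exists but is off by default. Axial mode
doubles angles, halves the direction, and reports it in (−90°, 90°].

The permutation test shuffles the amplitude–phase pairing, recomputes R
per surrogate (vectorized over all shuffles), z-scores the observed R
against the surrogate mean/SD, reports the one-tailed
p = (b + 1)/(n + 1) (never zero), and calls significance when R exceeds
the 95th surrogate percentile — 5,000 shuffles by default. Surrogates
use the observed statistic's mode by default; `surrogate_mode` allows
the asymmetric comparison (axial observed vs unimodal surrogates) used
when bimodal data are scored against unimodal nulls. A degenerate
surrogate spread (constant amplitudes) is guarded with an absolute
1e-9 tolerance. The Rayleigh uniformity test is delegated to
`pingouin.circ_rayleigh`.

## Cluster statistics

Unpaired pooled-variance t at every (contact, time) cell over kept
trials; cells with |t| above the two-sided pointwise 0.05 threshold are
clustered — always along time, and across neighbouring contacts under
the default spatiotemporal adjacency (both modes exposed and recorded
in outputs, since observed clusters span several layers); positive and
negative clusters stay separate; mass = Σt. The null is the maximum
|mass| per label permutation (2,000 by default, computed from group
sufficient statistics via a single matrix product per statistic);
cluster p = (b + 1)/(n + 1), significant below the 0.01 critical value.
The smallest attainable p at 2,000 permutations is 1/2001.

## MUA

300–5,000 Hz 4th-order zero-phase band-pass; threshold
α·median(|x|)/0.6745 per contact with α = 3.5 (the constant is
median(|N(0,1)|), making the estimator an SD that spikes cannot
inflate). Events are positive-going threshold crossings with a 1 ms
dead time merged to the first crossing; a negative-polarity mode
exists. On pure noise the crossing rate follows the Rice upcrossing
expectation — "silence" is not expected and the tests bound the false
rate rather than assert zero. PSTHs: 10 ms bins over 0–250 ms,
counts→rates, averaged over trials then over a layer's contacts, with
the per-trial time-averaged rate table kept for t tests. Peak/trough
trial selection uses |φ| ≤ 45° and |φ ∓ 180°| ≤ 45°; the window is an
inference from selected-trial proportions (~ a quarter of uniform
trials each) and is configurable.

## Driving-force demonstrator

A deliberate reduction of a full cortical-column simulation to one
leaky compartment: τ_m dV/dt = −(V − E_L) + λ_E·E(t) − g(t)(V − E_syn),
with τ_m = 10 ms, E_L = −70 mV, E_syn = 0 mV, λ_E = 0.2 mV/(V/m)
(free parameter; not constrained at this level of reduction), field
16 V/m at 1.5 Hz, alpha-function conductance (τ = 5 ms, dimensionless
peak 0.05). Heun integration at 0.1 ms with a τ/10 stability guard;
onsets are snapped to the integration grid (the 1.5 Hz half-period is
not a grid multiple; unsnapped alignments sample the conductance
differently and fabricate a difference at zero field). The model
demonstrates three laws — positive peak-minus-trough current difference
for a depolarizing field, exact zero without a field, antisymmetry
under coupling-sign flip — plus the RC closed form
λ_E·E₀/√(1 + (2πfτ_m)²) for the polarization amplitude. It makes no
quantitative claim about real neurons.

## Pipeline order and determinism

Phase labels are computed from the **raw** stimulation record's
narrowband, before cleaning — cleaning removes the very signal that
defines phase. The cluster comparison uses the cleaned stimulation
epochs against the no-stimulation epochs. Every stage takes its seed
from the analysis config; repeated runs produce byte-identical CSVs.

## Problem sizes

The test suite exercises reduced but fully representative problems:
40 s sessions (~67 trials) for pipeline-level tests, the full default
160 s session (~230 trials) for artifact-removal fidelity, 400-trial
amplitude-level synthetics across 50 seeds for phase recovery, 200
null runs (n_perm = 2,000) for phase-test calibration and 100 null
runs (12 contacts × 150 samples, n_perm = 1,000) for cluster
calibration. These sizes were chosen so the whole suite settles in a
few minutes while keeping every estimator at its defaults.

## Known limitations

* Layer assignment codifies a procedure that in the original workflow
  also consulted anatomical references; the priors-based fill-in is a
  package convention and is flagged in the `provenance` field.
* SOBI is fit on the whole record; a per-segment option is not
  implemented (the whole-record fit matches the stationary-artifact
  assumption the DFT subtraction relies on).
* The DFT filter removes a *stationary* sinusoid; residuals remain
  inside the ramps by construction, which is why epochs and QC exclude
  them. Amplitude-drifting artifacts would need a tracking regressor,
  which is out of scope.
* The evoked train at 2.3 Hz has genuine (small) sideband energy at
  1.5 Hz when modulation is on; the sinusoid fit absorbs it. The effect
  is far below the evoked-preservation tolerance but is strictly
  nonzero.
* No NWB/EDF readers, no iCSD/kCSD, no TFCE, no spike sorting, no GUI.
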