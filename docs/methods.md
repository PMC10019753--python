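# Methods

## Signal model of the synthetic cohorts

A recording is 20 channels (10 tagged left, 10 right, labels
`PF_L1…PF_L10`, `PF_R1…PF_R10`) at 250 Hz, concatenating up to four
states in protocol order (baseline, meditation, transmission, post;
default durations 300/600/600/300 s). Within each state and band, one
*common* narrowband process is shared by every channel and each channel
adds its own *private* process:

    x_ch(t) = κ · common(t) + (1 − κ) · private_ch(t),

summed over the four bands, plus white measurement noise of standard
deviation `noise_sd` (default 0.3; band processes are normalized to unit
variance before mixing, so noise_sd is relative to single-band signal
scale). Narrowband processes are white noise band-pass filtered to the
band edges — *not* sinusoids, whose degenerate phase statistics would
make phase-locking targets trivial. The mixing weight κ ∈ [0, 1] is
looked up per (group, state, band).

The default coupling map is additive and clipped to [0, 1]:
group base (LTM 0.45, STM 0.30, NM 0.15) + state offset (baseline 0,
meditation 0.20, transmission 0.25, post 0.05) + band offset (delta and
theta 0.05, alpha 0.10, beta 0). These constants plant the qualitative
structure the analysis is designed to detect — stronger coupling for
meditators and during meditation/transmission, slightly stronger in the
slow/alpha bands — at effect sizes large enough to be resolvable in
60 s segments. They are design constants of the generator, not estimates
of any real effect size.

Per-subject random substreams come from `SeedSequence(master_seed)`
keyed by (group index, subject index), so a subject's signal is
invariant to cohort composition and cohorts are bytewise reproducible.

The empirical map κ → PLV is *not* assumed analytic; it is measured.
At κ = 1 with zero noise all channels are identical and PLV = r = 1.
At κ = 0 the channels are independent, and the PLV of two independent
narrowband signals has a sampling floor set by the number of
*effectively independent* phase samples — approximately B·T for
bandwidth B and duration T, giving E[PLV] ≈ 0.886/√(B·T_eff) (the
Rayleigh mean; e.g. ≈ 0.15 for a 10 s alpha epoch after edge trimming).
The raw sample count L overstates the information content because
narrowband phases are autocorrelated over ~1/B seconds. In between, PLV
and |r| are monotone in κ (measured Spearman ρ ≈ 0.98 across the grid
κ ∈ {0, 0.25, 0.5, 0.75, 1} over 20 seeds).

## Preprocessing

* **Band filter**: Butterworth order 4, applied forward–backward
  (`sosfiltfilt`), so the magnitude response is squared and the phase
  response identically zero — mandatory, since any group delay would
  bias phase-locking. Ends are reflect-padded by three low-edge periods.
  Measured filtfilt attenuation one octave outside the band edges is
  ≥ 52 dB for all four bands; passband center gain is unity within well
  under 5%. Tones in the transition band (e.g. 10 Hz against the
  12 Hz beta edge) are suppressed to ~6%, not to stop-band levels —
  inherent to any finite-order design.
* **Delta low edge** is 0.3 Hz (not 0), which keeps DC and slow drift
  out of the delta band.
* **Epochs**: the full state segment is filtered first, then cut into
  non-overlapping 10 s windows (trailing partial window dropped), so no
  window carries per-epoch filter transients. 10 s gives ≥ 3 delta
  cycles per window and ≥ 30 windows per 5-minute state.
* **Line noise**: synthetic data is generated clean; a notch stage is
  deliberately absent from the default path.
* Channel selection accepts a montage map (label → left/right/drop) and
  reorders retained channels left block first; hemisphere counts must
  be equal.

## Connectivity

* Correlation is the standard product-moment coefficient; constant
  channels make it undefined and raise (`UndefinedFeatureError`) rather
  than silently contributing 0.
* PLV uses the modulus of the mean unit phasor of the per-sample Hilbert
  phase difference. The modulus is essential — without it the average
  is complex and the nominal range [0, 1] unreachable. 5% of samples
  are trimmed from each end of the phase series before averaging
  (analytic-signal boundary distortion); the trimmed L is recorded on
  the matrix.
* Full 20×20 matrices are computed (graph metrics need the whole
  graph); the 10×10 left×right block, exposed by an accessor, is the
  feature source.

## Graph metrics

* Edge weights: |r| for correlation (a strong negative association is
  still coupling, and weights must be non-negative), PLV as-is; zero
  diagonal. An optional proportional threshold keeps the strongest
  fraction q of edges (default q = 1, no thresholding — with all 19
  neighbors retained, thresholding is the main lever on clustering and
  is surfaced in config rather than silently applied).
* Clustering uses the Onnela triangle form
  (w_jk·w_jl·w_kl)^{1/3} with binary degree over nonzero edges; nodes
  with fewer than two neighbors get C_j = 0, and the graph mean is taken
  over nodes of degree ≥ 2.
* Distances: d = 1/w (d = 1 − w available behind a switch), Dijkstra
  from every source; unreachable pairs are infinite and *excluded* from
  the characteristic-path mean, with the finite-pair fraction reported
  alongside rather than imputed.
* Graph metrics are computed from the **PLV matrix by default**
  (configurable to correlation): phase-synchrony graphs are the common
  convention for band-limited EEG networks, and the choice is exposed as
  `graph_source` in `extract_features`.

## Feature tables and classification

The sample unit is the (subject, epoch) pair. State-wise tables fix a
state and spread measures over bands (16 columns); band-wise tables fix
a band and spread measures over states, pairing epochs across states by
index and truncating to the shortest state so rows are complete.
Missing cells are an error, never imputed.

Cross-validation is 10-fold and stratified, with **subject-level folds
by default**: all epochs of a subject share a fold, so a classifier
never sees a test subject during training. This is stricter than
epoch-level folding (available via `fold_unit="epoch"` for comparison),
which lets classifiers memorize subjects and inflates accuracy. With
fewer than 10 subjects the subject scheme is infeasible and the code
falls back to epoch folds with an explicit leakage warning.
Standardization is fit on training folds only. Fixed hyperparameters:
DT depth ≤ 5; LDA and LR in textbook binary form; SVM with RBF kernel,
C = 1, scale gamma; KNN with k = 5; ensemble = 100 bagged depth-≤5
trees. The state-wise grid covers baseline/meditation/transmission
(post is recorded and can be added via config); the band-wise grid
covers all four bands.

## Group statistics

Per (measure, band, state) cell, epoch values are first averaged within
subject — the subject is the independent unit; epoch-level testing would
pseudo-replicate — then group pairs are compared with Welch's t-test
(the design's own choice of test), starred at p < 0.05/0.01/0.001. No
multiple-testing correction by default (each cell reported on its own);
Benjamini–Hochberg and a one-way ANOVA variant are available as options.
Measured type-I error under the null is ≈ 4–5% at α = 0.05 over 1000
simulations.

## Calibration experiments and problem sizes

The standing experiments (`meditfc.experiments`, reused by the test
suite and `scripts/acceptance.py`) run at desk scale: 60 s per state
(six 10 s epochs), single subjects for the κ-grid and direction checks,
10 + 10-subject two-group cohorts for classifier calibration, and the
full 13/11/10 design for the demonstration grid. Chance bands for null
classifier accuracy use the subject × seed count as the effective
number of independent Bernoulli units, since epochs within a subject
are dependent.

## What the synthetic results do and do not show

Passing calibration demonstrates that the pipeline *recovers planted
coupling structure*: monotone κ → PLV, correct directional state
effects, chance-level accuracy when no group effect exists, and
near-perfect accuracy when groups are well separated. It does **not**
validate any claim about real meditators. In particular the generator
omits: between-subject variability in coupling (every subject of a
group shares one κ, which is why default-map cohorts classify at ~100%
accuracy — real cohorts with overlapping subject distributions would
not), artifacts (ocular, muscular), volume conduction (which inflates
zero-lag measures in real EEG), 1/f background spectra, and full-scalp
geometry. Accuracies measured here are therefore upper bounds of a
clean, well-specified world, and only the *qualitative* patterns
(directions of effects, relative difficulty of contrasts) transfer.

## Degenerate inputs and numerical conventions

Constant channels, all-zero signals and sub-16-sample epochs raise
errors rather than return sentinel values. Connectivity matrices are
symmetrized (averaged with their transpose) and clipped to their
nominal ranges to absorb float round-off, with the diagonal set
exactly to 1. Graph weights must lie in [0, 1] with zero diagonal;
negative weights raise. Ties in the proportional threshold are broken
by sort order after descending weight sort. Recordings serialize to
channels×samples CSV (`%.6e`, round-trip accurate to ~1e-6 relative)
with a versioned JSON sidecar; EDF reading is supported through MNE
when installed, with the hemisphere assignment supplied by a montage
CSV.
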