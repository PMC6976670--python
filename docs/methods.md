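# Methods

This note documents the generative model, the analysis conventions and
the numerical choices behind `statebold`, in enough detail to reproduce
or modify any stage.

## Temporal design

A session is `n_runs` sparse-sampling EPI runs (default 5 runs of 313
volumes; TR 2.25 s of which the final 0.75 s is a silent acquisition
gap). Stimulation events are triple pulses at 15 Hz (train length
133 ms), which fits inside one gap, so the −500 … −5 ms pre-event EEG
window is free of gradient artifacts by construction.

The scheduler draws one merged stream of event slots per run with
inter-slot intervals uniform on [11.25, 15.75] s (mean 13.5 s), snaps
each onset to the nearest gap center, and assigns `tms` / `null` labels
by a balanced random shuffle per run. Null events therefore follow the
same temporal law as TMS events and are count-matched per run by
construction. At the defaults this yields ~125–135 TMS events per
session. Events are modelled at the gap center; the few-hundred-ms
offset between gap onset and pulse delivery in a real rig is far below
the hemodynamic sampling scale and is deliberately not modelled.

## EEG generative model

Each band-limited oscillation is a sinusoid multiplied by a log-Gaussian
Ornstein–Uhlenbeck envelope: the log-amplitude relaxes toward its mean
with time constant τ = 2 s and stationary SD 0.5, giving a smooth,
strictly positive, lognormal envelope — the canonical description of
resting alpha power fluctuations (slow, right-skewed, multiplicative).
The parietal channel carries the alpha oscillation (median amplitude
20 µV), the frontal channel an independent beta oscillation (10 µV), and
every channel adds 1/f noise (5 µV RMS). The *true* pre-event power
(mean envelope²/2 over the −500 … −5 ms window) is recorded per event as
ground truth.

Not emulated: MRI gradient and ballistocardiogram artifacts (the
analysis windows are artifact-free by design), volume conduction,
alpha–beta coupling, and oscillatory phase. Passing tests therefore
demonstrate correct recovery of *power-coded* state dependence under
realistic envelope dynamics, not robustness to artifact residue.

## BOLD generative model

Single-trial amplitude in region r: `β_i = β₀ + γ_r·z_i + ε_i` with
`z_i` the standardized true pre-event alpha power over TMS events,
`γ_r = γ` (default −0.5) in gated regions and 0 elsewhere, and
`ε_i ~ N(0, σ_ε)` drawn independently per region (default σ_ε = 1), so
regions act as near-independent replicates. Null events evoke nothing.
The implied trial-level correlation is γ/√(γ²+σ_ε²) ≈ −0.45 at the
defaults — a deliberately realistic single-trial effect size rather
than a toy one.

Amplitude-weighted sticks are convolved with the HRF on a 0.05 s grid
(0.05 divides the TR, so scan samples land exactly on grid points) and
sampled at volume onsets. Scanner noise is AR(2) per voxel/region
(coefficients 0.4, 0.1 — matching the analysis model's order), plus a
random linear + half-cycle sinusoidal drift per run and a random linear
coupling of six simulated motion confounds (smoothed random walks).
Region-level simulation scales noise by 1/√(cluster size) to match the
average of independent voxel noise; voxel-level simulation (20×20×12
grid with face-connected clusters) is available when ROI definition
itself is under test.

For large-replicate statistical calibration the package also draws
trial tables directly from the amplitude model (`simulate_trial_table`),
with lognormal per-trial power — the stationary law of the envelope
process. This skips the waveform stages, which contribute estimation
noise but no additional statistical structure; the waveform path is
separately verified by noiseless exact recovery and by a full-pipeline
detection-rate check across 100 gated regions.

## HRF

Canonical double-gamma: response gamma with mode at 5 s, undershoot
gamma with mode at 15 s, peak:undershoot ratio 6, dispersion 1 s, length
30 s, unit peak (normalized on an internal 1 ms grid so the curve is
independent of the caller's sampling). All parameters are configurable
(`HRFParams`); the defaults are the standard values used when no
vendor-specific parameterization is documented.

## EEG analysis conventions

* Downsampling 5000 → 500 Hz by polyphase anti-aliased decimation,
  then average-reference over the configured electrode set (default: the
  22-electrode fronto-central/parietal montage), then a zero-phase
  Butterworth band-pass 0.5–40 Hz. The 24 dB/oct slope maps to order 4,
  applied forward–backward (`sosfiltfilt`); the 50 Hz notch
  (Q = 30) is applied after downsampling — at a 250 Hz Nyquist the
  notch is well-conditioned, and ordering relative to decimation is
  immaterial for the analysis band.
* Epochs are closed-start/open-end in seconds: [−0.500, −0.005) at
  500 Hz gives exactly 248 samples. Baseline (mean over [−0.450,
  −0.050)) is subtracted before linear detrending.
* Artifact rules per channel and epoch: adjacent-sample gradient
  > 20 µV/ms, range > 200 µV within any 50 ms interval, or |amplitude|
  > 80 µV; flags carry reason codes and rejection is monotone in every
  threshold. Trials rejected on an analysis channel are excluded from
  both the EEG and fMRI sides of all later analyses (the pairing
  requires joint retention).
* Power: per frequency f on the 8–18 Hz grid (2 Hz steps), a Hanning
  taper of length 3/f slides across the detrended epoch at one-sample
  steps (maximal overlap); power at f is the squared magnitude of the
  tapered Fourier coefficient averaged over window positions, calibrated
  so a unit sinusoid at f yields its variance (0.5). The hop size is
  configurable; maximal overlap is the default because the window count
  per epoch is small.
* Peak frequency: argmax of the across-trial mean spectrum within the
  band; ties resolve to the lowest grid frequency.

## fMRI analysis conventions

* Temporal preprocessing per run: regression against a constant, a
  linear ramp and sine/cosine pairs at whole frequencies below 2
  cycles/run, then z-normalization. A trigonometric-pair basis (rather
  than cosine-only) is used so that slow components of arbitrary phase —
  including odd-symmetric ones — are fully removed; a 1 cycle/run
  sinusoid is annihilated, a 10 cycles/run one passes within 5%.
  Betas are consequently in per-run SD units. Constant series are
  flagged, zeroed and reported, not fatal.
* Single-trial design: one stick column per TMS event; null-event
  amplitudes come from a separate single-trial model with all TMS events
  aggregated into one column (mirroring how an aggregate-TMS model
  isolates null-event responses). Six motion confounds and one constant
  per run complete every design. The 133 ms pulse train is one stick.
  Regressors are sampled at volume onset; the acquisition gap only
  positions events.
* AR(2) correction is two-pass (Cochrane–Orcutt-style): OLS residuals →
  Yule–Walker coefficients (shrunk toward zero in the rare non-stationary
  case) → per-run prewhitening of data and design, dropping the first
  two scans of each run → OLS on the whitened system. On small instances
  this matches full GLS up to the discarded edge rows.
* Contrast maps: t per voxel; conjunctions take the minimum t and
  maximum p across contrasts (one-sided activation p). ROIs are
  face-connected (6-neighbour) clusters of voxels surviving
  Benjamini–Hochberg FDR at q = 0.05 with ≥ 10 voxels. An empty result
  warns rather than raising.

## Statistics

* Permutation engine: the amplitude vector is permuted against fixed
  power values (default 20 000 draws; tests and calibration use 500).
  When n! ≤ n_perm all permutations are enumerated. p-values use the
  add-one convention `(1 + #extreme)/(n_perm + 1)`, with "as or more
  extreme" including equality, so p = 0 is impossible. Alpha-band tests
  are one-tailed toward negative associations (the inhibition
  hypothesis is directional); all other tests are two-tailed.
* Category analysis: stable sort by power (ties broken by trial order);
  weak/strong bins of `bin_size` = 40 trials. Cohen's d for dependent
  samples pairs the i-th lowest-power trial of the weak bin with the
  i-th lowest-power trial of the strong bin (rank pairing — a
  documented convention, since category membership induces no natural
  pairing) and divides the mean difference by the SD of the
  differences; d = 0 by convention when the differences are constant.
  Because only power *ranks* enter the binning, category p-values are
  invariant to monotone rescaling of power.
* The per-region significance decision is the permutation p at 0.05; an
  optional BH-FDR correction across cells is available but off by
  default, matching per-region reporting. A signed-rank statistic is
  sometimes quoted alongside permutation nulls in this literature; the
  permutation p is the primary inference here and the signed-rank test
  is reserved for the MEP count comparison, where the pairing (per run)
  is well defined.
* Drift check: Pearson ρ of null-event alpha power against trial order,
  p from the exact t transform on n−2 df, two-sided.

## EMG / MEP stage

Epochs span 0–260 ms after the first pulse (configurable within
160–260 ms). The ±5 SD criterion is read as two-sided about the 0–10 ms
baseline mean (baseline mean subtracted before thresholding, so the
decision is scale-invariant). Detection requires the first crossing
inside 5–40 ms and the absolute extremum inside 15–50 ms. A zero
baseline SD flags the trial. TMS and null counts are compared per run
with the exact two-sided Wilcoxon signed-rank test (n ≤ 25), zero
differences dropped; all-zero differences give p = 1.

## Problem sizes and verification scope

The package's verification runs at desk scale, chosen so the full suite
and the acceptance script each complete in well under a minute of
compute: trial-level calibration uses 1000 replicates × 500
permutations at n = 135 trials; recovery and specificity use 100
replicates; the waveform-level check uses one 5-run session at a 1 kHz
EEG rate with 100 independently-noised gated regions. Study-scale
defaults (5 kHz EEG, 20 000 permutations) remain the configuration
defaults throughout and are exercised structurally by the same code
paths.

## Known limitations

* The generator encodes a *linear* power–amplitude coupling; saturating
  or threshold-like gating would attenuate the recovered γ.
* No oscillatory phase effects, no gradient/BCG artifact model, no
  spatial preprocessing of real volumes (slice-timing, motion
  correction, normalization are out of scope; inputs are assumed
  spatially preprocessed or ROI-level).
* Single-subject inference only; no group model.
* AR noise is stationary within run; physiological noise
  (respiration/cardiac aliasing) is subsumed into the AR + drift model.
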