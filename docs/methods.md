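# Methods

## Overview

`fatiguekit` implements a short-calibration, inter-subject mental-fatigue
assessment procedure.  One five-minute session per subject — 30 s eyes closed
(EC), 30 s eyes open (EO), and a 4-minute auditory oddball (AO) task with 120
stimuli (96 frequent, 24 non-frequent, 80:20, presented for 1 s with a 1 s
inter-stimulus interval) — yields a 226-dimensional feature vector:

| group | count | definition |
|---|---|---|
| P300 | 16 | peak amplitude and onset-to-peak latency of the averaged non-frequent response per channel |
| normalized band power | 40 | mean of `NP(t) = (AO(t) − mean_EO) / mean_EO` per band and channel |
| band-power ratios | 160 | mean of all 20 ordered band-pair ratios per channel, pre-normalization |
| wristband | 10 | EO-normalized VLF/LF/HF/TP of the BVP signal, LF/HF, LFNU, and raw AO means of IBI, HR, EDA, ST |

Fatigue ground truth is the 10-item Fatigue Assessment Scale (FAS) total
(10–50), binned into three classes: no fatigue (≤ 21), substantial (22–35),
extreme (≥ 36).  Features are ranked by the two-tailed p-value of their
Pearson correlation with the FAS totals (exact t test on m − 2 degrees of
freedom), and multiple linear regression models on the k best features are
fitted by the normal equation (`w = pinv(XᵀX) Xᵀ y`, Moore–Penrose on
rank-deficient designs) and evaluated over a grid of subject-level splits
(70:30, 80:20, leave-one-out), feature counts (k = 1 … 15) and AO durations
(240, 120, 60, 30, 15 s), with 10 random repeats per cell.  Reported metrics
are the mean percentage of test subjects assigned the correct fatigue class
and the mean RMSE of the predicted totals.

## Signal processing

* **Filter chain.** 60 Hz IIR notch (Q = 30) followed by a 0.1–100 Hz
  4th-order Butterworth bandpass, both applied forward–backward
  (`filtfilt`), so the passband is phase-neutral and the effective
  attenuation corresponds to order 8.  "4th order" names the designed order
  before forward–backward application.
* **ASR.** Artifact subspace reconstruction with κ = 15: the EC segment
  supplies a calibration covariance (Euclidean average; no Riemannian
  averaging or automatic clean-window search — the calibration segment is
  given explicitly).  Each 500 ms window (50 % overlap, tapered overlap-add)
  is diagonalized by its own principal components; a component whose window
  variance exceeds (κ × calibration standard deviation in that direction)²
  is projected out.  Diagonalizing the *window* covariance matters: a
  broadband transient splits across an (often degenerate) calibration
  eigenbasis and would otherwise evade the threshold.  Clean windows pass
  through unchanged to ≲ 1e−15, and the operation is idempotent.
* **ERP.** Epochs span −200 … +800 ms around non-frequent onsets
  (250 samples, onset at index 50).  The 0.1–10 Hz zero-phase bandpass is
  applied to the continuous record *before* epoching: a 0.1 Hz highpass is
  numerically ill-conditioned on 1-s windows (its time constant exceeds the
  window) and costs a systematic ≈ 6 % peak loss when applied per epoch; for
  a zero-phase LTI filter the two orderings differ only in edge handling.
  The baseline is the channel's mean EO amplitude (default), with the
  conventional pre-stimulus mean available via `baseline="prestim"`.  The
  P300 is the windowed maximum in 200–500 ms (ties to the earliest sample;
  non-positive maxima are returned with a warning).  When an AO truncation
  leaves no non-frequent stimulus inside the window, the full AO stimuli are
  used for the ERP features (logged).
* **Spectra.** Band powers are *integrated* periodogram powers: 1-s
  non-overlapping rectangular windows aligned to the segment start, one-sided
  PSD summed over bins inside the band × bin width (1 Hz bins at 250 Hz).
  Band edges are inclusive on both sides exactly as defined (δ 1–4, θ 4–7,
  α 8–12, β 13–29, γ 30–50 Hz), so the 4 Hz bin contributes to both δ and θ.
  Ratios are averaged per window (mean of per-window ratios), not ratios of
  averaged powers.
* **Wristband.** BVP is analyzed directly (no beat detection): 30-s windows
  advanced 1 s, per-window mean removal, DC bin excluded from every band.
  At 30-s windows the resolution is 1/30 Hz, so no bin falls inside the
  printed VLF range (0–0.03 Hz) and the VLF power is identically zero; it is
  kept for structural fidelity, its EO-normalization is defined as 0, and
  LFNU = LF/(TP − VLF) then reduces to LF/TP.  For AO durations below 30 s
  a single window spanning the truncated interval is used (logged).

## Modeling and evaluation

* **Split sizes** at m = 14: 70:30 → 10 train / 4 test; 80:20 → 11 / 3;
  LOO → 13 / 1 with the held-out subject sampled without replacement across
  the 10 repeats (with replacement once all subjects have been used).
* **Selection modes.** The default (`per_fold`) recomputes the correlation
  ranking on the training subjects of every repeat, so no test information
  leaks into selection.  `paper_faithful` ranks once on all subjects before
  splitting — the original protocol — and is the right null model when
  studying the procedure's permutation behavior.  At m = 14 the per-fold
  mode selects more extreme spurious correlates under label permutation
  (near-collinear reciprocal-ratio companions then produce wild
  out-of-sample predictions), so its permutation-null accuracy sits well
  below the majority-class rate, while the paper-faithful null lands near it.
* **Redundancy pruning (NR-EEG).** Reciprocal ratio pairs on the same
  channel (α/θ vs θ/α) carry the same information; the non-redundant variant
  keeps the lower-p member of each pair.
* **E4 variant.** The wristband-only model uses the fixed six-feature set
  {st, lf, tp, hf, lfnu, lf_hf} ranked by p without the significance filter
  (no wristband feature needs to clear α for the variant to be evaluable).
* **Class mapping of predictions.** Real-valued predictions are binned at
  the midpoints 21.5 and 35.5 (the integer class bins extended to the reals).
* **Tie-breaking.** The p-value sort breaks ties by |r| descending, then
  feature name, so every k-prefix model is reproducible.
* **Degenerate features.** Numerically constant columns are assigned
  r = 0, p = 1 (excluded) — their "correlation" is rounding noise.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable
without recordings: 17-subject-style cohorts (default n = 14, the number of
complete subjects), FAS totals drawn per class from the reported
compositions (no fatigue 19 ± 2, substantial 27 ± 3, extreme 37 ± 3; weights
3 : 8 : 6), and per-subject physiology:

* **EEG background** is a *block-randomized random-phase multisine*: each
  band is a sum of equal-amplitude tones on the integer-Hz FFT-bin grid
  inside the band, with phases redrawn independently every 1-s block.
  Because analysis windows are aligned to the same grid, every window's band
  power equals the planted value exactly, which makes amplitude inversion
  from target power ratios analytic and noise-free; because phases change
  between blocks, stimulus-locked averaging still suppresses the background
  as 1/√n_epochs.  Each integer frequency belongs to exactly one band (the
  shared 4 Hz edge bin goes to θ) so no two tones interfere on one bin.
  A classical bandpass-filtered white-noise background is available via
  `SubjectProfile(background="filtered_noise")`; its Butterworth skirts leak
  across neighbouring bands and make window powers stochastic, which is more
  realistic but makes planted effects only approximately recoverable.
* **P300** is a positive Gaussian deflection (σ = 40 ms; only peak time and
  height matter to the detector) added on every channel after each
  non-frequent onset, with per-subject latency on the 4-ms sample grid.
* **Task-engagement gains.** Every (band, channel) receives a per-subject
  amplitude gain U(0.9, 1.15) on the AO segment so normalized-power features
  carry genuine inter-subject variance; bands tied together by a planted
  ratio share one gain per channel, which cancels in the ratio.
* **Wristband.** BVP is two sinusoids at the profile's LF/HF frequencies
  plus white noise; EDA/ST are levels with small drift and noise; HR is a
  noisy constant and IBI is 60/HR plus jitter, all at the device rates
  (64 / 4 / 4 / 1 / 1 Hz).
* **Planted fatigue effects.** `generate_cohort` inverts the feature
  definitions: target power ratios become band-amplitude ratios
  (power ∝ amplitude²), normalized-power targets become AO gains
  √(1 + target).  The FAS total is then set to
  `b0 + Σ slope_j · feature_j + N(0, noise_sd)` where `feature_j` is the
  value the default extraction pipeline actually measures on the synthesized
  recording at the full AO duration — the features come from the signal
  physics and the questionnaire total is the generator's free variable, so
  with `noise_sd = 0` the planted linear law holds exactly downstream.
  Default targets mirror the strongest fatigue correlates of this kind of
  data (β/θ at C3, α/θ at O2 and C3) with slope −10 FAS units per ratio unit
  and noise_sd = 2 FAS units.  Synthetic FAS totals are therefore
  real-valued; questionnaire scoring of item responses still yields integers.

**What the generator does not emulate:** volume conduction and channel
covariance, 1/f spectral shape, eye-blink/EMG artifact morphology (the ASR
tests plant simple large transients instead), non-stationarity across the
session, beat-to-beat BVP morphology, and any nonlinear feature–fatigue
relation.  Passing tests therefore demonstrate correctness of the
*procedure* (filters, detectors, formulas, selection, CV mechanics,
parameter recovery), not real-data effect sizes; the headline accuracies of
any particular study can only be checked against its own recordings.

## Problem sizes and numerical tolerances

Tests and the acceptance script run at the study's protocol scale: 5-min
sessions at native rates, 14-subject cohorts, 10 CV repeats (50 for the
permutation null), 20 subjects for P300 recovery, and 1000 simulated
cohorts for selection calibration.  Formula implementations agree with
independent references (scipy's `pearsonr`, QR-based least squares, directly
coded expressions) to ≤ 1e−8; planted-cohort recovery reaches 100 %
classification accuracy with RMSE < 1e−6 at k = 3; ASR pass-through is exact
to ≲ 1e−15 and planted 500 µV transients are attenuated by ≥ 80 %.  P300
recovery at the boundary noise condition (per-band background RMS equal to
amplitude/5) is asserted per subject — median across the 8 channels within
one sample (4 ms) in latency and 10 % in amplitude — because individual
channel detections from only 24 averaged epochs retain a residual-background
error whose tail exceeds one sample in roughly a tenth of detections.

## Known limitations

* The ASR here is the κ-threshold core of the published algorithm, not the
  full adaptive implementation (no Riemannian covariance averaging, no
  automatic calibration-data selection, no sliding threshold statistics).
* Regularization (e.g. LASSO) and nonlinear models are out of scope, as is
  multiple-testing correction of the selection step (none is applied, by
  design of the original procedure).
* At m = 14 the permutation-null accuracy distribution is wide; single-run
  null estimates should be read with the reported standard errors.
* EDF/BDF/XDF ingestion and live streaming are not supported; bundles are
  plain-CSV directories.
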