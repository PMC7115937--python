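# Methods

## The detection model

The detector treats an arousal as a sustained (≥ 3 s) excursion of 1 s
band power above what the recording itself declares normal. There is no
training and no absolute power threshold anywhere in the EEG path: every
decision compares a statistic of the current epoch against a median or
maximum of the same statistic elsewhere in the same recording. Two
consequences follow and are enforced by tests: detections are invariant
under global amplitude rescaling of the recording, and the detector is
deterministic — identical input and configuration give identical output.

The assumptions this rests on:

- the background spectrum is locally stationary at the 30 s scale, so
  twice the local median band power is an abnormality criterion;
- the whole-night median band power is a meaningful "fixed" floor, i.e.
  the night is not mostly artefact;
- muscle tone in the first 4 min of the recording is artefact-free and
  representative, so its maximum per-epoch amplitude is a global EMG
  baseline;
- spindle activity is separable from arousal activity by *relative* sigma
  power, σ/(α+σ+β), compared against the night's own maximum.

## Parameters

All defaults live in `RunConfig` and serialise to YAML; unknown keys are
rejected. The printed constants of the published rule set are the
defaults; changing any of them is an explicit configuration act.

| parameter | default | meaning |
|---|---|---|
| filter order / edges | 3; EEG 0.5–30, EOG 0.1–5, EMG 10–100 Hz | per-modality Butterworth band-pass |
| `sd_low_uv`, `sd_high_uv` | 1, 6·10³ µV | whole-night flat / saturated EEG screen |
| `window_sd_ratio` | 5 | per-window deviation ratio (two-sided by default) |
| `emg_flat_median_uv` | 0.1 µV | per-window flat-EMG screen (median of absolute value) |
| `emg_noisy_ratio`, quota | 2, > 15 of 30 | transitory-noise confirmation on 1 s epochs |
| `emg_baseline_s` | 240 s | global EMG tone baseline span |
| `emg_local_factor`, `emg_valid_factor` | 2.0, 2.0 | EMG cascade steps 2 and 3 |
| `adaptive_factor` | 2.0 | EEG shift: power > 2× local clean median |
| `sigma_quantile` | 0.85 | spindle epoch: relative σ > 85 % of night max |
| `min_duration_s` | 3 s | minimum arousal duration |
| `conversion_threshold_s` | 0.5 s | epoch counts as arousal if coverage strictly exceeds this |
| `event_overlap_s` | 1 s | events are common if they share at least this |

## Numerical and design choices

**Zero-phase filtering.** Filters are applied forward–backward so event
onsets carry no group delay; the effective roll-off is twice the order-3
slope. Because all detection thresholds are data-derived ratios this
changes nothing structurally. Causal mode is available
(`filters.zero_phase: false`). The EMG low-pass edge (100 Hz) exceeds
Nyquist for 128 Hz data and is clipped to 0.9·fs/2 with a warning.

**Band power estimator.** Rectangular-window periodogram per 1 s epoch.
With an integer sampling rate the bins fall on integer frequencies, so
half-open band integration [lo, hi) is exact for on-bin sinusoids (a sine
of amplitude A contributes A²/2 to its band) and the flat-spectrum
expectation is proportional to band width — both are frozen oracle tests.
The printed α (7–13) and σ (11–16) bands overlap; the overlap is kept
exactly as printed, each band integrating its own half-open interval.

**Channel fusion.** Band power is aggregated across the EEG channels that
are good in the surrounding window by the median (robust to one residual
bad channel); a `max` mode flags a shift seen on any channel.

**Per-window deviation ratio.** The > 5 rule is applied two-sided
(> 5 or < 1/5) so channels that die inside one window are caught; the
reference is the median SD of the other good channels. One-sided mode is
available.

**EMG composite.** The "median value < 0.1 µV" flat test is read as the
median of the absolute signal: a mean-corrected channel has a plain median
near zero at any amplitude, so the literal reading is degenerate. The same
reading applies to the "at least twice the other" noisy test. Windows in
which both channels are excluded are masked as EMG-unavailable, never
zero-filled; downstream, EMG shifts are false there and REM arousals
cannot be confirmed.

**EMG cascade step 2.** The "3 s scoring window" median filter is a
centred 3-epoch running median on the per-epoch mean absolute amplitude.
Step 3 confirms a candidate when its amplitude exceeds `emg_valid_factor`
times the median of the 10 nearest candidate-free epochs on each side
(clipped at the recording edges). Neither comparison factor is printed in
the rule set; both default to the 2× used everywhere else in it and are
configurable.

**Adaptive EEG threshold with no clean epochs.** If a window's selection
set (its EMG-shift-free epochs plus ten on each side) is empty, the
adaptive threshold falls back to twice the whole-night median and the
event is logged.

**Spindle exclusion and run splitting.** The trigger mask is
(θ ∨ α ∨ β) ∧ ¬spindle, and runs are recomputed on the post-exclusion
mask; a spindle epoch inside an otherwise continuous run therefore *can*
split it, and each fragment must reach 3 s on its own. This is the literal
reading of "excluding those concomitant with a sigma shift".

**EMG association.** An event is EMG-associated when an EMG shift
overlaps it or lies within 1 s of its boundaries (scoring practice accepts
muscle activity accompanying the EEG change); strict-overlap mode is
available. The REM rule uses the same definition. No 10 s inter-arousal
merge is applied by default — that gap is part of the *human* scoring
definition, not of the per-epoch rule set; a merge-gap option exists.

**Band hand-over.** A run may be sustained by different bands in
different epochs (θ→α counts as one event); requiring a single band to
carry the whole run is a config switch, under which mixed runs are
dropped unless some single band spans ≥ 3 s.

**Cohen's κ variants.** The published chance term,
Pr = (TP+TN)(TP+FP)/n², is not the standard Cohen expected agreement.
Both are implemented; the default is the standard marginal-product form
(the coefficient is cited as Cohen's), every report names the variant
used, and the worked-example tests pin both formulas.

**Event matching.** One-to-one and greedy in onset order: each gold event
consumes the earliest-onset unmatched test event sharing ≥ 1 s. A gold
event overlapped by two test events yields one TPe and one FPe.
Many-to-one mode is available. `C` is gold-delimited: the fraction of the
matched gold event's seconds covered by the test *track*.

**Undefined ratios** (no gold events, no test events, no matches) are
reported as `None` with a reason string, never as silent NaN.

**Morlet profiles.** Events are characterised on their first 3 s with
7-cycle Morlet wavelets on 1 Hz bins centred at 1…29 Hz (covering
0.5–29.5 Hz), computed on a zero-padded context window so wavelet edge
effects stay out of the analysed span, channel-aggregated by the median.
Per bin, the mean power over the event's first 500 ms is subtracted
(`pre-event` baseline mode is available), the 3 s sum is rectified at
zero — power below baseline carries no activation, and rectification
keeps relative powers and band sums inside [0, 1] — and the profile is
normalised to sum to 1. Band sums use θ 4.5–7.5, α 8.5–11.5,
β 16.5–29.5 Hz; no bin belongs to two bands.

## The synthetic generator

`synth_psg` emulates exactly the statistical structure the detector
conditions on, with a complete ground-truth ledger:

- stage-labelled background EEG as 1/f-like coloured Gaussian noise
  (exponent 1 by default) whose RMS follows the hypnogram
  (W/N1/REM 20 µV, N2 25 µV, N3 35 µV) with linear ramps between windows
  so stage changes do not create broadband steps;
- a stationary broadband EMG pair (5 µV RMS per channel);
- events as band-limited bursts. Each burst is synthesized in the
  physiological *rhythm* range of its band (θ 4–7, α 8–11, σ 13–15,
  β 18–28 Hz) — narrower than the analysis bands, because real rhythms
  are; in particular a spindle occupies ~13–15 Hz rather than the whole
  printed 11–16 Hz σ band, which overlaps the α analysis band. Burst
  intensity is a *power gain* relative to the local background in the
  analysis band, delivered in every second of the event (an arousal is a
  sustained acceleration; raw narrowband noise has Rayleigh envelope
  fades that would make single seconds of a nominally "4×" event
  arbitrarily weak). A pure-sine mode exists for analytic unit tests;
- optional EMG bursts accompanying events, and injected channel faults
  (flat or 20× intervals);
- a simulated human rater (`make_rater`) that drops and jitters ledger
  events with stated probabilities.

Everything is driven by one integer seed; equal seeds give bit-identical
output.

What the generator does **not** emulate: K-complexes, slow oscillations,
sawtooth waves, the cyclic alternating pattern, ocular and cardiac
artefacts, topographic structure across electrodes (channels are
independent noise plus a common burst), or the 10 s stable-sleep context
of the human scoring definition. Passing tests therefore show that the
implementation realises the stated rule set and is well calibrated on
spectrally realistic backgrounds — not that its agreement with human
scorers on real PSG matches any particular figure.

## Problem sizes

The validation runs use an 8 h night at 128 Hz with 3 EEG + 2 EMG
channels and 40 injected events (the agreement framework is additionally
checked exhaustively on all 16.8 M ordered pairs of 12-epoch tracks
against a brute-force enumeration oracle, and on 1,000 random 500-epoch
pairs). Event durations are drawn uniformly from 3–10 s, the short end of
scored arousal durations; gains default to 4× local band power. These
sizes exercise every rule — REM confirmation, spindle exclusion, EMG
association, partial windows — while a full run of the test-suite stays
in the minutes range.

## Known limitations

- EDF support is a minimal 16-bit profile (shared integer sampling rate,
  1 s records, no annotation track); BrainVision/FIF are out of scope.
- The package does not resample; it trusts the rate the file declares.
- Cohort-level statistics on agreement coefficients (mixed models,
  correlations across recordings) are out of scope; the package exposes
  the per-recording coefficients such models consume.
- Sleep re-staging after an arousal and respiratory-event linkage are not
  modelled.
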