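# arousalkit

Fully automatic, self-calibrating detection of micro-arousals in
whole-night sleep EEG, together with the scorer-agreement framework used
to validate such detectors and a ground-truth-labelled synthetic
polysomnography (PSG) generator.

Arousals are transient (≥ 3 s) accelerations of the sleep EEG toward
theta/alpha/beta frequencies — excluding sleep spindles — that index sleep
fragmentation. They are usually scored by eye, which is slow and varies
between raters and centres. `arousalkit` implements an algorithmic
translation of the scoring rules in which **every threshold is derived
from the recording itself** (medians and maxima of band power and EMG
tone), so the detector needs no training phase and is invariant to global
amplitude scaling of the input.

## Who this is for

Sleep researchers who want a reproducible arousal count/event list from
standard PSG (EEG referenced to linked mastoids, a bipolar submental EMG
pair, optional EOG, a 30 s hypnogram), and methodologists who want the
event-level agreement machinery (sensitivity, overlap, FDR, Bennett's S,
Cohen's κ) for comparing scorers.

## The algorithm

Per 30 s scoring window and 1 s epoch:

1. **Preprocess** — order-3 Butterworth band-pass per modality
   (EEG 0.5–30 Hz, EOG 0.1–5 Hz, EMG 10–100 Hz, clipped below Nyquist),
   mean correction, 30 s / 1 s grid.
2. **Channel quality** — EEG channels with whole-night SD < 1 µV or
   > 6·10³ µV are discarded; per window, a channel whose SD deviates from
   the other good channels' by more than 5× is masked. The EMG pair is
   merged into one composite trace after per-window flat (< 0.1 µV median
   amplitude) and noisy (≥ 2× the other channel, confirmed on > 15 of 30
   epochs) exclusion.
3. **Shift features** — per 1 s epoch: EMG tone shifts via a three-step
   cascade (global 240 s-baseline screen, local 3 s running-median screen,
   validation against the 10 clean neighbour epochs each side); EEG power
   shifts in θ (3–7), α (7–13), β (16–30 Hz) requiring both the
   whole-night median (fixed threshold) and twice the local EMG-shift-free
   median (adaptive threshold); spindle epochs via relative sigma power
   (11–16 Hz) above 85 % of the night's maximum.
4. **Event assembly** — runs of ≥ 3 consecutive shifted epochs, spindle
   epochs excluded, become arousals; events are labelled EMG-associated
   when muscle tone shifts accompany them; in REM only EMG-associated
   events survive; wake events are dropped.

Two detections A (test) and B (gold standard) are compared after
converting events to 1 s tracks (an epoch counts if > 0.5 s is covered):

- epoch level: `S = 2·P0 − 1` and Cohen's `κ = (P0 − Pe)/(1 − Pe)`
  (a "paper-literal" κ chance-term variant is also provided),
- event level (≥ 1 s overlap defines a common event):
  `Se = TPe/(TPe+FNe)`, `FDR = FPe/(TPe+FPe)`, and `C`, the mean fraction
  of a matched gold event's seconds covered by the test detection.

Two raters can be fused into an *inclusive* (union) or *conservative*
(both raters) gold standard.

## Worked example

```bash
arousalkit demo --duration 3600 --n-events 12 --seed 4
```

synthesizes a one-hour night (3 EEG + 2 EOG + 2 EMG channels at 128 Hz,
1/f background following a cyclic hypnogram), injects 12 band-limited
bursts at 4× local band power (half with EMG tone bursts), runs the
detector, and scores it against the ground-truth ledger:

```json
{
  "S": 0.9994444444444444,
  "kappa": 0.9936467598475213,
  "kappa_variant": "standard",
  "kappa_interpretation": "Almost perfect",
  "Se": 1.0,
  "C": 1.0,
  "FDR": 0.0,
  "counts": {
    "TPs": 80, "FPs": 1, "TNs": 3519, "FNs": 0,
    "TPe": 12, "FPe": 0, "FNe": 0, "n": 3600
  },
  "n_injected": 12,
  "n_detected": 12
}
```

All 12 injected events are recovered (`Se = 1.0`, `FDR = 0.0`); the one
spurious positive epoch (`FPs = 1`) is a detected event extending one
second past its injected counterpart. The same pipeline is available
stepwise — `arousalkit synth`, `arousalkit detect`, `arousalkit agree`,
`arousalkit profile` — and as a library:

```python
import arousalkit as ak

rec = ak.read_recording("night.edf", role_map={"Fz": "EEG", ...})
hyp = ak.read_hypnogram("night.hyp")
events = ak.detect(rec, hyp)          # EventList of ArousalEvent
report = ak.compare(ak.to_track(events, n), ak.to_track(human, n))
```

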