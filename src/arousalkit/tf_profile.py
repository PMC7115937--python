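"""Morlet time-frequency characterisation of detected arousals.

Each event's first 3 s are decomposed with Morlet wavelets on 1 Hz bins
(centres 1..29 Hz, covering 0.5-29.5 Hz). Per bin, power is baseline
corrected (subtracting the bin's mean over the first 500 ms of the event,
or over the 500 ms preceding it in ``pre-event`` mode), summed over the
3 s, and normalised across bins so the profile sums to 1. Band sums are
reported for theta 4.5-7.5 Hz, alpha 8.5-11.5 Hz and beta 16.5-29.5 Hz;
no bin belongs to two bands.

The signal enters the transform with generous context around the event
(zero-padded at recording edges) so wavelet edge effects do not contaminate
the 3 s of interest; power is aggregated across EEG channels by the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .config import TFConfig
from .io_formats import Event, Recording

TF_BANDS = {
    "theta": (4.5, 7.5),
    "alpha": (8.5, 11.5),
    "beta": (16.5, 29.5),
}


@dataclass
class TFProfile:
    """Relative Morlet power of one event's first 3 s, per 1 Hz bin."""

    freqs: np.ndarray          # bin centres, Hz
    rel_power: np.ndarray      # sums to 1
    band_sums: dict[str, float]


def _bin_centres(cfg: TFConfig) -> np.ndarray:
    # 1 Hz bins covering [fmin, fmax]: centres at fmin+0.5, ...
    return np.arange(cfg.fmin + 0.5, cfg.fmax, 1.0)


def event_tf_profile(
    rec: Recording,
    event: Event,
    cfg: TFConfig | None = None,
) -> TFProfile:
    """Morlet relative-power profile of the event's first 3 s."""
    cfg = cfg or TFConfig()
    if event.duration_s < 3.0:
        raise ValueError("events shorter than 3 s have no 3 s profile")
    fs = rec.fs
    onset = int(round(event.onset_s * fs))
    span = int(round(3.0 * fs))
    if onset + span > rec.n_samples:
        raise ValueError("event too close to recording end for a 3 s profile")

    freqs = _bin_centres(cfg)
    # context so the longest wavelet (n_cycles / fmin_centre) fits comfortably
    pad = int(np.ceil(cfg.n_cycles / freqs[0] * fs))
    lo = onset - pad
    hi = onset + span + pad
    eeg = rec.pick("EEG")
    seg = np.zeros((eeg.shape[0], hi - lo))
    src_lo, src_hi = max(0, lo), min(rec.n_samples, hi)
    seg[:, src_lo - lo : src_hi - lo] = eeg[:, src_lo:src_hi]

    power = tfr_array_morlet(
        seg[np.newaxis], sfreq=fs, freqs=freqs, n_cycles=cfg.n_cycles,
        output="power", zero_mean=True, verbose="error",
    )[0]                       # (n_channels, n_freqs, n_times)
    power = np.median(power, axis=0)

    ev0 = pad                  # event onset within the segment
    nbase = int(round(cfg.baseline_s * fs))
    if cfg.baseline == "event-initial":
        base = power[:, ev0 : ev0 + nbase]
    else:
        b_lo = max(0, ev0 - nbase)
        base = power[:, b_lo:ev0]
    corrected = power[:, ev0 : ev0 + span] - base.mean(axis=1, keepdims=True)

    # a bin whose 3 s power stays below its baseline carries no activation;
    # rectify so relative power and band sums stay within [0, 1]
    sums = np.clip(corrected.sum(axis=1), 0.0, None)
    total = float(sums.sum())
    if total <= 0:
        raise ValueError("non-positive total power after baseline correction")
    rel = sums / total
    band_sums = {
        name: float(rel[(freqs >= lo_) & (freqs <= hi_)].sum())
        for name, (lo_, hi_) in TF_BANDS.items()
    }
    return TFProfile(freqs=freqs, rel_power=rel, band_sums=band_sums)


def compare_profiles(
    only_ad: list[TFProfile], shared: list[TFProfile]
) -> dict[str, dict[str, float]]:
    """Descriptive per-band comparison of two event groups.

    Returns per band: the group means and SDs of the relative band power
    and their difference (``shared`` minus ``only_ad``).
    """
    if not only_ad or not shared:
        raise ValueError("both profile groups must be non-empty")
    out: dict[str, dict[str, float]] = {}
    for band in TF_BANDS:
        a = np.array([p.band_sums[band] for p in only_ad])
        b = np.array([p.band_sums[band] for p in shared])
        out[band] = {
            "only_ad_mean": float(a.mean()),
            "only_ad_sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
            "shared_mean": float(b.mean()),
            "shared_sd": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
            "mean_diff": float(b.mean() - a.mean()),
        }
    return out
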