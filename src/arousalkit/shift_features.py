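"""Per-1 s-epoch boolean features: EMG tone shifts, EEG band-power shifts,
and spindle (sigma) epochs.

All thresholds are derived from the recording itself (medians and maxima of
the data), which makes every mask invariant to a global amplitude rescaling
of the recording -- the property that lets the detector run unchanged
across amplifiers and montages.

Band power is estimated per 1 s epoch with a rectangular-window
periodogram; with an integer sampling rate this puts bins exactly on
integer frequencies, so band integration over half-open intervals
[lo, hi) Hz is exact for on-bin sinusoids (a pure sine of amplitude A
contributes A^2/2 to its band). Channel fusion is the median over the EEG
channels that are good in the surrounding 30 s window; a "max" mode
(flag if any channel shifts) is available.

EMG tone shifts use a three-step cascade:

1. global screen -- a 1 s epoch whose mean absolute amplitude exceeds the
   maximum over the first 240 s (taken as the night's artefact-free
   baseline of muscular tone) is a candidate peak;
2. local screen -- an epoch exceeding a centred 3-epoch running median by
   a configurable factor (default 2) is also a candidate;
3. validation -- a candidate is confirmed only if it exceeds (again by a
   factor, default 2) the median amplitude of the 10 nearest clean
   (non-candidate) epochs on each side; contiguous confirmed epochs merge
   into one shift.

EEG shifts in theta/alpha/beta require both a fixed threshold (the
whole-night median band power) and an adaptive one (twice the median band
power over the EMG-shift-free epochs of the scoring window plus the first
10 EMG-shift-free epochs on each side). Spindle epochs are those whose
relative sigma power, sigma / (alpha + sigma + beta), exceeds 85% of the
night's maximum relative sigma power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .channel_quality import BadChannelMask, CompositeEMG
from .config import FeatureConfig
from .io_formats import Recording
from .preprocess import EpochGrid

logger = logging.getLogger(__name__)

BANDS = ("theta", "alpha", "sigma", "beta")
TRIGGER_BANDS = ("theta", "alpha", "beta")


@dataclass
class BandPowerTable:
    """Per-epoch, channel-aggregated band power in µV^2.

    ``power`` has shape (n_epochs, 4), columns ordered as :data:`BANDS`.
    Epochs whose window has no good EEG channel are NaN, never 0.
    """

    power: np.ndarray
    bands: tuple[str, ...] = BANDS

    def band(self, name: str) -> np.ndarray:
        return self.power[:, self.bands.index(name)]


@dataclass
class ShiftMasks:
    """Boolean per-1 s-epoch feature masks feeding the event assembler."""

    emg_shift: np.ndarray                  # (n_epochs,)
    eeg_shift: dict[str, np.ndarray]       # band -> (n_epochs,)
    spindle: np.ndarray                    # (n_epochs,)


def _band_edges(cfg: FeatureConfig) -> dict[str, tuple[float, float]]:
    return {
        "theta": cfg.theta_band,
        "alpha": cfg.alpha_band,
        "sigma": cfg.sigma_band,
        "beta": cfg.beta_band,
    }


def band_power(
    rec: Recording,
    grid: EpochGrid,
    mask: BadChannelMask | None = None,
    cfg: FeatureConfig | None = None,
) -> BandPowerTable:
    """Periodogram band power per 1 s epoch, fused across good EEG channels."""
    cfg = cfg or FeatureConfig()
    fs = grid.fs
    eeg_idx = rec.channel_indices("EEG")
    n_ch = len(eeg_idx)
    n_ep = grid.n_epochs

    # (n_channels, n_epochs, fs) view of whole seconds
    x = rec.data[eeg_idx, : n_ep * fs].reshape(n_ch, n_ep, fs)
    spec = np.fft.rfft(x, axis=2)
    # one-sided power spectrum (amplitude^2/2 per non-edge bin)
    ps = (np.abs(spec) ** 2) / (fs * fs)
    ps[:, :, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(fs, d=1.0 / fs)

    edges = _band_edges(cfg)
    per_ch = np.empty((n_ch, n_ep, len(BANDS)))
    for b, name in enumerate(BANDS):
        lo, hi = edges[name]
        sel = (freqs >= lo) & (freqs < hi)
        per_ch[:, :, b] = ps[:, :, sel].sum(axis=2)

    # fuse across channels, honouring per-window bad flags
    out = np.full((n_ep, len(BANDS)), np.nan)
    if mask is None:
        fused = (
            np.median(per_ch, axis=0)
            if cfg.aggregation == "median"
            else np.max(per_ch, axis=0)
        )
        out[:] = fused
        return BandPowerTable(power=out)

    for w in range(grid.n_windows):
        good = mask.good_channel_indices(w)
        eps = grid.epochs_of_window(w)
        sl = slice(eps[0], eps[-1] + 1)
        if not good:
            continue  # stays NaN: missing marker
        block = per_ch[good, sl, :]
        out[sl] = (
            np.median(block, axis=0)
            if cfg.aggregation == "median"
            else np.max(block, axis=0)
        )
    return BandPowerTable(power=out)


def emg_magnitude(emg: CompositeEMG, grid: EpochGrid) -> np.ndarray:
    """Per-1 s-epoch mean absolute amplitude of the composite EMG (NaN where masked)."""
    fs = grid.fs
    x = emg.signal[: grid.n_epochs * fs].reshape(grid.n_epochs, fs)
    return np.mean(np.abs(x), axis=1)


def _running_median3(m: np.ndarray) -> np.ndarray:
    """Centred 3-epoch median with edge replication; NaN-tolerant."""
    left = np.concatenate([m[:1], m[:-1]])
    right = np.concatenate([m[1:], m[-1:]])
    stacked = np.vstack([left, m, right])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN epochs stay NaN
        return np.nanmedian(stacked, axis=0)


def detect_emg_shifts(
    emg: CompositeEMG,
    grid: EpochGrid,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Three-step EMG tone-shift detection; returns a boolean epoch mask."""
    cfg = cfg or FeatureConfig()
    m = emg_magnitude(emg, grid)
    usable = ~np.isnan(m)
    if not usable.any():
        logger.warning("no usable EMG anywhere; EMG shifts all false")
        return np.zeros(grid.n_epochs, dtype=bool)

    n_base = min(cfg.emg_baseline_s, grid.n_epochs)
    base = m[:n_base]
    if np.isnan(base).all():
        logger.warning("EMG baseline window fully masked; global screen disabled")
        baseline_max = np.inf
    else:
        baseline_max = float(np.nanmax(base))

    with np.errstate(invalid="ignore"):
        cand = (m > baseline_max) | (m > cfg.emg_local_factor * _running_median3(m))
    cand &= usable

    clean = usable & ~cand
    confirmed = np.zeros(grid.n_epochs, dtype=bool)
    clean_idx = np.flatnonzero(clean)
    for e in np.flatnonzero(cand):
        pos = np.searchsorted(clean_idx, e)
        neigh = np.concatenate(
            [clean_idx[max(0, pos - cfg.neighbourhood_epochs) : pos],
             clean_idx[pos : pos + cfg.neighbourhood_epochs]]
        )
        if neigh.size == 0:
            continue
        ref = float(np.median(m[neigh]))
        if ref > 0 and m[e] > cfg.emg_valid_factor * ref:
            confirmed[e] = True
    return confirmed


def _selection_threshold(
    p: np.ndarray,
    clean: np.ndarray,
    eps: range,
    cfg: FeatureConfig,
    global_med: float,
) -> float:
    """Adaptive threshold for one scoring window (see module doc)."""
    sel = [e for e in eps if clean[e]]
    k = cfg.neighbourhood_epochs
    # first k clean epochs scanning outward on each side of the window
    e = eps[0] - 1
    left: list[int] = []
    while e >= 0 and len(left) < k:
        if clean[e]:
            left.append(e)
        e -= 1
    e = eps[-1] + 1
    right: list[int] = []
    while e < len(p) and len(right) < k:
        if clean[e]:
            right.append(e)
        e += 1
    sel.extend(left)
    sel.extend(right)
    if not sel:
        logger.warning("no EMG-shift-free epochs for adaptive threshold; using global median")
        return cfg.adaptive_factor * global_med
    return cfg.adaptive_factor * float(np.median(p[sel]))


def detect_eeg_shifts(
    bp: BandPowerTable,
    emg_shift: np.ndarray,
    grid: EpochGrid,
    cfg: FeatureConfig | None = None,
) -> dict[str, np.ndarray]:
    """Fixed + adaptive band-power thresholding per theta/alpha/beta band."""
    cfg = cfg or FeatureConfig()
    out: dict[str, np.ndarray] = {}
    for name in TRIGGER_BANDS:
        p = bp.band(name)
        valid = ~np.isnan(p)
        if not valid.any():
            out[name] = np.zeros(grid.n_epochs, dtype=bool)
            continue
        global_med = float(np.nanmedian(p))
        clean = valid & ~emg_shift
        flags = np.zeros(grid.n_epochs, dtype=bool)
        for w in range(grid.n_windows):
            eps = grid.epochs_of_window(w)
            thr = _selection_threshold(p, clean, eps, cfg, global_med)
            logger.debug("window %d band %s adaptive threshold %.4g µV²", w, name, thr)
            for e in eps:
                if valid[e] and p[e] > global_med and p[e] > thr:
                    flags[e] = True
        out[name] = flags
    return out


def detect_spindle_epochs(
    bp: BandPowerTable, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Epochs whose relative sigma power is within 85% of the night's maximum."""
    cfg = cfg or FeatureConfig()
    sig = bp.band("sigma")
    denom = bp.band("alpha") + sig + bp.band("beta")
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(denom > 0, sig / denom, np.nan)
    if np.isnan(rel).all():
        logger.warning("relative sigma power undefined everywhere; no spindle epochs")
        return np.zeros(len(rel), dtype=bool)
    peak = float(np.nanmax(rel))
    with np.errstate(invalid="ignore"):
        return rel > cfg.sigma_quantile * peak


def extract_masks(
    rec: Recording,
    grid: EpochGrid,
    emg: CompositeEMG | None,
    mask: BadChannelMask | None = None,
    cfg: FeatureConfig | None = None,
) -> ShiftMasks:
    """Convenience: all three feature masks from a filtered recording."""
    cfg = cfg or FeatureConfig()
    bp = band_power(rec, grid, mask, cfg)
    if emg is None:
        emg_mask = np.zeros(grid.n_epochs, dtype=bool)
    else:
        emg_mask = detect_emg_shifts(emg, grid, cfg)
    eeg = detect_eeg_shifts(bp, emg_mask, grid, cfg)
    spindle = detect_spindle_epochs(bp, cfg)
    return ShiftMasks(emg_shift=emg_mask, eeg_shift=eeg, spindle=spindle)
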