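"""Bad-channel detection and composite EMG reconstruction.

EEG channels are screened twice: once over the whole night (flat if the
standard deviation is below 1 µV, saturated/noisy if above 6e3 µV), and
once per 30 s scoring window, where a channel whose SD deviates from the
median SD of the other good channels by a factor > 5 (or < 1/5; the rule is
two-sided by default so dead-in-window channels are caught too) is flagged
for that window only.

The two submental EMG channels are merged into one composite trace: per
30 s window, a referenced channel is dropped if flat (median absolute
value < 0.1 µV) or noisy (its median absolute value at least twice the
other's, confirmed on 1 s epochs -- the window is declared noisy only if
more than 15 of its 30 epochs have an absolute-mean ratio > 2). Where both
survive, the composite is the bipolar difference; where one survives, the
single referenced channel; where none does, the window is masked as
EMG-unavailable (never silently zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ChannelQualityConfig
from .io_formats import Recording
from .preprocess import EpochGrid

logger = logging.getLogger(__name__)


class AllChannelsBadError(RuntimeError):
    """Every EEG channel failed the global quality screen."""


@dataclass
class BadChannelMask:
    """Global and per-window bad flags for the EEG channels."""

    labels: list[str]                 # EEG channel labels, recording order
    global_bad: set[str]
    window_bad: np.ndarray            # bool, shape (n_eeg_channels, n_windows)

    def __post_init__(self) -> None:
        for lab in self.global_bad:
            idx = self.labels.index(lab)
            self.window_bad[idx, :] = True

    def is_bad(self, label: str, window: int) -> bool:
        return bool(self.window_bad[self.labels.index(label), window])

    def good_channel_indices(self, window: int) -> list[int]:
        return [i for i in range(len(self.labels)) if not self.window_bad[i, window]]


@dataclass
class CompositeEMG:
    """Single usable EMG trace with per-window provenance.

    provenance values: ``both`` (bipolar difference), ``emg1-only``,
    ``emg2-only`` (single referenced channel), ``none`` (window unusable;
    the signal there is NaN-masked).
    """

    signal: np.ndarray                # µV, NaN where unusable
    provenance: list[str] = field(default_factory=list)

    def available_epochs(self, grid: EpochGrid) -> np.ndarray:
        """Boolean per 1 s epoch: EMG usable in the parent window."""
        ok = np.zeros(grid.n_epochs, dtype=bool)
        for w, src in enumerate(self.provenance):
            if src != "none":
                for e in grid.epochs_of_window(w):
                    ok[e] = True
        return ok


def _window_slice(grid: EpochGrid, window: int) -> slice:
    eps = grid.epochs_of_window(window)
    return slice(eps[0] * grid.fs, (eps[-1] + 1) * grid.fs)


def detect_bad_eeg_global(
    rec: Recording, cfg: ChannelQualityConfig | None = None
) -> set[str]:
    """Whole-recording screen: SD < 1 µV (flat) or > 6e3 µV (noisy)."""
    cfg = cfg or ChannelQualityConfig()
    bad: set[str] = set()
    eeg_idx = rec.channel_indices("EEG")
    for i in eeg_idx:
        sd = float(np.std(rec.data[i]))
        if sd < cfg.sd_low_uv or sd > cfg.sd_high_uv:
            bad.add(rec.labels[i])
            logger.info("EEG channel %s globally bad (SD %.3g µV)", rec.labels[i], sd)
    if len(bad) == len(eeg_idx):
        raise AllChannelsBadError("all EEG channels failed the global screen")
    return bad


def detect_bad_eeg_windows(
    rec: Recording,
    grid: EpochGrid,
    global_bad: set[str],
    cfg: ChannelQualityConfig | None = None,
) -> BadChannelMask:
    """Per-30 s-window screen against the median SD of the other good channels."""
    cfg = cfg or ChannelQualityConfig()
    eeg_idx = rec.channel_indices("EEG")
    labels = [rec.labels[i] for i in eeg_idx]
    mask = np.zeros((len(eeg_idx), grid.n_windows), dtype=bool)

    good_rows = [k for k, lab in enumerate(labels) if lab not in global_bad]
    if len(good_rows) < 2:
        logger.warning("fewer than 2 good EEG channels; per-window screen skipped")
        return BadChannelMask(labels=labels, global_bad=set(global_bad), window_bad=mask)

    # per-window SD for every good channel
    sds = np.empty((len(eeg_idx), grid.n_windows))
    for w in range(grid.n_windows):
        sl = _window_slice(grid, w)
        for k, i in enumerate(eeg_idx):
            sds[k, w] = np.std(rec.data[i, sl])

    for w in range(grid.n_windows):
        for k in good_rows:
            others = [r for r in good_rows if r != k]
            ref = float(np.median(sds[others, w]))
            if ref == 0.0:
                continue
            ratio = sds[k, w] / ref
            if ratio > cfg.window_sd_ratio or (
                cfg.two_sided_ratio and ratio < 1.0 / cfg.window_sd_ratio
            ):
                mask[k, w] = True
    return BadChannelMask(labels=labels, global_bad=set(global_bad), window_bad=mask)


def build_composite_emg(
    rec: Recording,
    grid: EpochGrid,
    cfg: ChannelQualityConfig | None = None,
) -> CompositeEMG:
    """Reconstruct one usable EMG trace from the bipolar pair (see module doc)."""
    cfg = cfg or ChannelQualityConfig()
    emg_idx = rec.channel_indices("EMG")
    if len(emg_idx) != 2:
        raise ValueError(f"composite EMG needs exactly 2 EMG channels, got {len(emg_idx)}")
    e1 = rec.data[emg_idx[0]]
    e2 = rec.data[emg_idx[1]]

    composite = np.full(rec.n_samples, np.nan)
    provenance: list[str] = []

    for w in range(grid.n_windows):
        sl = _window_slice(grid, w)
        a1 = np.abs(e1[sl])
        a2 = np.abs(e2[sl])
        med1 = float(np.median(a1))
        med2 = float(np.median(a2))

        flat1 = med1 < cfg.emg_flat_median_uv
        flat2 = med2 < cfg.emg_flat_median_uv
        use1, use2 = not flat1, not flat2

        if use1 and use2:
            # noisy test: window medians first, then the per-epoch confirmation
            cand1 = med2 > 0 and med1 >= cfg.emg_noisy_ratio * med2
            cand2 = med1 > 0 and med2 >= cfg.emg_noisy_ratio * med1
            if cand1 or cand2:
                eps = grid.epochs_of_window(w)
                noisy1 = noisy2 = 0
                for e in eps:
                    es = grid.sample_slice(e)
                    m1 = float(np.mean(np.abs(e1[es])))
                    m2 = float(np.mean(np.abs(e2[es])))
                    if m2 > 0 and m1 / m2 > cfg.emg_noisy_ratio:
                        noisy1 += 1
                    if m1 > 0 and m2 / m1 > cfg.emg_noisy_ratio:
                        noisy2 += 1
                if cand1 and noisy1 > cfg.emg_noisy_epoch_quota:
                    use1 = False
                if cand2 and noisy2 > cfg.emg_noisy_epoch_quota:
                    use2 = False

        if use1 and use2:
            composite[sl] = e1[sl] - e2[sl]
            provenance.append("both")
        elif use1:
            composite[sl] = e1[sl]
            provenance.append("emg1-only")
        elif use2:
            composite[sl] = e2[sl]
            provenance.append("emg2-only")
        else:
            provenance.append("none")
            logger.warning("window %d: no usable EMG channel; EMG masked", w)

    return CompositeEMG(signal=composite, provenance=provenance)
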