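"""Filtering, mean correction, and the 30 s window / 1 s epoch time grid.

Each modality gets an order-3 Butterworth band-pass (EEG 0.5-30 Hz,
EOG 0.1-5 Hz, EMG 10-100 Hz), applied forward-backward so event onsets are
not lagged by filter group delay. A low-pass edge at or above Nyquist is
clipped to 0.9 * fs/2 with a warning (the common case: EMG 100 Hz on data
stored at 128 Hz).

The grid partitions the recording into whole seconds, grouped in 30 s
scoring windows; it is the universal time coordinate of every later stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import FilterConfig
from .io_formats import Recording

logger = logging.getLogger(__name__)

EPOCHS_PER_WINDOW = 30


@dataclass(frozen=True)
class EpochGrid:
    """30 s scoring-window / 1 s epoch partition of a recording.

    ``n_epochs`` whole seconds (remainder samples beyond the last whole
    second are excluded); window ``w`` covers epochs ``[30w, 30w+30)``.
    The final window may be partial.
    """

    fs: int
    n_epochs: int

    @property
    def n_windows(self) -> int:
        return -(-self.n_epochs // EPOCHS_PER_WINDOW)

    @property
    def partial_last_window(self) -> bool:
        return self.n_epochs % EPOCHS_PER_WINDOW != 0

    @property
    def epochs_per_window(self) -> int:
        return EPOCHS_PER_WINDOW

    def window_of(self, epoch: int) -> int:
        if not 0 <= epoch < self.n_epochs:
            raise IndexError(f"epoch {epoch} outside grid")
        return epoch // EPOCHS_PER_WINDOW

    def epoch_in_window(self, epoch: int) -> int:
        self.window_of(epoch)
        return epoch % EPOCHS_PER_WINDOW

    def epochs_of_window(self, window: int) -> range:
        if not 0 <= window < self.n_windows:
            raise IndexError(f"window {window} outside grid")
        start = window * EPOCHS_PER_WINDOW
        return range(start, min(start + EPOCHS_PER_WINDOW, self.n_epochs))

    def sample_slice(self, epoch: int) -> slice:
        self.window_of(epoch)
        return slice(epoch * self.fs, (epoch + 1) * self.fs)


def build_grid(rec: Recording) -> EpochGrid:
    """Build the epoch grid for a recording (>= 30 s required)."""
    fs = int(round(rec.fs))
    if abs(rec.fs - fs) > 1e-9:
        raise ValueError("epoch grid requires an integer sampling rate")
    n_epochs = rec.n_samples // fs
    if n_epochs < EPOCHS_PER_WINDOW:
        raise ValueError(
            f"recording too short for a 30 s scoring window ({n_epochs} s)"
        )
    grid = EpochGrid(fs=fs, n_epochs=int(n_epochs))
    if grid.partial_last_window:
        logger.info(
            "final scoring window is partial (%d of 30 epochs)",
            grid.n_epochs % EPOCHS_PER_WINDOW,
        )
    return grid


def _band_for_role(role: str, spec: FilterConfig) -> tuple[float, float]:
    return {
        "EEG": spec.eeg_band,
        "EOG": spec.eog_band,
        "EMG": spec.emg_band,
    }[role]


def apply_filters(rec: Recording, spec: FilterConfig | None = None) -> Recording:
    """Band-pass each channel according to its role.

    Raises if the recording is shorter than three time constants of the
    slowest high-pass corner among the roles present (the filter transient
    would dominate the output).
    """
    spec = spec or FilterConfig()
    nyq = rec.fs / 2.0

    lowest_hp = min(_band_for_role(r, spec)[0] for r in set(rec.roles))
    if rec.duration_s < 3.0 / lowest_hp:
        raise ValueError(
            f"recording ({rec.duration_s:.1f} s) shorter than 3 time "
            f"constants of the {lowest_hp} Hz high-pass corner"
        )

    out = np.empty_like(rec.data)
    sos_cache: dict[tuple[float, float], np.ndarray] = {}
    for i, role in enumerate(rec.roles):
        lo, hi = _band_for_role(role, spec)
        if lo >= nyq:
            raise ValueError(
                f"{role} high-pass edge {lo} Hz is above Nyquist ({nyq} Hz)"
            )
        if hi >= nyq:
            clipped = 0.9 * nyq
            logger.warning(
                "%s low-pass edge %.1f Hz >= Nyquist; clipped to %.1f Hz",
                role, hi, clipped,
            )
            hi = clipped
        key = (lo, hi)
        if key not in sos_cache:
            sos_cache[key] = signal.butter(
                spec.order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos"
            )
        if spec.zero_phase:
            out[i] = signal.sosfiltfilt(sos_cache[key], rec.data[i])
        else:
            out[i] = signal.sosfilt(sos_cache[key], rec.data[i])
    return rec.copy_with(out)


def mean_correct(rec: Recording) -> Recording:
    """Subtract each channel's whole-recording mean."""
    return rec.copy_with(rec.data - rec.data.mean(axis=1, keepdims=True))
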