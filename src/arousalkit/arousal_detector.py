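"""Assemble per-epoch shift masks into arousal events.

An arousal is a run of at least 3 consecutive 1 s epochs showing an EEG
frequency shift in theta, alpha or beta, after removing epochs whose shift
is concomitant with a sigma (spindle) epoch. Removing a spindle epoch can
split a run; runs are recomputed on the post-exclusion mask. An event is
EMG-associated if an EMG tone shift overlaps it or lies within 1 s of its
boundaries (strict-overlap mode available). Events whose onset window is
REM are kept only when EMG-associated; events starting in wake are
dropped. No inter-arousal merge gap is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import channel_quality, preprocess, shift_features
from .config import RunConfig
from .io_formats import Event, EventList, Hypnogram, Recording
from .preprocess import EpochGrid
from .shift_features import ShiftMasks, TRIGGER_BANDS

logger = logging.getLogger(__name__)


@dataclass(order=True)
class ArousalEvent(Event):
    """Detected arousal: integer-second onset/duration plus trigger metadata."""

    bands: frozenset[str] = field(default=frozenset(), compare=False)
    stage: str = field(default="", compare=False)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def assemble_events(
    masks: ShiftMasks,
    hyp: Hypnogram,
    grid: EpochGrid,
    cfg: RunConfig | None = None,
) -> EventList:
    """Apply the assembly rules (module doc) to the feature masks."""
    cfg = cfg or RunConfig()
    det = cfg.detector
    n = grid.n_epochs
    for name, m in masks.eeg_shift.items():
        if len(m) != n:
            raise ValueError(f"{name} mask length {len(m)} != grid epochs {n}")
    if hyp.duration_s < n:
        logger.info(
            "hypnogram (%d s) shorter than grid (%d s); tail treated as wake",
            hyp.duration_s, n,
        )

    any_band = np.zeros(n, dtype=bool)
    for name in TRIGGER_BANDS:
        any_band |= masks.eeg_shift[name]
    trigger = any_band & ~masks.spindle

    if not det.band_handover:
        # require one single band to sustain the whole run: events are
        # computed per band and merged afterwards
        events = []
        for name in TRIGGER_BANDS:
            bm = masks.eeg_shift[name] & ~masks.spindle
            events.extend(
                (s, ln, frozenset([name])) for s, ln in _runs(bm) if ln >= det.min_duration_s
            )
        events.sort()
        candidates = _dedupe_overlaps(events)
    else:
        candidates = []
        for start, length in _runs(trigger):
            if length < det.min_duration_s:
                continue
            bands = frozenset(
                name
                for name in TRIGGER_BANDS
                if masks.eeg_shift[name][start : start + length].any()
            )
            candidates.append((start, length, bands))

    if det.merge_gap_s > 0:
        candidates = _merge_gaps(candidates, det.merge_gap_s)

    margin = 0 if det.strict_emg_overlap else det.emg_margin_s
    out: list[ArousalEvent] = []
    for start, length, bands in candidates:
        lo = max(0, start - margin)
        hi = min(n, start + length + margin)
        emg_assoc = bool(masks.emg_shift[lo:hi].any())
        stage = hyp.stage_at_second(start)
        if stage == "W":
            continue
        if stage == "REM" and not emg_assoc:
            continue
        out.append(
            ArousalEvent(
                onset_s=float(start),
                duration_s=float(length),
                rater_id="AD",
                emg_associated=emg_assoc,
                bands=bands,
                stage=stage,
            )
        )
    return EventList(events=out)


def _dedupe_overlaps(events):
    """Merge per-band runs that overlap in time into one event (band union)."""
    merged = []
    for start, length, bands in sorted(events):
        if merged and start < merged[-1][0] + merged[-1][1]:
            ps, pl, pb = merged[-1]
            end = max(ps + pl, start + length)
            merged[-1] = (ps, end - ps, pb | bands)
        else:
            merged.append((start, length, bands))
    return merged


def _merge_gaps(events, gap):
    merged = []
    for start, length, bands in events:
        if merged and start - (merged[-1][0] + merged[-1][1]) < gap:
            ps, pl, pb = merged[-1]
            merged[-1] = (ps, start + length - ps, pb | bands)
        else:
            merged.append((start, length, bands))
    return merged


def detect(
    rec: Recording,
    hyp: Hypnogram,
    cfg: RunConfig | None = None,
    emg_only: bool = False,
) -> EventList:
    """Full pipeline: filter, screen channels, extract features, assemble events.

    Deterministic: identical inputs and config yield identical output.
    ``emg_only`` restricts the output to EMG-associated events (the
    detector's conservative variant).
    """
    cfg = cfg or RunConfig()
    filtered = preprocess.apply_filters(rec, cfg.filters)
    filtered = preprocess.mean_correct(filtered)
    grid = preprocess.build_grid(filtered)

    global_bad = channel_quality.detect_bad_eeg_global(filtered, cfg.quality)
    mask = channel_quality.detect_bad_eeg_windows(filtered, grid, global_bad, cfg.quality)

    emg = None
    if filtered.n_role("EMG") == 2:
        emg = channel_quality.build_composite_emg(filtered, grid, cfg.quality)

    masks = shift_features.extract_masks(filtered, grid, emg, mask, cfg.features)
    events = assemble_events(masks, hyp, grid, cfg)
    if emg_only:
        events = EventList(events=[e for e in events if e.emg_associated])
    return events
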