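"""Ground-truth-labelled synthetic polysomnography.

The generator emulates the statistical structure the detector relies on,
not sleep physiology: stage-labelled background EEG as 1/f-like coloured
Gaussian noise whose amplitude follows the hypnogram (deeper NREM louder),
submental EMG as a stationary broadband tone on a bipolar pair, transient
band-limited bursts (narrowband-filtered noise by default; pure sines for
analytic unit tests) standing for arousals (theta/alpha/beta) and spindles
(sigma), optional EMG tone bursts accompanying events, and injected
channel faults (flat or noisy intervals). Everything is deterministic
given the seed, and every injected feature is recorded in a ledger.

Burst intensity is specified as a POWER gain relative to the local
background power in the same band (measured on the generated background at
the event location), so "a 4x burst" means the band power during the event
is about five times the background's: the quantity the detector's
data-derived thresholds actually see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Event, EventList, Hypnogram, Recording

logger = logging.getLogger(__name__)

#: Analysis band edges (the detector's), used to express burst gain as a
#: power ratio against the local background in the band being analysed.
BAND_EDGES = {
    "theta": (3.0, 7.0),
    "alpha": (7.0, 13.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 30.0),
}

#: Synthesis rhythm bands: the oscillation an injected event actually
#: carries. These are the physiological rhythm ranges (theta ~4-7 Hz,
#: alpha rhythm ~8-11 Hz, fast spindles ~13-15 Hz, beta ~18-28 Hz), each
#: strictly inside its analysis band. Keeping them narrower than the
#: analysis bands matters for sigma in particular: a burst smeared over
#: the whole printed 11-16 Hz sigma band would put 2 of its 5 bins inside
#: the alpha analysis band (7-13 Hz overlaps 11-16 Hz), which no real
#: spindle does.
RHYTHM_BANDS = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 11.0),
    "sigma": (13.0, 15.0),
    "beta": (18.0, 28.0),
}

#: Background RMS amplitude per sleep stage, µV. Deeper NREM carries more
#: slow-wave power; REM and wake sit near N1. Values are in the range of
#: scalp EEG referenced to linked mastoids.
STAGE_AMP_UV = {"W": 20.0, "N1": 20.0, "N2": 25.0, "N3": 35.0, "REM": 20.0, "NREM": 25.0}


@dataclass(frozen=True)
class EventSpec:
    """One injected burst: seconds, band, power gain, optional EMG burst."""

    onset_s: int
    duration_s: int
    band: str
    gain: float = 4.0
    with_emg: bool = False

    def __post_init__(self) -> None:
        if self.band not in BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")
        if self.duration_s < 1:
            raise ValueError("event duration must be >= 1 s")


@dataclass(frozen=True)
class ChannelFault:
    """Injected per-channel fault over [start_s, end_s)."""

    channel: str
    start_s: int
    end_s: int
    kind: str  # "flat" | "noisy"


@dataclass
class SynthSpec:
    """Full description of one synthetic night."""

    duration_s: int = 3600
    fs: int = 128
    n_eeg: int = 3
    n_eog: int = 2
    stages: list[str] | None = None          # per 30 s; default: cyclic plan
    stage_amp_uv: dict[str, float] = field(default_factory=lambda: dict(STAGE_AMP_UV))
    spectral_exponent: float = 1.0           # background PSD ~ 1/f^exponent
    emg_rms_uv: float = 5.0
    emg_burst_gain: float = 5.0              # amplitude factor of EMG bursts
    events: list[EventSpec] = field(default_factory=list)
    faults: list[ChannelFault] = field(default_factory=list)
    burst_mode: str = "noise"                # "noise" | "sine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 30:
            raise ValueError("night must be at least one 30 s window")
        ordered = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if a.onset_s + a.duration_s > b.onset_s:
                raise ValueError(f"overlapping injected events at {b.onset_s} s")
        for ev in self.events:
            if ev.onset_s < 0 or ev.onset_s + ev.duration_s > self.duration_s:
                raise ValueError(f"event at {ev.onset_s} s outside recording")
        self.events = ordered


@dataclass
class GroundTruthLedger:
    """Exact record of what was injected."""

    events: list[EventSpec]
    faults: list[ChannelFault]
    duration_s: int

    def event_list(self, rater_id: str = "truth") -> EventList:
        return EventList(
            events=[
                Event(
                    onset_s=float(e.onset_s),
                    duration_s=float(e.duration_s),
                    rater_id=rater_id,
                    emg_associated=e.with_emg,
                )
                for e in self.events
            ]
        )

    def expected_arousals(self, hyp: Hypnogram) -> EventList:
        """Injected events a faithful detector should report: arousal-band
        bursts outside wake, and (in REM) only the EMG-accompanied ones."""
        keep = []
        for e in self.events:
            if e.band == "sigma":
                continue
            stage = hyp.stage_at_second(e.onset_s)
            if stage == "W":
                continue
            if stage == "REM" and not e.with_emg:
                continue
            keep.append(e)
        return GroundTruthLedger(keep, [], self.duration_s).event_list()


def make_stage_plan(duration_s: int) -> list[str]:
    """Simple cyclic hypnogram: 10 min wake, then 75 min sleep cycles
    (N1 5' / N2 25' / N3 20' / N2 10' / REM 15')."""
    plan: list[str] = []
    cycle = [("N1", 10), ("N2", 50), ("N3", 40), ("N2", 20), ("REM", 30)]
    plan.extend(["W"] * 20)
    while len(plan) * 30 < duration_s:
        for stage, n in cycle:
            plan.extend([stage] * n)
    return plan[: -(-duration_s // 30)]


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with PSD ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def _narrowband(n: int, fs: int, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (brick-wall in [lo, hi))."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f >= band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _band_power_1s(x: np.ndarray, fs: int, band: tuple[float, float]) -> float:
    """Mean per-1 s-epoch periodogram band power of a signal segment,
    using the same half-open integer-bin convention as the detector."""
    n_ep = len(x) // fs
    seg = x[: n_ep * fs].reshape(n_ep, fs)
    ps = (np.abs(np.fft.rfft(seg, axis=1)) ** 2) / (fs * fs)
    ps[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(fs, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    return float(ps[:, sel].sum(axis=1).mean())


def _taper(n: int, fs: int, ramp_s: float = 0.1) -> np.ndarray:
    r = min(int(ramp_s * fs), n // 2)
    env = np.ones(n)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def generate(spec: SynthSpec) -> tuple[Recording, Hypnogram, GroundTruthLedger]:
    """Synthesize one night. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = spec.duration_s * fs

    stages = spec.stages if spec.stages is not None else make_stage_plan(spec.duration_s)
    hyp = Hypnogram(stages=list(stages))

    # per-sample amplitude envelope following the hypnogram (linear ramps
    # between window centres avoid broadband steps at stage boundaries)
    n_win = len(hyp.stages)
    centres = (np.arange(n_win) + 0.5) * 30 * fs
    amps = np.array([spec.stage_amp_uv[s] for s in hyp.stages])
    envelope = np.interp(np.arange(n), centres, amps)

    labels: list[str] = []
    roles: list[str] = []
    chans: list[np.ndarray] = []
    for i in range(spec.n_eeg):
        chans.append(_colored_noise(n, spec.spectral_exponent, rng) * envelope)
        labels.append(f"EEG{i + 1}")
        roles.append("EEG")
    for i in range(spec.n_eog):
        eog = _colored_noise(n, 2.0, rng) * 40.0
        chans.append(eog)
        labels.append(f"EOG{i + 1}")
        roles.append("EOG")
    emg_rows: list[int] = []
    for i in range(2):
        emg_rows.append(len(chans))
        chans.append(rng.standard_normal(n) * spec.emg_rms_uv)
        labels.append(f"EMG{i + 1}")
        roles.append("EMG")
    data = np.vstack(chans)
    eeg_rows = list(range(spec.n_eeg))

    # inject bursts
    for ev in spec.events:
        lo = ev.onset_s * fs
        hi = (ev.onset_s + ev.duration_s) * fs
        m = hi - lo
        band = BAND_EDGES[ev.band]
        rhythm = RHYTHM_BANDS[ev.band]
        if spec.burst_mode == "sine":
            fc = 0.5 * (rhythm[0] + rhythm[1])
            burst = np.sqrt(2.0) * np.sin(2 * np.pi * fc * np.arange(m) / fs)
        else:
            burst = _narrowband(m, fs, rhythm, rng)
            # an arousal is a sustained acceleration: deliver the stated
            # band power in every second of the event, not just on average
            # (Rayleigh envelope fades of raw narrowband noise would
            # otherwise make single seconds of the event arbitrarily weak)
            chunks = burst[: ev.duration_s * fs].reshape(ev.duration_s, fs)
            per_s = np.array([_band_power_1s(c, fs, band) for c in chunks])
            burst = (chunks / np.sqrt(per_s)[:, None]).reshape(-1)
        burst = burst * _taper(m, fs)
        burst_unit_power = _band_power_1s(burst, fs, band)
        for r in eeg_rows:
            ctx_lo = max(0, lo - 4 * fs)
            ctx_hi = min(n, hi + 4 * fs)
            p_bg = _band_power_1s(data[r, ctx_lo:ctx_hi], fs, band)
            data[r, lo:hi] += burst * np.sqrt(ev.gain * p_bg / burst_unit_power)
        if ev.with_emg:
            amp = spec.emg_burst_gain * spec.emg_rms_uv
            for r in emg_rows:
                data[r, lo:hi] += rng.standard_normal(m) * amp * _taper(m, fs)

    # channel faults, applied last
    for fault in spec.faults:
        try:
            r = labels.index(fault.channel)
        except ValueError as exc:
            raise ValueError(f"fault names unknown channel {fault.channel!r}") from exc
        lo, hi = fault.start_s * fs, fault.end_s * fs
        if fault.kind == "flat":
            data[r, lo:hi] = rng.standard_normal(hi - lo) * 0.01
        elif fault.kind == "noisy":
            data[r, lo:hi] *= 20.0
        else:
            raise ValueError(f"unknown fault kind {fault.kind!r}")

    rec = Recording(data=data, fs=float(fs), labels=labels, roles=roles,
                    reference="synthetic linked-mastoid montage")
    ledger = GroundTruthLedger(events=list(spec.events), faults=list(spec.faults),
                               duration_s=spec.duration_s)
    return rec, hyp, ledger


def plan_events(
    hyp: Hypnogram,
    n_events: int,
    duration_s: int | tuple[int, int] = (3, 10),
    bands: tuple[str, ...] = ("theta", "alpha", "beta"),
    gain: float = 4.0,
    with_emg_fraction: float = 0.5,
    seed: int = 0,
    min_gap_s: int = 20,
    start_after_s: int = 240,
) -> list[EventSpec]:
    """Randomly place non-overlapping bursts in staged sleep.

    ``duration_s`` is either a fixed integer or an inclusive range from
    which each event's duration is drawn uniformly; the default 3-10 s
    spans the short end of scored arousal durations (the scoring minimum
    is 3 s; typical events run up to ~15 s). Events are kept out of wake
    windows, out of the first ``start_after_s`` (which the EMG-shift
    detector treats as its artefact-free tone baseline), and EEG-only
    events are kept out of REM (where the detector is required to reject
    them). ``with_emg_fraction`` of the events get a concomitant EMG burst.
    """
    rng = np.random.default_rng(seed)
    total = hyp.duration_s
    if isinstance(duration_s, int):
        dur_lo = dur_hi = duration_s
    else:
        dur_lo, dur_hi = duration_s
    candidates = [
        s
        for s in range(start_after_s, total - dur_hi - min_gap_s)
        if all(
            hyp.stage_at_second(t) != "W"
            for t in range(s, s + dur_hi + 1, 30)
        )
    ]
    rng.shuffle(candidates)
    chosen: list[tuple[int, int, str, bool]] = []
    taken: list[tuple[int, int]] = []
    i = 0
    for s in candidates:
        if len(chosen) >= n_events:
            break
        if any(abs(s - t0) < dur_hi + min_gap_s for t0, _ in taken):
            continue
        with_emg = (len(chosen) % max(1, round(1 / with_emg_fraction)) == 0
                    if 0 < with_emg_fraction < 1 else with_emg_fraction >= 1)
        band = bands[i % len(bands)]
        if hyp.stage_at_second(s) == "REM" and not with_emg:
            continue
        dur = int(rng.integers(dur_lo, dur_hi + 1))
        chosen.append((s, dur, band, with_emg))
        taken.append((s, dur))
        i += 1
    if len(chosen) < n_events:
        logger.warning("placed only %d of %d requested events", len(chosen), n_events)
    return sorted(
        (EventSpec(onset_s=s, duration_s=d, band=b, gain=gain, with_emg=w)
         for s, d, b, w in chosen),
        key=lambda e: e.onset_s,
    )


def make_rater(
    ledger: GroundTruthLedger,
    miss_rate: float,
    jitter_s: float,
    seed: int,
    rater_id: str = "HR",
) -> EventList:
    """Simulated human rater: drops each ledger event with ``miss_rate`` and
    jitters onsets/durations by up to ``jitter_s`` (uniform)."""
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for e in ledger.events:
        if rng.uniform() < miss_rate:
            continue
        onset = max(0.0, e.onset_s + rng.uniform(-jitter_s, jitter_s))
        dur = max(1.0, e.duration_s + rng.uniform(-jitter_s, jitter_s))
        dur = min(dur, ledger.duration_s - onset)
        out.append(Event(onset_s=onset, duration_s=dur, rater_id=rater_id,
                         emg_associated=e.with_emg))
    return EventList(events=out)
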