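"""Containers and file I/O for polysomnography signals, hypnograms and event lists.

Signals live in :class:`Recording` (µV, one sampling rate for all channels).
Sleep staging lives in :class:`Hypnogram` (30 s labels). Scored or detected
arousals live in :class:`EventList` (seconds, half-open intervals
``[onset, onset + duration)``).

EDF support is a deliberately minimal 16-bit EDF reader/writer (1 s data
records, integer sampling rates). It exists because the pipeline's native
exchange format for signals is EDF and round-trip fidelity (µV in, µV out,
up to 16-bit quantisation) is required by the detector's unit conventions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

ROLES = ("EEG", "EOG", "EMG")

#: Sleep-stage vocabulary. The reduced set {W, NREM, REM} is also accepted.
STAGES = ("W", "N1", "N2", "N3", "REM", "NREM")

_STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "1": "N1", "S1": "N1",
    "N2": "N2", "2": "N2", "S2": "N2",
    "N3": "N3", "3": "N3", "4": "N3", "S3": "N3", "S4": "N3", "SWS": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
    "NREM": "NREM", "NR": "NREM",
}

EPOCH_LEN_S = 30


class IOFormatError(ValueError):
    """Raised for malformed files or containers violating their invariants."""


@dataclass
class Recording:
    """Multichannel PSG signal block.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz, shared by every channel.
    labels : list of str
        Channel names.
    roles : list of str
        Per-channel role, one of ``EEG``, ``EOG``, ``EMG``.
    reference : str
        Free-text montage note (e.g. "linked mastoids").
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    roles: list[str]
    reference: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise IOFormatError("data must be 2-D (channels x samples)")
        if not (len(self.labels) == len(self.roles) == self.data.shape[0]):
            raise IOFormatError("labels/roles/data channel counts differ")
        if self.fs <= 0:
            raise IOFormatError("sampling rate must be positive")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise IOFormatError(f"unknown channel roles: {sorted(bad)}")
        if self.n_role("EEG") == 0:
            raise IOFormatError("at least one EEG channel is required")
        if self.n_role("EMG") not in (0, 2):
            raise IOFormatError(
                "EMG must be absent or a bipolar pair (exactly 2 channels); "
                f"got {self.n_role('EMG')}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def n_role(self, role: str) -> int:
        return sum(r == role for r in self.roles)

    def channel_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    def pick(self, role: str) -> np.ndarray:
        """View of all channels with the given role, shape (k, n_samples)."""
        return self.data[self.channel_indices(role)]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.array(data, dtype=float))


@dataclass
class Hypnogram:
    """Sequence of 30 s sleep-stage labels."""

    stages: list[str]
    epoch_len: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.epoch_len != EPOCH_LEN_S:
            raise IOFormatError("hypnogram epochs are fixed at 30 s")
        norm = []
        for s in self.stages:
            key = str(s).strip().upper()
            if key not in _STAGE_ALIASES:
                raise IOFormatError(f"unknown sleep-stage token {s!r}")
            norm.append(_STAGE_ALIASES[key])
        self.stages = norm

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> int:
        return len(self.stages) * self.epoch_len

    def stage_at_second(self, second: int) -> str:
        """Stage of the 30 s window containing ``second``.

        Seconds past the staged span are treated as wake: arousals are not
        scored in wake, so an unstaged tail is conservatively masked out.
        """
        w = int(second) // self.epoch_len
        if w < 0:
            raise IndexError("negative second index")
        if w >= len(self.stages):
            return "W"
        return self.stages[w]

    def is_rem_window(self, window: int) -> bool:
        return window < len(self.stages) and self.stages[window] == "REM"


@dataclass(order=True)
class Event:
    """One scored interval ``[onset_s, onset_s + duration_s)`` in seconds."""

    onset_s: float
    duration_s: float
    rater_id: str = field(default="", compare=False)
    emg_associated: bool | None = field(default=None, compare=False)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EventList:
    """Sorted, validated list of events from one rater or the detector."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.onset_s < 0:
                raise IOFormatError(f"negative onset {ev.onset_s}")
            if ev.duration_s <= 0:
                raise IOFormatError(f"non-positive duration {ev.duration_s}")
        self.events = sorted(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        return [
            (e.onset_s, e.duration_s, e.rater_id, e.emg_associated)
            for e in self.events
        ] == [
            (e.onset_s, e.duration_s, e.rater_id, e.emg_associated)
            for e in other.events
        ]

    def check_within(self, n_seconds: float) -> None:
        for ev in self.events:
            if ev.end_s > n_seconds:
                raise IOFormatError(
                    f"event [{ev.onset_s}, {ev.end_s}) extends past "
                    f"recording end at {n_seconds} s"
                )


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format), minimal profile: all channels share one
# integer sampling rate; data records last exactly 1 s.
# ---------------------------------------------------------------------------

_EDF_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt8(v: float) -> str:
    """Format a physical bound into <= 8 EDF header characters."""
    for spec in ("{:.6g}", "{:.4g}", "{:.2g}", "{:.1e}"):
        s = spec.format(v)
        if len(s) <= 8:
            return s
    raise IOFormatError(f"cannot encode physical bound {v} in 8 chars")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to 16-bit EDF with 1 s data records.

    The total duration is truncated to whole seconds (EDF records are 1 s).
    Physical dimension is written as uV; per-channel physical min/max are
    tight around the data so quantisation error is ~range/2^16.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise IOFormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise IOFormatError("recording shorter than one EDF record (1 s)")
    nchan = rec.n_channels
    header_bytes = 256 + 256 * nchan

    phys_min, phys_max, scaled = [], [], []
    for ch in range(nchan):
        x = rec.data[ch, : n_records * fs]
        lo = float(np.min(x))
        hi = float(np.max(x))
        if hi - lo < 1e-6:  # flat channel: avoid zero physical range
            hi = lo + 1.0
        # scale against the bounds as they will be STORED (8-char header
        # fields), so the round trip is exact up to 16-bit quantisation
        lo_s, hi_s = _fmt8(lo), _fmt8(hi)
        if float(lo_s) > lo:   # stored bound rounded inside the data range
            lo_s = _fmt8(lo - max(abs(lo) * 1e-4, 1e-4))
        if float(hi_s) < hi:
            hi_s = _fmt8(hi + max(abs(hi) * 1e-4, 1e-4))
        lo, hi = float(lo_s), float(hi_s)
        dig = np.clip(np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0), -32768, 32767)
        scaled.append(dig.astype("<i2"))
        phys_min.append(lo_s)
        phys_max.append(hi_s)

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X", 80))
        fh.write(_pad(f"ref: {rec.reference}" if rec.reference else "X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(nchan), 4))

        labels = [f"{rec.roles[i]} {rec.labels[i]}" for i in range(nchan)]
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in range(nchan):
            fh.write(_pad("", 80))  # transducer
        for _ in range(nchan):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(v, 8))
        for v in phys_max:
            fh.write(_pad(v, 8))
        for _ in range(nchan):
            fh.write(_pad("-32768", 8))
        for _ in range(nchan):
            fh.write(_pad("32767", 8))
        for _ in range(nchan):
            fh.write(_pad("", 80))  # prefiltering
        for _ in range(nchan):
            fh.write(_pad(str(fs), 8))
        for _ in range(nchan):
            fh.write(_pad("", 32))

        for r in range(n_records):
            for ch in range(nchan):
                fh.write(scaled[ch][r * fs : (r + 1) * fs].tobytes())


def _read_edf_raw(path: Path) -> tuple[list[str], list[np.ndarray], list[float], list[str]]:
    """Parse an EDF file; returns (labels, per-channel µV arrays, rates, units)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IOFormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            nchan = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise IOFormatError(f"{path}: malformed EDF header") from exc

        def fields(width: int) -> list[str]:
            raw = fh.read(width * nchan)
            return [
                raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
                for i in range(nchan)
            ]

        labels = fields(16)
        fields(80)  # transducer
        units = fields(8)
        phys_min = [float(v) for v in fields(8)]
        phys_max = [float(v) for v in fields(8)]
        dig_min = [float(v) for v in fields(8)]
        dig_max = [float(v) for v in fields(8)]
        fields(80)  # prefiltering
        ns = [int(v) for v in fields(8)]
        fields(32)

        payload = fh.read()

    rec_len = sum(ns)
    data = np.frombuffer(payload, dtype="<i2", count=n_records * rec_len)
    data = data.reshape(n_records, rec_len)
    out, rates = [], []
    off = 0
    for ch in range(nchan):
        dig = data[:, off : off + ns[ch]].reshape(-1).astype(float)
        off += ns[ch]
        gain = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
        phys = phys_min[ch] + (dig - dig_min[ch]) * gain
        unit = units[ch]
        scale = _EDF_UNIT_TO_UV.get(unit)
        if scale is None:
            logger.warning("channel %s: unknown unit %r, assuming µV", labels[ch], unit)
            scale = 1.0
        out.append(phys * scale)
        rates.append(ns[ch] / record_dur)
    return labels, out, rates, units


def read_recording(path: str | Path, role_map: dict[str, str]) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` in µV.

    Parameters
    ----------
    path : path
        EDF file.
    role_map : dict
        Maps channel labels (as stored, or with any ``"EEG "``-style prefix
        stripped) to roles. Channels absent from the map are dropped with a
        warning.
    """
    path = Path(path)
    labels, signals, rates, _units = _read_edf_raw(path)

    keep: list[int] = []
    roles: list[str] = []
    names: list[str] = []
    for i, lab in enumerate(labels):
        # EDF convention often prefixes the signal type ("EEG Fz-A1A2")
        stripped = lab.split(" ", 1)[1] if " " in lab else lab
        role = role_map.get(lab, role_map.get(stripped))
        if role is None:
            logger.warning("channel %r not in role_map; dropped", lab)
            continue
        if role not in ROLES:
            raise IOFormatError(f"role_map assigns unknown role {role!r}")
        keep.append(i)
        roles.append(role)
        names.append(stripped)

    if not keep:
        raise IOFormatError(f"{path}: no channels retained by role_map")
    rset = {rates[i] for i in keep}
    if len(rset) != 1:
        raise IOFormatError(f"{path}: mismatched sampling rates {sorted(rset)}")
    fs = rset.pop()
    data = np.vstack([signals[i] for i in keep])
    return Recording(data=data, fs=fs, labels=names, roles=roles)


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, dialect: str = "lines") -> Hypnogram:
    """Read a hypnogram; ``dialect`` is ``"lines"`` (one stage token per
    30 s epoch per line) or ``"csv"`` (columns ``onset_s,stage`` with
    contiguous 30 s rows)."""
    path = Path(path)
    if dialect == "lines":
        tokens = [t for t in path.read_text().split() if t]
        return Hypnogram(stages=tokens)
    if dialect == "csv":
        stages = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            expected = 0.0
            for row in reader:
                onset = float(row["onset_s"])
                if onset != expected:
                    raise IOFormatError(
                        f"non-contiguous hypnogram: expected onset {expected}, "
                        f"got {onset}"
                    )
                stages.append(row["stage"])
                expected += EPOCH_LEN_S
        return Hypnogram(stages=stages)
    raise IOFormatError(f"unknown hypnogram dialect {dialect!r}")


def write_hypnogram(hyp: Hypnogram, path: str | Path, dialect: str = "lines") -> None:
    path = Path(path)
    if dialect == "lines":
        path.write_text("\n".join(hyp.stages) + "\n")
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["onset_s", "stage"])
            for i, s in enumerate(hyp.stages):
                w.writerow([i * EPOCH_LEN_S, s])
    else:
        raise IOFormatError(f"unknown hypnogram dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Event lists (CSV: onset_s,duration_s,rater_id,emg_associated)
# ---------------------------------------------------------------------------

_EVENT_HEADER = ["onset_s", "duration_s", "rater_id", "emg_associated"]


def write_events(events: EventList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_HEADER)
        for ev in events:
            flag = "" if ev.emg_associated is None else str(int(ev.emg_associated))
            w.writerow([repr(ev.onset_s), repr(ev.duration_s), ev.rater_id, flag])


def read_events(path: str | Path) -> EventList:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _EVENT_HEADER:
            raise IOFormatError(
                f"{path}: expected header {','.join(_EVENT_HEADER)}"
            )
        for row in reader:
            flag = row["emg_associated"]
            out.append(
                Event(
                    onset_s=float(row["onset_s"]),
                    duration_s=float(row["duration_s"]),
                    rater_id=row["rater_id"],
                    emg_associated=None if flag == "" else bool(int(flag)),
                )
            )
    return EventList(events=out)
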