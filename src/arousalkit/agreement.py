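"""Scorer-agreement framework: 1 s epoch and event-level comparison of two
arousal detections, and the five coefficients S, kappa, Se, C, FDR.

Human scores are first converted to a 1 s-resolution boolean track: an
epoch counts as arousal iff strictly more than 0.5 s of it is marked.
Events (maximal runs of marked epochs) are considered common between two
raters when they share at least 1 s. Matching is one-to-one and greedy in
onset order by default (a gold event consumes the earliest-onset unmatched
overlapping test event); a many-to-one mode is available.

Coefficients:

* Bennett's S = 2*P0 - 1, with P0 the epoch-level accuracy;
* Cohen's kappa = (P0 - Pe)/(1 - Pe). Two chance terms are implemented:
  the standard marginal product
  Pe = [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)] / n^2, and a "paper-literal"
  variant Pr = (TP+TN)(TP+FP)/n^2 that reproduces the source formula as
  printed; reports always state which was used;
* Se = TPe / (TPe + FNe) -- fraction of gold events detected;
* C = mean over matched gold events of (seconds of the gold event covered
  by the test track) / (gold event duration);
* FDR = FPe / (TPe + FPe) -- fraction of test events matching nothing.

Undefined ratios (0/0) are reported as None with a reason, never silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AgreementConfig
from .io_formats import EventList, Hypnogram

KAPPA_BANDS = [
    (-float("inf"), 0.0, "Poor"),
    (0.0, 0.20, "Slight"),
    (0.21, 0.40, "Fair"),
    (0.41, 0.60, "Moderate"),
    (0.61, 0.80, "Substantial"),
    (0.81, 1.00, "Almost perfect"),
]


@dataclass
class DetectionTrack:
    """Boolean arousal labels, one per 1 s epoch."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 1:
            raise ValueError("track labels must be 1-D")

    @property
    def n(self) -> int:
        return len(self.labels)

    def runs(self) -> list[tuple[int, int]]:
        """Maximal true runs as (start, length) in seconds."""
        return _runs_from_bytes(bytes(self.labels.view(np.uint8)))


@dataclass
class ConfusionCounts:
    """Epoch- and event-level confusion counts plus matched-event overlaps."""

    tp_s: int
    fp_s: int
    tn_s: int
    fn_s: int
    tp_e: int
    fp_e: int
    fn_e: int
    matched: list[tuple[int, int]] = field(default_factory=list)
    # matched: (seconds of gold event covered by test track, gold event length)

    @property
    def n(self) -> int:
        return self.tp_s + self.fp_s + self.tn_s + self.fn_s


@dataclass
class AgreementReport:
    S: float | None
    kappa: float | None
    se: float | None
    c: float | None
    fdr: float | None
    counts: ConfusionCounts
    kappa_variant: str
    missing: dict[str, str] = field(default_factory=dict)

    def interpretation(self) -> str | None:
        return None if self.kappa is None else kappa_interpretation(self.kappa)

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "S": self.S,
            "kappa": self.kappa,
            "kappa_variant": self.kappa_variant,
            "kappa_interpretation": self.interpretation(),
            "Se": self.se,
            "C": self.c,
            "FDR": self.fdr,
            "counts": {
                "TPs": c.tp_s, "FPs": c.fp_s, "TNs": c.tn_s, "FNs": c.fn_s,
                "TPe": c.tp_e, "FPe": c.fp_e, "FNe": c.fn_e, "n": c.n,
            },
            "missing": self.missing,
        }


def to_track(events: EventList, n_seconds: int) -> DetectionTrack:
    """Convert events in seconds to a 1 s boolean track (> 0.5 s rule)."""
    events.check_within(n_seconds)
    cover = np.zeros(n_seconds)
    for ev in events:
        first = int(np.floor(ev.onset_s))
        last = int(np.ceil(ev.end_s))
        for e in range(first, min(last, n_seconds)):
            cover[e] += max(0.0, min(ev.end_s, e + 1.0) - max(ev.onset_s, e))
    return DetectionTrack(labels=cover > 0.5)


def _runs_from_bytes(b: bytes) -> list[tuple[int, int]]:
    out = []
    i, n = 0, len(b)
    while i < n:
        if b[i]:
            j = i + 1
            while j < n and b[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def _match_events(
    test_runs: list[tuple[int, int]],
    gold_runs: list[tuple[int, int]],
    min_overlap: int,
    one_to_one: bool,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy onset-order matching; returns (TPe, FPe, FNe, matched gold runs)."""
    test_used = [False] * len(test_runs)
    tp = 0
    matched_gold: list[tuple[int, int]] = []
    for gs, gl in gold_runs:
        ge = gs + gl
        hit = False
        for k, (ts, tl) in enumerate(test_runs):
            if one_to_one and test_used[k]:
                continue
            ov = min(ge, ts + tl) - max(gs, ts)
            if ov >= min_overlap:
                test_used[k] = True
                hit = True
                break
        if hit:
            tp += 1
            matched_gold.append((gs, gl))
    if one_to_one:
        fp = sum(1 for u in test_used if not u)
    else:
        fp = 0
        for ts, tl in test_runs:
            te = ts + tl
            if not any(min(te, gs + gl) - max(ts, gs) >= min_overlap for gs, gl in gold_runs):
                fp += 1
    fn = len(gold_runs) - tp
    return tp, fp, fn, matched_gold


def confusion(
    test: DetectionTrack,
    gold: DetectionTrack,
    cfg: AgreementConfig | None = None,
) -> ConfusionCounts:
    """Epoch- and event-level confusion counts of test against gold."""
    cfg = cfg or AgreementConfig()
    if test.n != gold.n:
        raise ValueError(f"track length mismatch: {test.n} vs {gold.n}")
    t = bytes(test.labels.view(np.uint8))
    g = bytes(gold.labels.view(np.uint8))

    tp_s = fp_s = tn_s = fn_s = 0
    for a, b in zip(t, g):
        if a:
            if b:
                tp_s += 1
            else:
                fp_s += 1
        elif b:
            fn_s += 1
        else:
            tn_s += 1

    test_runs = _runs_from_bytes(t)
    gold_runs = _runs_from_bytes(g)
    min_ov = int(round(cfg.event_overlap_s))
    tp_e, fp_e, fn_e, matched_gold = _match_events(
        test_runs, gold_runs, min_ov, cfg.matching == "one-to-one"
    )
    matched = []
    for gs, gl in matched_gold:
        covered = sum(1 for e in range(gs, gs + gl) if t[e])
        matched.append((covered, gl))
    return ConfusionCounts(
        tp_s=tp_s, fp_s=fp_s, tn_s=tn_s, fn_s=fn_s,
        tp_e=tp_e, fp_e=fp_e, fn_e=fn_e, matched=matched,
    )


def coefficients(
    counts: ConfusionCounts,
    kappa_variant: str = "standard",
) -> AgreementReport:
    """The five agreement coefficients from confusion counts."""
    n = counts.n
    if n <= 0:
        raise ValueError("empty tracks: no epochs to compare")
    missing: dict[str, str] = {}
    p0 = (counts.tp_s + counts.tn_s) / n
    s = 2.0 * p0 - 1.0

    if kappa_variant == "standard":
        pe = (
            (counts.tp_s + counts.fp_s) * (counts.tp_s + counts.fn_s)
            + (counts.tn_s + counts.fn_s) * (counts.tn_s + counts.fp_s)
        ) / (n * n)
    elif kappa_variant == "paper-literal":
        pe = (counts.tp_s + counts.tn_s) * (counts.tp_s + counts.fp_s) / (n * n)
    else:
        raise ValueError(f"unknown kappa variant {kappa_variant!r}")
    if pe == 1.0:
        kappa = None
        missing["kappa"] = "chance agreement is 1 (degenerate marginals)"
    else:
        kappa = (p0 - pe) / (1.0 - pe)

    if counts.tp_e + counts.fn_e > 0:
        se = counts.tp_e / (counts.tp_e + counts.fn_e)
    else:
        se = None
        missing["Se"] = "gold standard has no events"
    if counts.tp_e + counts.fp_e > 0:
        fdr = counts.fp_e / (counts.tp_e + counts.fp_e)
    else:
        fdr = None
        missing["FDR"] = "test has no events"
    if counts.matched:
        c = float(np.mean([ov / gl for ov, gl in counts.matched]))
    else:
        c = None
        missing["C"] = "no matched events"
    return AgreementReport(
        S=s, kappa=kappa, se=se, c=c, fdr=fdr,
        counts=counts, kappa_variant=kappa_variant, missing=missing,
    )


def compare(
    test: DetectionTrack,
    gold: DetectionTrack,
    cfg: AgreementConfig | None = None,
) -> AgreementReport:
    cfg = cfg or AgreementConfig()
    return coefficients(confusion(test, gold, cfg), cfg.kappa_variant)


def fuse_raters(
    a: DetectionTrack,
    b: DetectionTrack,
    mode: str,
    cfg: AgreementConfig | None = None,
) -> DetectionTrack:
    """Composite gold standard from two raters.

    ``inclusive``: epochwise union of the tracks. ``conservative``: only
    events identified by both raters, i.e. pairs of events sharing >= 1 s;
    each confirmed pair contributes its union interval (or the
    intersection, per config).
    """
    cfg = cfg or AgreementConfig()
    if a.n != b.n:
        raise ValueError("track length mismatch")
    if mode == "inclusive":
        return DetectionTrack(labels=a.labels | b.labels)
    if mode != "conservative":
        raise ValueError(f"unknown fusion mode {mode!r}")

    runs_a = a.runs()
    runs_b = b.runs()
    min_ov = int(round(cfg.event_overlap_s))
    out = np.zeros(a.n, dtype=bool)
    used_b = [False] * len(runs_b)
    for sa, la in runs_a:
        ea = sa + la
        for k, (sb, lb) in enumerate(runs_b):
            if used_b[k]:
                continue
            ov = min(ea, sb + lb) - max(sa, sb)
            if ov >= min_ov:
                used_b[k] = True
                if cfg.conservative_fusion == "union":
                    out[min(sa, sb) : max(ea, sb + lb)] = True
                else:
                    out[max(sa, sb) : min(ea, sb + lb)] = True
                break
    return DetectionTrack(labels=out)


def kappa_interpretation(kappa: float) -> str:
    """Qualitative label for a kappa value (Landis & Koch bands)."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.0:
        return "Poor"
    for lo, hi, label in KAPPA_BANDS[1:]:
        if kappa <= hi:
            return label
    return "Almost perfect"


def per_stage_epoch_agreement(
    test: DetectionTrack,
    gold: DetectionTrack,
    hyp: Hypnogram,
    kappa_variant: str = "standard",
) -> dict[str, dict]:
    """S and kappa restricted to the epochs of each sleep stage.

    Event-level coefficients are deliberately not stratified: entire event
    classes can be absent within a stage, which makes them unstable.
    """
    if test.n != gold.n:
        raise ValueError("track length mismatch")
    stages = np.array([hyp.stage_at_second(e) for e in range(test.n)])
    out: dict[str, dict] = {}
    for stage in sorted(set(stages)):
        sel = stages == stage
        t = test.labels[sel]
        g = gold.labels[sel]
        counts = ConfusionCounts(
            tp_s=int(np.sum(t & g)), fp_s=int(np.sum(t & ~g)),
            tn_s=int(np.sum(~t & ~g)), fn_s=int(np.sum(~t & g)),
            tp_e=0, fp_e=0, fn_e=0,
        )
        rep = coefficients(counts, kappa_variant)
        out[stage] = {"S": rep.S, "kappa": rep.kappa, "n_epochs": int(sel.sum())}
    return out
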