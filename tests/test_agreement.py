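"""Agreement coefficients against hand arithmetic and a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arousalkit as ak
from arousalkit.agreement import ConfusionCounts, DetectionTrack
from arousalkit.config import AgreementConfig


def track(bits):
    return DetectionTrack(labels=np.array(list(bits), dtype=int).astype(bool))


def brute_confusion(test, gold, min_overlap=1):
    """Independent oracle: enumerate every second and every event pair."""
    t = [bool(v) for v in test.labels]
    g = [bool(v) for v in gold.labels]
    tp = sum(1 for a, b in zip(t, g) if a and b)
    fp = sum(1 for a, b in zip(t, g) if a and not b)
    tn = sum(1 for a, b in zip(t, g) if not a and not b)
    fn = sum(1 for a, b in zip(t, g) if not a and b)

    def events(x):
        evs, cur = [], []
        for i, v in enumerate(x):
            if v:
                cur.append(i)
            elif cur:
                evs.append(set(cur))
                cur = []
        if cur:
            evs.append(set(cur))
        return evs

    tev, gev = events(t), events(g)
    used = set()
    tp_e = 0
    matched = []
    for ge in gev:
        for k, te in enumerate(sorted(tev, key=min)):
            if k in used:
                continue
            if len(ge & te) >= min_overlap:
                used.add(k)
                tp_e += 1
                covered = sum(1 for s in ge if t[s])
                matched.append((covered, len(ge)))
                break
    return ConfusionCounts(
        tp_s=tp, fp_s=fp, tn_s=tn, fn_s=fn,
        tp_e=tp_e, fp_e=len(tev) - len(used), fn_e=len(gev) - tp_e,
        matched=matched,
    )


def assert_counts_equal(a, b):
    assert (a.tp_s, a.fp_s, a.tn_s, a.fn_s) == (b.tp_s, b.fp_s, b.tn_s, b.fn_s)
    assert (a.tp_e, a.fp_e, a.fn_e) == (b.tp_e, b.fp_e, b.fn_e)
    assert sorted(a.matched) == sorted(b.matched)


class TestToTrack:
    def test_whole_second_event(self):
        evs = ak.EventList(events=[ak.Event(10.0, 3.0)])
        t = ak.to_track(evs, 20)
        assert list(np.flatnonzero(t.labels)) == [10, 11, 12]

    def test_fractional_coverage_rule(self):
        t = ak.to_track(ak.EventList(events=[ak.Event(10.6, 1.0)]), 20)
        assert not t.labels[10] and t.labels[11]      # 0.4 s vs 0.6 s

    def test_exactly_half_second_is_excluded(self):
        # both epochs get exactly 0.5 s: the rule is strictly greater-than
        t = ak.to_track(ak.EventList(events=[ak.Event(10.5, 1.0)]), 20)
        assert not t.labels.any()

    def test_event_beyond_end_rejected(self):
        with pytest.raises(Exception, match="past"):
            ak.to_track(ak.EventList(events=[ak.Event(18.0, 5.0)]), 20)


class TestFuseRaters:
    def test_disjoint_events(self):
        a = track("0111000000")
        b = track("0000001110")
        inc = ak.fuse_raters(a, b, "inclusive")
        con = ak.fuse_raters(a, b, "conservative")
        assert list(inc.labels) == list(a.labels | b.labels)
        assert not con.labels.any()

    def test_identical_tracks_fixed_point(self):
        a = track("0011100110")
        for mode in ("inclusive", "conservative"):
            assert np.array_equal(ak.fuse_raters(a, a, mode).labels, a.labels)

    def test_overlapping_pair_union_and_intersection(self):
        a = track("0" * 10 + "1" * 5 + "0" * 5)      # 10-15
        b = track("0" * 13 + "1" * 5 + "0" * 2)      # 13-18
        inc = ak.fuse_raters(a, b, "inclusive")
        assert list(np.flatnonzero(inc.labels)) == list(range(10, 18))
        con_union = ak.fuse_raters(a, b, "conservative")
        assert list(np.flatnonzero(con_union.labels)) == list(range(10, 18))
        cfg = AgreementConfig(conservative_fusion="intersection")
        con_inter = ak.fuse_raters(a, b, "conservative", cfg)
        assert list(np.flatnonzero(con_inter.labels)) == list(range(13, 15))

    def test_inclusive_dominates_inputs(self):
        rng = np.random.default_rng(0)
        a = DetectionTrack(labels=rng.random(200) < 0.1)
        b = DetectionTrack(labels=rng.random(200) < 0.1)
        inc = ak.fuse_raters(a, b, "inclusive")
        assert (inc.labels | a.labels | b.labels == inc.labels).all()

    def test_conservative_event_count_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = DetectionTrack(labels=rng.random(120) < 0.15)
            b = DetectionTrack(labels=rng.random(120) < 0.15)
            con = ak.fuse_raters(a, b, "conservative")
            assert len(con.runs()) <= min(len(a.runs()), len(b.runs()))


class TestConfusion:
    def test_identical_tracks(self):
        a = track("001110011100111000")
        c = ak.confusion(a, a)
        assert (c.tp_e, c.fp_e, c.fn_e) == (3, 0, 0)
        assert (c.fp_s, c.fn_s) == (0, 0)

    def test_fully_shifted_track(self):
        gold = track("0011100000000")
        test = track("0000000011100")
        c = ak.confusion(test, gold)
        assert (c.tp_e, c.fp_e, c.fn_e) == (0, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ak.confusion(track("01"), track("011"))

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(5, 200))
            test = DetectionTrack(labels=rng.random(n) < 0.25)
            gold = DetectionTrack(labels=rng.random(n) < 0.25)
            assert_counts_equal(ak.confusion(test, gold), brute_confusion(test, gold))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**14 - 1), st.integers(0, 2**14 - 1))
    def test_oracle_equivalence_property(self, a_bits, b_bits):
        a = DetectionTrack(labels=np.array([(a_bits >> k) & 1 for k in range(14)], bool))
        b = DetectionTrack(labels=np.array([(b_bits >> k) & 1 for k in range(14)], bool))
        assert_counts_equal(ak.confusion(a, b), brute_confusion(a, b))


class TestCoefficients:
    def test_perfect_agreement(self):
        a = track("0011100110")
        rep = ak.compare(a, a)
        assert (rep.S, rep.kappa, rep.se, rep.c, rep.fdr) == (1.0, 1.0, 1.0, 1.0, 0.0)
        rep_lit = ak.coefficients(ak.confusion(a, a), "paper-literal")
        assert rep_lit.kappa == 1.0

    def test_complement_gives_minus_one(self):
        a = track("0011100110")
        b = DetectionTrack(labels=~a.labels)
        rep = ak.compare(b, a)
        assert rep.S == -1.0

    def test_hand_worked_contingency(self):
        counts = ConfusionCounts(tp_s=50, fp_s=50, tn_s=850, fn_s=50,
                                 tp_e=0, fp_e=0, fn_e=0)
        rep = ak.coefficients(counts, "standard")
        assert rep.S == pytest.approx(0.8)
        # Pe = (100*100 + 900*900)/1e6 = 0.82 -> kappa = 0.08/0.18 = 4/9
        assert rep.kappa == pytest.approx(4.0 / 9.0)
        rep_lit = ak.coefficients(counts, "paper-literal")
        # Pr = (900*100)/1e6 = 0.09 -> (0.9-0.09)/0.91
        assert rep_lit.kappa == pytest.approx((0.9 - 0.09) / 0.91)

    def test_undefined_ratios_reported_not_nan(self):
        counts = ConfusionCounts(tp_s=0, fp_s=0, tn_s=10, fn_s=0,
                                 tp_e=0, fp_e=0, fn_e=0)
        rep = ak.coefficients(counts)
        assert rep.se is None and "Se" in rep.missing
        assert rep.fdr is None and "FDR" in rep.missing
        assert rep.c is None and "C" in rep.missing

    def test_kappa_never_exceeds_accuracy(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = DetectionTrack(labels=rng.random(100) < 0.2)
            g = DetectionTrack(labels=rng.random(100) < 0.2)
            rep = ak.compare(t, g)
            p0 = (rep.counts.tp_s + rep.counts.tn_s) / rep.counts.n
            if rep.kappa is not None:
                assert rep.kappa <= p0 + 1e-12

    def test_c_is_gold_delimited_fraction(self):
        gold = track("0011110000")         # one 4 s event
        test = track("0001100000")         # covers 2 of its 4 s
        rep = ak.compare(test, gold)
        assert rep.c == pytest.approx(0.5)


class TestKappaInterpretation:
    @pytest.mark.parametrize(
        "value,label",
        [(-0.1, "Poor"), (0.0, "Slight"), (0.20, "Slight"), (0.21, "Fair"),
         (0.40, "Fair"), (0.50, "Moderate"), (0.61, "Substantial"),
         (0.80, "Substantial"), (0.81, "Almost perfect"), (0.95, "Almost perfect"),
         (1.0, "Almost perfect")],
    )
    def test_bands(self, value, label):
        assert ak.kappa_interpretation(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            ak.kappa_interpretation(1.1)


class TestPerStage:
    def test_stratified_epoch_agreement(self):
        hyp = ak.Hypnogram(stages=["N2", "REM"])
        rng = np.random.default_rng(4)
        gold = DetectionTrack(labels=rng.random(60) < 0.3)
        test = DetectionTrack(labels=gold.labels.copy())
        test.labels[:30] = ~test.labels[:30]   # destroy agreement in N2 only
        out = ak.per_stage_epoch_agreement(test, gold, hyp)
        assert out["REM"]["S"] == 1.0
        assert out["N2"]["S"] == -1.0
        assert set(out) == {"N2", "REM"}
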