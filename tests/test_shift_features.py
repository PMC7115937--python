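"""Band-power calibration, EMG/EEG shift cascades, spindle epochs."""

import numpy as np
import pytest

import arousalkit as ak
from arousalkit.channel_quality import BadChannelMask, CompositeEMG
from arousalkit.preprocess import EpochGrid
from arousalkit.shift_features import emg_magnitude

from conftest import noise_recording

FS = 128


def composite_from(signal):
    n_win = len(signal) // (30 * FS)
    return CompositeEMG(signal=np.asarray(signal, float),
                        provenance=["both"] * n_win)


class TestBandPower:
    def test_sine_power_matches_parseval(self):
        t = np.arange(60 * FS) / FS
        rec = ak.Recording((30.0 * np.sin(2 * np.pi * 10 * t))[np.newaxis],
                           float(FS), ["c"], ["EEG"])
        bp = ak.band_power(rec, ak.build_grid(rec))
        assert np.allclose(bp.band("alpha"), 30.0**2 / 2, rtol=1e-6)
        assert np.allclose(bp.band("theta"), 0.0, atol=1e-6)
        assert np.allclose(bp.band("beta"), 0.0, atol=1e-6)

    def test_white_noise_band_ratios(self):
        """Flat-spectrum oracle: band power proportional to band width
        (theta:alpha:sigma:beta = 4:6:5:14)."""
        rec = noise_recording(n_eeg=1, duration_s=600, seed=11)
        bp = ak.band_power(rec, ak.build_grid(rec))
        means = {b: np.nanmean(bp.band(b)) for b in ("theta", "alpha", "sigma", "beta")}
        for band, width in (("alpha", 6), ("sigma", 5), ("beta", 14)):
            ratio = means[band] / means["theta"]
            assert abs(ratio - width / 4) / (width / 4) < 0.1

    def test_all_bad_window_is_missing(self):
        rec = noise_recording(n_eeg=2, duration_s=90, seed=12)
        grid = ak.build_grid(rec)
        window_bad = np.zeros((2, grid.n_windows), dtype=bool)
        window_bad[:, 1] = True
        mask = BadChannelMask(labels=["E0", "E1"], global_bad=set(),
                              window_bad=window_bad)
        bp = ak.band_power(rec, grid, mask)
        assert np.isnan(bp.power[30:60]).all()
        assert np.isfinite(bp.power[:30]).all()


class TestEMGShifts:
    def flat_with_burst(self, burst_at, burst_len, factor=10.0, duration_s=600, seed=1):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(duration_s * FS) * 5.0
        x[burst_at * FS : (burst_at + burst_len) * FS] *= factor
        return composite_from(x)

    def test_burst_epochs_flagged(self):
        grid = EpochGrid(fs=FS, n_epochs=600)
        emg = self.flat_with_burst(400, 2)
        mask = ak.detect_emg_shifts(emg, grid)
        assert mask[400] and mask[401]
        assert mask.sum() == 2

    def test_stationary_noise_unflagged(self):
        grid = EpochGrid(fs=FS, n_epochs=600)
        rng = np.random.default_rng(2)
        emg = composite_from(rng.standard_normal(600 * FS) * 5.0)
        assert ak.detect_emg_shifts(emg, grid).sum() == 0

    def test_burst_inside_baseline_window_detected(self):
        """The global screen is blind inside its own 240 s baseline, but the
        local median + validation steps still catch a 1 s peak there."""
        grid = EpochGrid(fs=FS, n_epochs=600)
        emg = self.flat_with_burst(100, 1)
        mask = ak.detect_emg_shifts(emg, grid)
        assert mask[100]

    def test_unavailable_windows_stay_false(self):
        grid = EpochGrid(fs=FS, n_epochs=600)
        emg = self.flat_with_burst(400, 2)
        emg.signal[390 * FS : 420 * FS] = np.nan
        emg.provenance[13] = "none"
        assert ak.detect_emg_shifts(emg, grid).sum() == 0

    def test_magnitude_is_epoch_mean_abs(self):
        grid = EpochGrid(fs=FS, n_epochs=60)
        sig = np.ones(60 * FS)
        sig[: FS] = -2.0
        m = emg_magnitude(composite_from(sig), grid)
        assert m[0] == 2.0 and np.allclose(m[1:], 1.0)


class TestEEGShifts:
    def base_table(self, n_epochs=600, level=10.0, seed=3):
        rng = np.random.default_rng(seed)
        power = rng.gamma(4.0, level / 4.0, size=(n_epochs, 4))
        return power

    def test_stationary_noise_low_flag_rate(self):
        """Simulation oracle: on stationary noise, channel-aggregated band
        power rarely beats both the global median and 2x the local median."""
        rec = noise_recording(n_eeg=3, duration_s=600, seed=4)
        grid = ak.build_grid(rec)
        bp = ak.band_power(rec, grid)
        flags = ak.detect_eeg_shifts(bp, np.zeros(600, bool), grid)
        for band in ("theta", "alpha", "beta"):
            assert flags[band].mean() < 0.05

    def test_isolated_spike_flagged(self):
        power = self.base_table()
        power[300, 1] = 10 * np.median(power[:, 1])
        bp = ak.BandPowerTable(power=power)
        grid = EpochGrid(fs=FS, n_epochs=600)
        flags = ak.detect_eeg_shifts(bp, np.zeros(600, bool), grid)
        assert flags["alpha"][300]

    def test_elevated_window_raises_adaptive_threshold(self):
        """The same 10x epoch is NOT flagged when its whole window (and
        neighbourhood) is elevated by the same factor: self-calibration."""
        power = self.base_table()
        power[270:330, :] *= 10.0
        bp = ak.BandPowerTable(power=power)
        grid = EpochGrid(fs=FS, n_epochs=600)
        flags = ak.detect_eeg_shifts(bp, np.zeros(600, bool), grid)
        assert not flags["alpha"][300]

    def test_flags_subset_of_above_global_median(self):
        power = self.base_table(seed=5)
        power[100:104, 0] = 20 * np.median(power[:, 0])
        bp = ak.BandPowerTable(power=power)
        grid = EpochGrid(fs=FS, n_epochs=600)
        flags = ak.detect_eeg_shifts(bp, np.zeros(600, bool), grid)
        for i, band in enumerate(("theta", "alpha", "beta")):
            col = bp.band(band)
            assert not flags[band][col <= np.median(col)].any()

    def test_emg_shift_epochs_excluded_from_adaptive_median(self):
        """Elevated power co-occurring with EMG shifts must not inflate the
        local threshold for the clean epochs around it."""
        power = self.base_table(seed=6)
        emg = np.zeros(600, bool)
        emg[300:315] = True
        power[300:315, 1] = 50 * np.median(power[:, 1])
        power[320, 1] = 10 * np.median(power[:, 1])
        bp = ak.BandPowerTable(power=power)
        grid = EpochGrid(fs=FS, n_epochs=600)
        flags = ak.detect_eeg_shifts(bp, emg, grid)
        assert flags["alpha"][320]


class TestSpindles:
    def test_sigma_sine_epoch_flagged(self):
        rec = noise_recording(n_eeg=1, duration_s=120, seed=7)
        t = np.arange(5 * FS) / FS
        rec.data[0, 60 * FS : 65 * FS] += 200 * np.sin(2 * np.pi * 13.5 * t)
        bp = ak.band_power(rec, ak.build_grid(rec))
        mask = ak.detect_spindle_epochs(bp)
        assert mask[60:65].all()
        assert mask.sum() <= 10

    def test_alpha_sine_epoch_not_flagged(self):
        rec = noise_recording(n_eeg=1, duration_s=120, seed=8)
        t = np.arange(5 * FS) / FS
        rec.data[0, 60 * FS : 65 * FS] += 200 * np.sin(2 * np.pi * 10 * t)
        # give the night a real spindle so the 85% reference is meaningful
        rec.data[0, 90 * FS : 93 * FS] += 200 * np.sin(2 * np.pi * 13.5 * t[: 3 * FS])
        bp = ak.band_power(rec, ak.build_grid(rec))
        mask = ak.detect_spindle_epochs(bp)
        assert not mask[60:65].any()
        assert mask[90:93].all()

    def test_uniform_relative_sigma_flags_everything(self):
        t = np.arange(60 * FS) / FS
        rec = ak.Recording((50 * np.sin(2 * np.pi * 13.5 * t))[np.newaxis],
                           float(FS), ["c"], ["EEG"])
        bp = ak.band_power(rec, ak.build_grid(rec))
        assert ak.detect_spindle_epochs(bp).all()


class TestScaleInvariance:
    @pytest.mark.parametrize("factor", [0.1, 10.0])
    def test_masks_invariant_to_amplitude(self, event_night, default_config, factor):
        rec, _, _ = event_night
        out = []
        for k in (1.0, factor):
            scaled = rec.copy_with(rec.data * k)
            f = ak.mean_correct(ak.apply_filters(scaled, default_config.filters))
            grid = ak.build_grid(f)
            emg = ak.build_composite_emg(f, grid, default_config.quality)
            masks = ak.extract_masks(f, grid, emg, None, default_config.features)
            out.append(masks)
        assert np.array_equal(out[0].emg_shift, out[1].emg_shift)
        assert np.array_equal(out[0].spindle, out[1].spindle)
        for band in ("theta", "alpha", "beta"):
            assert np.array_equal(out[0].eeg_shift[band], out[1].eeg_shift[band])


def test_injected_burst_epoch_recall(event_night, default_config):
    """Ground-truth bursts at 4x local band power: per-epoch recall >= 0.9
    with false-flag rate <= 0.05 outside events."""
    rec, hyp, ledger = event_night
    f = ak.mean_correct(ak.apply_filters(rec, default_config.filters))
    grid = ak.build_grid(f)
    emg = ak.build_composite_emg(f, grid, default_config.quality)
    masks = ak.extract_masks(f, grid, emg, None, default_config.features)
    any_band = (masks.eeg_shift["theta"] | masks.eeg_shift["alpha"]
                | masks.eeg_shift["beta"])
    truth = np.zeros(grid.n_epochs, bool)
    for ev in ledger.events:
        truth[ev.onset_s : ev.onset_s + ev.duration_s] = True
    assert any_band[truth].mean() >= 0.9
    assert any_band[~truth].mean() <= 0.05
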