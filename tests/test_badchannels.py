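"""Bad-channel criteria against independent brute-force recomputations."""

import numpy as np
import pytest
from scipy import signal as sps

from eegclean import (
    ArtifactSpec,
    PipelineConfig,
    SimSpec,
    detect_bad_channels,
    detect_flatline,
    detect_line_noise_ratio,
    detect_low_correlation,
    detect_spectrum_outliers,
    inject_artifact,
    legacy_detect,
    simulate_clean_eeg,
)
from eegclean.badchannels import CORR_BROKEN_FRACTION, CORR_WINDOW_S, LNR_SPLIT_HZ

from conftest import make_recording


# ---------------------------------------------------------------------------
# brute-force oracles: explicit loops, no shared code with the detectors
# ---------------------------------------------------------------------------

def brute_flatline(data, fs, flatline_s, tol=1e-8):
    out = []
    need = int(round(flatline_s * fs))
    for c in range(data.shape[0]):
        run = 1
        best = 1
        for i in range(1, data.shape[1]):
            if abs(data[c, i] - data[c, i - 1]) < tol:
                run += 1
            else:
                run = 1
            best = max(best, run)
        out.append(best >= need)
    return out


def brute_lnr(data, fs, sd):
    sos = sps.butter(4, LNR_SPLIT_HZ, btype="lowpass", fs=fs, output="sos")
    ratios = []
    for c in range(data.shape[0]):
        low = sps.sosfiltfilt(sos, data[c])
        resid = data[c] - low
        mad = lambda v: np.median(np.abs(v - np.median(v)))
        ratios.append(mad(resid) / mad(low))
    ratios = np.array(ratios)
    med = np.median(ratios)
    scale = 1.4826 * np.median(np.abs(ratios - med))
    if scale == 0:
        return [False] * len(ratios)
    return [bool((r - med) / scale > sd) for r in ratios]


def brute_spectrum(data, fs, z_thresh):
    vals = []
    for c in range(data.shape[0]):
        f, p = sps.welch(data[c], fs, nperseg=min(int(2 * fs), data.shape[1]))
        band = (f >= 1.0) & (f <= min(100.0, fs / 2))
        vals.append(np.log10(np.maximum(p[band], 1e-30)).mean())
    vals = np.array(vals)
    z = (vals - vals.mean()) / vals.std() if vals.std() > 0 else np.zeros_like(vals)
    return [bool(abs(zi) > z_thresh) for zi in z]


class TestFlatline:
    def test_six_second_flat_flagged(self, sim_short):
        data = sim_short.data.copy()
        i = sim_short.labels.index("P3")
        s = int(10 * sim_short.fs)
        data[i, s : s + int(6 * sim_short.fs)] = data[i, s]
        rec = sim_short.with_data(data, "flat")
        assert detect_flatline(rec, 5.0) == ["P3"]

    def test_four_second_flat_not_flagged(self, sim_short):
        data = sim_short.data.copy()
        i = sim_short.labels.index("P3")
        s = int(10 * sim_short.fs)
        data[i, s : s + int(4 * sim_short.fs)] = data[i, s]
        rec = sim_short.with_data(data, "flat")
        assert detect_flatline(rec, 5.0) == []

    def test_all_zero_channel_flagged(self, sim_short):
        data = sim_short.data.copy()
        data[0] = 0.0
        rec = sim_short.with_data(data, "zeroed")
        assert sim_short.labels[0] in detect_flatline(rec, 5.0)

    def test_extra_clean_channel_never_unflags(self, sim_short):
        data = sim_short.data.copy()
        data[2] = 1.0
        rec = sim_short.with_data(data, "flat")
        flagged = detect_flatline(rec, 5.0)
        bigger = make_recording(
            np.vstack([data, np.random.default_rng(0).normal(size=data.shape[1])]),
            fs=sim_short.fs,
            labels=sim_short.labels + ["EXTRA"],
        )
        assert set(flagged) <= set(detect_flatline(bigger, 5.0))


class TestLineNoiseRatio:
    def test_strong_line_channel_flagged(self, sim_short):
        cont, _ = inject_artifact(
            sim_short,
            ArtifactSpec(kind="line_sine", amplitude=2.0, params={"freq_hz": 60.0}),
        )
        data = cont.data.copy()
        i = cont.labels.index("C4")
        t = np.arange(data.shape[1]) / cont.fs
        data[i] += 20.0 * np.sin(2 * np.pi * 60 * t)  # 10x the others
        rec = cont.with_data(data, "noisy")
        assert detect_line_noise_ratio(rec, 2.5) == ["C4"]

    def test_identical_channels_none_flagged(self):
        row = np.random.default_rng(1).normal(size=2000)
        rec = make_recording(np.tile(row, (6, 1)), fs=250.0)
        assert detect_line_noise_ratio(rec, 2.5) == []

    def test_fewer_than_three_channels_skipped(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 2000)), fs=250.0)
        assert detect_line_noise_ratio(rec, 2.5) == []


class TestSpectrumOutliers:
    def test_scaled_up_channel_flagged(self, sim_short):
        data = sim_short.data.copy()
        data[4] *= 20.0
        rec = sim_short.with_data(data, "x20")
        assert detect_spectrum_outliers(rec, 2.75) == [sim_short.labels[4]]

    def test_homogeneous_none_flagged(self, sim_short):
        assert detect_spectrum_outliers(sim_short, 2.75) == []

    def test_near_silent_channel_flagged(self, sim_short):
        data = sim_short.data.copy()
        data[7] *= 0.01
        rec = sim_short.with_data(data, "x0.01")
        assert detect_spectrum_outliers(rec, 2.75) == [sim_short.labels[7]]


class TestLowCorrelation:
    def test_independent_noise_channel_flagged(self, sim_short, rng):
        data = sim_short.data.copy()
        i = sim_short.labels.index("O1")
        data[i] = rng.normal(0, data[i].std(), size=data.shape[1])
        rec = sim_short.with_data(data, "indep")
        assert "O1" in detect_low_correlation(rec, 0.7)

    def test_duplicate_channels_not_flagged(self, rng):
        base = rng.normal(size=(3, 2500))
        data = np.vstack([base, base[0]])  # duplicate pair r = 1
        rec = make_recording(data, fs=250.0)
        flagged = detect_low_correlation(rec, 0.7)
        assert "ch0" not in flagged and "ch3" not in flagged

    def test_fraction_rule(self, rng):
        # channel bad in exactly 3 of 10 windows (30% < 40%): not flagged
        fs = 100.0
        nwin = int(CORR_WINDOW_S * fs)
        shared = rng.normal(size=10 * nwin)
        a = shared + 0.01 * rng.normal(size=shared.size)
        b = shared + 0.01 * rng.normal(size=shared.size)
        c = shared.copy()
        for w in range(3):
            sl = slice(w * nwin, (w + 1) * nwin)
            c[sl] = rng.normal(size=nwin)
        rec = make_recording(np.vstack([a, b, c]), fs=fs)
        assert detect_low_correlation(rec, 0.7) == []
        # 5 of 10 windows (50% > 40%): flagged
        for w in range(3, 5):
            sl = slice(w * nwin, (w + 1) * nwin)
            c[sl] = rng.normal(size=nwin)
        rec = make_recording(np.vstack([a, b, c]), fs=fs)
        assert detect_low_correlation(rec, 0.7) == ["ch2"]


class TestOracleEquivalence:
    """Randomized 8-12 channel instances against the brute-force loops."""

    @pytest.mark.parametrize("trial", range(25))
    def test_flatline_matches_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_ch = int(rng.integers(8, 13))
        fs = 100.0
        data = rng.normal(0, 20, size=(n_ch, int(12 * fs)))
        for _ in range(rng.integers(0, 3)):
            c = int(rng.integers(0, n_ch))
            s = int(rng.integers(0, 6 * fs))
            length = int(rng.uniform(3, 8) * fs)
            data[c, s : s + length] = data[c, s]
        rec = make_recording(data, fs=fs)
        expected = [l for l, b in zip(rec.labels, brute_flatline(data, fs, 5.0)) if b]
        assert detect_flatline(rec, 5.0) == expected

    @pytest.mark.parametrize("trial", range(15))
    def test_lnr_matches_brute_force(self, trial):
        rng = np.random.default_rng(200 + trial)
        n_ch = int(rng.integers(8, 13))
        fs = 250.0
        t = np.arange(int(8 * fs)) / fs
        data = rng.normal(0, 10, size=(n_ch, t.size))
        sos = sps.butter(4, 30, btype="lowpass", fs=fs, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=1) * 3
        for c in rng.choice(n_ch, size=rng.integers(0, 3), replace=False):
            data[c] += rng.uniform(5, 30) * np.sin(2 * np.pi * 60 * t)
        rec = make_recording(data, fs=fs)
        expected = [l for l, b in zip(rec.labels, brute_lnr(data, fs, 2.5)) if b]
        assert detect_line_noise_ratio(rec, 2.5) == expected

    @pytest.mark.parametrize("trial", range(15))
    def test_spectrum_matches_brute_force(self, trial):
        rng = np.random.default_rng(300 + trial)
        n_ch = int(rng.integers(8, 13))
        fs = 250.0
        data = rng.normal(0, 10, size=(n_ch, int(8 * fs)))
        for c in rng.choice(n_ch, size=rng.integers(0, 3), replace=False):
            data[c] *= rng.choice([0.02, 30.0])
        rec = make_recording(data, fs=fs)
        expected = [l for l, b in zip(rec.labels, brute_spectrum(data, fs, 2.75)) if b]
        assert detect_spectrum_outliers(rec, 2.75) == expected

    def test_two_lnr_outliers_both_flagged(self):
        rng = np.random.default_rng(42)
        fs = 250.0
        t = np.arange(int(8 * fs)) / fs
        sos = sps.butter(4, 30, btype="lowpass", fs=fs, output="sos")
        data = sps.sosfiltfilt(sos, rng.normal(0, 10, size=(12, t.size)), axis=1) * 3
        data[2] += 40 * np.sin(2 * np.pi * 60 * t)
        data[9] += 35 * np.sin(2 * np.pi * 60 * t)
        rec = make_recording(data, fs=fs)
        got = detect_line_noise_ratio(rec, 2.5)
        expected = [l for l, b in zip(rec.labels, brute_lnr(data, fs, 2.5)) if b]
        assert got == expected
        assert {"ch2", "ch9"} <= set(got)


class TestLegacyDetect:
    def test_single_outlier_flagged(self, sim_short):
        data = sim_short.data.copy()
        data[3] *= 20.0
        assert legacy_detect(sim_short.with_data(data, "x")) == [sim_short.labels[3]]

    def test_homogeneous_empty(self, sim_short):
        assert legacy_detect(sim_short) == []

    def test_masked_outlier_found_in_second_iteration(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 10, size=(12, 2000))
        data[0] *= 400.0  # dominates the first-pass statistics
        data[1] *= 12.0  # only an outlier once ch0 is removed
        rec = make_recording(data, fs=250.0)
        first_pass = legacy_detect(rec)
        assert "ch0" in first_pass and "ch1" in first_pass
        # confirm masking: with ch0 present, a single 3-SD pass misses ch1
        vals = brute_spectrum(data, 250.0, 3.0)
        assert vals[1] is False


class TestDetectBadChannels:
    def test_injected_flat_and_noisy_found(self, sim_short):
        cont, _ = inject_artifact(
            sim_short, ArtifactSpec(kind="flat_channel", target_channels=["T8"], onsets_s=[0.0])
        )
        cont, _ = inject_artifact(
            cont, ArtifactSpec(kind="noisy_channel", amplitude=80.0, target_channels=["F4"])
        )
        out, report = detect_bad_channels(cont, PipelineConfig())
        assert set(report.union) == {"T8", "F4"}
        assert set(out.labels) == set(sim_short.labels) - {"T8", "F4"}

    def test_clean_file_empty_report(self, sim_short):
        out, report = detect_bad_channels(sim_short, PipelineConfig())
        assert report.union == []
        assert out.labels == sim_short.labels

    def test_disabled_returns_untouched(self, sim_short):
        out, report = detect_bad_channels(
            sim_short, PipelineConfig(run_bad_channels=False)
        )
        assert report.union == []
        assert np.array_equal(out.data, sim_short.data)

    def test_all_bad_fails(self):
        rec = make_recording(np.zeros((4, 3000)), fs=250.0)
        with pytest.raises(RuntimeError):
            detect_bad_channels(rec, PipelineConfig())

    def test_deterministic(self, sim_short):
        cont, _ = inject_artifact(
            sim_short, ArtifactSpec(kind="noisy_channel", amplitude=80.0, target_channels=["F4"])
        )
        r1 = detect_bad_channels(cont, PipelineConfig())[1]
        r2 = detect_bad_channels(cont, PipelineConfig())[1]
        assert r1.union == r2.union
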