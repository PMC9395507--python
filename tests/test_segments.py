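"""Segmentation, within-segment interpolation, and rejection criteria."""

import numpy as np
import pytest

from eegclean import (
    PipelineConfig,
    SimSpec,
    default_montage,
    faster_interpolate_segments,
    reject_amplitude,
    reject_jointprob,
    reject_segments,
    segment_fixed,
    simulate_clean_eeg,
)
from eegclean.segments import SegmentedRecording, jointprob_scores, segment_channel_metrics

from conftest import make_recording


def _segmented(data, fs=100.0, seg_len=1.0, labels=None, montage=None):
    rec = make_recording(data, fs=fs, labels=labels, montage=montage)
    return segment_fixed(rec, seg_len)


class TestSegmentFixed:
    def test_count_no_overlap(self, rng):
        rec = make_recording(rng.normal(size=(3, 3000)), fs=100.0)  # 30 s
        seg = segment_fixed(rec, 2.0)
        assert seg.n_segments == 15
        assert seg.segments.shape == (15, 3, 200)

    def test_count_half_overlap(self, rng):
        rec = make_recording(rng.normal(size=(3, 3000)), fs=100.0)
        seg = segment_fixed(rec, 2.0, overlap=0.5)
        assert seg.n_segments == 29

    def test_remainder_dropped(self, rng):
        rec = make_recording(rng.normal(size=(2, 1070)), fs=100.0)  # 10.7 s
        seg = segment_fixed(rec, 1.0)
        assert seg.n_segments == 10

    def test_segment_longer_than_recording(self, rng):
        rec = make_recording(rng.normal(size=(2, 100)), fs=100.0)
        with pytest.raises(ValueError):
            segment_fixed(rec, 2.0)

    def test_segments_tile_the_data(self, sim_short):
        seg = segment_fixed(sim_short, 2.0)
        rebuilt = np.concatenate(list(seg.segments), axis=1)
        n = rebuilt.shape[1]
        assert np.array_equal(rebuilt, sim_short.data[:, :n])


class TestFasterInterpolation:
    def test_injected_pulse_interpolated_locally(self, sim_short):
        seg = segment_fixed(sim_short, 2.0)
        data = seg.segments.copy()
        # zero-mean square pulse: huge variance/gradient/range in one
        # segment without shifting the channel's grand mean (which feeds
        # the deviation metric of every other segment)
        data[5, 2, 100:150] += 1000.0 * np.where(np.arange(50) % 2 == 0, 1.0, -1.0)
        corrupted = SegmentedRecording(
            segments=data, fs=seg.fs, labels=seg.labels,
            seg_len_s=2.0, overlap=0.0, montage=seg.montage,
        )
        out = faster_interpolate_segments(corrupted)
        assert out.interpolated[5] == [seg.labels[2]]
        for s in range(out.n_segments):
            if s == 5:
                continue
            assert np.array_equal(out.segments[s], data[s])
        # within segment 5, other channels untouched
        others = [i for i in range(len(seg.labels)) if i != 2]
        assert np.array_equal(out.segments[5][others], data[5][others])
        # the corrupted channel was replaced and the pulse attenuated
        assert np.abs(out.segments[5, 2]).max() < 500.0

    def test_homogeneous_segments_untouched(self, sim_short):
        seg = segment_fixed(sim_short, 2.0)
        out = faster_interpolate_segments(seg)
        untouched = [i for i, labs in enumerate(out.interpolated) if not labs]
        for i in untouched:
            assert np.array_equal(out.segments[i], seg.segments[i])

    def test_metrics_match_brute_force(self, rng):
        data = rng.normal(0, 20, size=(8, 6, 150))
        seg = SegmentedRecording(
            segments=data, fs=100.0, labels=[f"c{i}" for i in range(6)],
            seg_len_s=1.5, overlap=0.0,
        )
        got = segment_channel_metrics(seg)
        grand = data.mean(axis=(0, 2))
        for s in range(8):
            for c in range(6):
                x = data[s, c]
                assert got[s, c, 0] == pytest.approx(np.var(x))
                assert got[s, c, 1] == pytest.approx(
                    np.median(np.abs(np.diff(x)))
                )
                assert got[s, c, 2] == pytest.approx(x.max() - x.min())
                assert got[s, c, 3] == pytest.approx(abs(x.mean() - grand[c]))


class TestRejectAmplitude:
    def test_breach_flagged(self, rng):
        data = rng.normal(0, 10, size=(5, 4, 100))
        data[2, 1, 50] = 200.0
        seg = SegmentedRecording(segments=data, fs=100.0,
                                labels=list("abcd"), seg_len_s=1.0, overlap=0.0)
        mask = reject_amplitude(seg, -150.0, 150.0)
        assert mask.tolist() == [False, False, True, False, False]

    def test_within_bounds_not_flagged(self, rng):
        data = rng.normal(0, 10, size=(5, 4, 100)).clip(-100, 100)
        seg = SegmentedRecording(segments=data, fs=100.0,
                                labels=list("abcd"), seg_len_s=1.0, overlap=0.0)
        assert not reject_amplitude(seg, -150.0, 150.0).any()

    def test_matches_brute_force_scan(self, rng):
        data = rng.normal(0, 80, size=(500, 5, 40))
        seg = SegmentedRecording(segments=data, fs=40.0,
                                labels=list("abcde"), seg_len_s=1.0, overlap=0.0)
        mask = reject_amplitude(seg, -150.0, 150.0)
        for s in range(500):
            expected = False
            for c in range(5):
                for v in data[s, c]:
                    if v < -150.0 or v > 150.0:
                        expected = True
            assert mask[s] == expected

    def test_required_channel_rule(self, rng):
        data = rng.normal(0, 5, size=(4, 3, 50))
        data[1, 0, 10] = 300.0  # only one frontal channel breaches
        data[3, 0, 10] = 300.0
        data[3, 1, 12] = -300.0  # both breach
        seg = SegmentedRecording(segments=data, fs=50.0,
                                labels=["F3", "F4", "Pz"], seg_len_s=1.0, overlap=0.0)
        mask = reject_amplitude(seg, -100.0, 100.0, require_channels=["F3", "F4"])
        assert mask.tolist() == [False, False, False, True]


class TestRejectJointprob:
    def test_injected_outlier_segments_flagged(self, rng):
        data = rng.normal(0, 10, size=(100, 6, 80))
        outliers = [7, 23, 42, 68, 91]
        data[outliers] *= 10.0
        seg = SegmentedRecording(segments=data, fs=80.0,
                                labels=list("abcdef"), seg_len_s=1.0, overlap=0.0)
        mask = reject_jointprob(seg, 2.0)
        assert set(np.where(mask)[0]) == set(outliers)

    def test_matches_brute_force_scoring(self, rng):
        data = rng.normal(0, 10, size=(60, 4, 50))
        data[[5, 40]] *= 8.0
        seg = SegmentedRecording(segments=data, fs=50.0,
                                labels=list("abcd"), seg_len_s=1.0, overlap=0.0)
        scores = jointprob_scores(seg)
        # brute force: histogram density per channel, mean -log p per segment
        for c in range(4):
            pooled = data[:, c, :].ravel()
            lo, hi = pooled.min(), pooled.max()
            counts, _ = np.histogram(pooled, bins=1000, range=(lo, hi))
            prob = (counts + 1.0) / (counts.sum() + 1000)
            for s in range(60):
                acc = 0.0
                for v in data[s, c]:
                    b = min(int((v - lo) / (hi - lo) * 1000), 999)
                    acc -= np.log(prob[b])
                assert scores[s, c] == pytest.approx(acc / data.shape[2])

    def test_identical_segments_none_flagged(self):
        one = np.random.default_rng(0).normal(size=(1, 3, 40))
        data = np.repeat(one, 20, axis=0)
        seg = SegmentedRecording(segments=data, fs=40.0,
                                labels=list("abc"), seg_len_s=1.0, overlap=0.0)
        assert not reject_jointprob(seg, 2.0).any()

    def test_lowering_sd_never_unflags(self, rng):
        data = rng.normal(0, 10, size=(80, 5, 60))
        data[rng.choice(80, 6, replace=False)] *= rng.uniform(2, 8)
        seg = SegmentedRecording(segments=data, fs=60.0,
                                labels=list("abcde"), seg_len_s=1.0, overlap=0.0)
        loose = reject_jointprob(seg, 3.0)
        strict = reject_jointprob(seg, 2.0)
        assert np.all(strict[loose])  # every 3-SD rejection also at 2 SD

    def test_too_few_segments_skipped(self, rng):
        data = rng.normal(size=(5, 3, 50))
        seg = SegmentedRecording(segments=data, fs=50.0,
                                labels=list("abc"), seg_len_s=1.0, overlap=0.0)
        assert not reject_jointprob(seg, 2.0).any()


class TestRejectSegments:
    def _outlier_set(self, rng):
        data = rng.normal(0, 30, size=(60, 4, 80))
        data[[3, 30]] *= 8.0  # joint-probability outliers
        data[10, 2, 5] = 400.0  # amplitude breach only
        return SegmentedRecording(segments=data, fs=80.0,
                                  labels=list("abcd"), seg_len_s=1.0, overlap=0.0)

    def test_both_is_union(self, rng):
        seg = self._outlier_set(rng)
        cfg = PipelineConfig(amp_min=-200.0, amp_max=200.0, jp_sd=2.0)
        jp = set(np.where(reject_jointprob(seg, 2.0))[0])
        amp = set(np.where(reject_amplitude(seg, -200.0, 200.0))[0])
        out = reject_segments(seg, "both", cfg)
        assert out.n_segments == 60 - len(jp | amp)

    def test_none_keeps_counts_equal(self, rng):
        seg = self._outlier_set(rng)
        out = reject_segments(seg, "none")
        assert out.n_segments == out.n_segments_pre == 60

    def test_all_rejected_fails(self):
        data = np.zeros((12, 3, 40))
        data[:, 0, 0] = 500.0
        seg = SegmentedRecording(segments=data, fs=40.0,
                                labels=list("abc"), seg_len_s=1.0, overlap=0.0)
        with pytest.raises(RuntimeError):
            reject_segments(seg, "amplitude")

    def test_percent_retained_identity(self, rng):
        seg = self._outlier_set(rng)
        out = reject_segments(seg, "both", PipelineConfig(amp_min=-200.0, amp_max=200.0))
        assert 100.0 * out.n_segments / out.n_segments_pre == pytest.approx(
            100.0 * out.n_segments / 60
        )
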