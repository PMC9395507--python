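"""Fixed-length segmentation, within-segment channel interpolation, and
segment rejection.

For recordings without event markers the data is cut into fixed-length
segments (optionally overlapping). Two rejection criteria are available,
alone or combined:

* **amplitude** -- a segment is rejected when any retained channel leaves
  the ``[amp_min, amp_max]`` band (defaults -150/150 uV); an optional mode
  requires a designated channel group (e.g. both frontal electrodes) to
  exceed the band, the rule used for blink identification.
* **joint probability** -- per channel, each segment is scored by the mean
  negative log probability of its samples under that channel's empirical
  amplitude distribution across all segments (histogram density, 1000
  bins, Laplace smoothing). A segment is rejected when any single
  channel's score, or the channel-averaged score, deviates more than
  ``sd`` standard deviations (default 2) from the mean across segments.

An optional pre-rejection step interpolates individual channels within
individual segments: per segment, four per-channel metrics (variance,
median absolute gradient, amplitude range, deviation from the channel's
grand mean) are z-scored across channels and any channel with |z| > 3 on
any metric is replaced by its spherical-spline estimate from the segment's
remaining channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .recording import Montage, Recording

#: z threshold for the per-segment channel metrics
SEGMENT_Z = 3.0
#: histogram bins for the joint-probability density estimate
JP_BINS = 1000
#: minimum number of segments for distribution estimation
JP_MIN_SEGMENTS = 10


@dataclass
class SegmentedRecording:
    """Segments x channels x samples plus rejection bookkeeping."""

    segments: np.ndarray  # (n_segments, n_channels, seg_samples)
    fs: float
    labels: list[str]
    seg_len_s: float
    overlap: float
    montage: Montage | None = None
    reject_mask: np.ndarray | None = None
    reject_reason: list[str] = field(default_factory=list)
    interpolated: list[list[str]] = field(default_factory=list)
    n_segments_pre: int | None = None

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        if self.segments.ndim != 3:
            raise ValueError("segments must be a 3-D array")
        if self.reject_mask is None:
            self.reject_mask = np.zeros(self.n_segments, dtype=bool)
        if not self.reject_reason:
            self.reject_reason = ["none"] * self.n_segments
        if not self.interpolated:
            self.interpolated = [[] for _ in range(self.n_segments)]
        if self.n_segments_pre is None:
            self.n_segments_pre = self.n_segments

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]


def segment_fixed(
    rec: Recording, seg_len_s: float, overlap: float = 0.0
) -> SegmentedRecording:
    """Cut the recording into the maximal number of full segments.

    With overlap fraction ``o`` the segment starts advance by
    ``seg_len_s * (1 - o)``; the trailing remainder is dropped.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    nseg_samples = int(round(seg_len_s * rec.fs))
    if nseg_samples > rec.n_samples:
        raise ValueError("segment length exceeds recording duration")
    step = max(int(round(nseg_samples * (1.0 - overlap))), 1)
    starts = range(0, rec.n_samples - nseg_samples + 1, step)
    segs = np.stack([rec.data[:, s : s + nseg_samples] for s in starts])
    return SegmentedRecording(
        segments=segs,
        fs=rec.fs,
        labels=list(rec.labels),
        seg_len_s=seg_len_s,
        overlap=overlap,
        montage=rec.montage,
    )


# ---------------------------------------------------------------------------
# within-segment channel interpolation
# ---------------------------------------------------------------------------

def segment_channel_metrics(seg: SegmentedRecording) -> np.ndarray:
    """The four per-channel metrics, shape (n_segments, n_channels, 4):
    variance, median absolute gradient, amplitude range, deviation of the
    segment mean from the channel's grand mean."""
    x = seg.segments
    grand_mean = x.mean(axis=(0, 2))  # per channel
    var = x.var(axis=2)
    grad = np.median(np.abs(np.diff(x, axis=2)), axis=2)
    rng = x.max(axis=2) - x.min(axis=2)
    dev = np.abs(x.mean(axis=2) - grand_mean[None, :])
    return np.stack([var, grad, rng, dev], axis=2)


def faster_interpolate_segments(
    seg: SegmentedRecording, montage: Montage | None = None
) -> SegmentedRecording:
    """Interpolate outlier channels within individual segments.

    Channels with any metric |z| > 3 across channels in a segment are
    replaced by the spherical-spline estimate from the segment's other
    channels. Segments where more than half the channels are flagged are
    left unmodified (and noted with a ``*`` in the log).
    """
    from .reference import spline_interpolation_matrix

    montage = montage or seg.montage
    if montage is None:
        raise ValueError("within-segment interpolation requires a montage")
    if seg.n_channels < 4:
        raise ValueError("within-segment interpolation requires >= 4 channels")
    metrics = segment_channel_metrics(seg)
    mu = metrics.mean(axis=1, keepdims=True)
    sd = metrics.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs((metrics - mu) / sd)
    z = np.nan_to_num(z, nan=0.0)
    bad = (z > SEGMENT_Z).any(axis=2)  # (n_segments, n_channels)

    out = seg.segments.copy()
    log: list[list[str]] = []
    pos = montage.unit_positions(seg.labels)
    for s in range(seg.n_segments):
        flagged = np.where(bad[s])[0]
        if flagged.size == 0:
            log.append([])
            continue
        if flagged.size > seg.n_channels // 2:
            log.append([seg.labels[i] + "*" for i in flagged])  # too many: skip
            continue
        good = np.setdiff1d(np.arange(seg.n_channels), flagged)
        mat = spline_interpolation_matrix(pos[good], pos[flagged])
        out[s, flagged] = mat @ out[s, good]
        log.append([seg.labels[i] for i in flagged])
    return SegmentedRecording(
        segments=out,
        fs=seg.fs,
        labels=seg.labels,
        seg_len_s=seg.seg_len_s,
        overlap=seg.overlap,
        montage=seg.montage,
        reject_mask=seg.reject_mask.copy(),
        reject_reason=list(seg.reject_reason),
        interpolated=log,
        n_segments_pre=seg.n_segments_pre,
    )


# ---------------------------------------------------------------------------
# rejection criteria
# ---------------------------------------------------------------------------

def reject_amplitude(
    seg: SegmentedRecording,
    amp_min: float = -150.0,
    amp_max: float = 150.0,
    require_channels: list[str] | None = None,
    require_count: int | None = None,
) -> np.ndarray:
    """Boolean mask of segments breaching the amplitude band.

    Default: any channel outside ``[amp_min, amp_max]`` flags the segment.
    With ``require_channels``, at least ``require_count`` (default: all) of
    the designated channels must breach the band -- the rule used to
    identify blinks from the frontal electrode pair.
    """
    if amp_min >= amp_max:
        raise ValueError("amp_min must be < amp_max")
    breach = (seg.segments < amp_min) | (seg.segments > amp_max)
    per_channel = breach.any(axis=2)  # (n_segments, n_channels)
    if require_channels is None:
        return per_channel.any(axis=1)
    idx = [seg.labels.index(l) for l in require_channels]
    need = len(idx) if require_count is None else require_count
    return per_channel[:, idx].sum(axis=1) >= need


def jointprob_scores(seg: SegmentedRecording) -> np.ndarray:
    """Per-channel, per-segment mean negative log probability,
    shape (n_segments, n_channels)."""
    n_seg, n_ch, n_samp = seg.segments.shape
    scores = np.empty((n_seg, n_ch))
    for c in range(n_ch):
        pooled = seg.segments[:, c, :].ravel()
        lo, hi = pooled.min(), pooled.max()
        if hi == lo:
            scores[:, c] = 0.0
            continue
        counts, edges = np.histogram(pooled, bins=JP_BINS, range=(lo, hi))
        prob = (counts + 1.0) / (counts.sum() + JP_BINS)  # Laplace smoothing
        idx = np.clip(
            ((seg.segments[:, c, :] - lo) / (hi - lo) * JP_BINS).astype(int),
            0,
            JP_BINS - 1,
        )
        scores[:, c] = -np.log(prob[idx]).mean(axis=1)
    return scores


def reject_jointprob(seg: SegmentedRecording, sd: float = 2.0) -> np.ndarray:
    """Boolean mask of segments with improbable amplitude distributions.

    A segment is flagged when any channel's score z (across segments) or
    the channel-averaged score z exceeds ``sd``.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if seg.n_segments < JP_MIN_SEGMENTS:
        return np.zeros(seg.n_segments, dtype=bool)
    scores = jointprob_scores(seg)
    mu = scores.mean(axis=0, keepdims=True)
    sigma = scores.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_local = np.abs((scores - mu) / sigma)
    z_local = np.nan_to_num(z_local, nan=0.0)
    gscore = scores.mean(axis=1)
    gsd = gscore.std()
    z_global = np.abs(gscore - gscore.mean()) / gsd if gsd > 0 else np.zeros_like(gscore)
    return (z_local > sd).any(axis=1) | (z_global > sd)


def reject_segments(
    seg: SegmentedRecording,
    method: str = "jointprob",
    config: PipelineConfig | None = None,
) -> SegmentedRecording:
    """Apply the selected rejection criteria and drop flagged segments.

    ``method`` is one of ``none``/``jointprob``/``amplitude``/``both``;
    ``both`` rejects segments failing either criterion. Pre/post counts
    are preserved on the result for reporting.
    """
    if method not in ("none", "jointprob", "amplitude", "both"):
        raise ValueError(f"unknown rejection method {method!r}")
    config = config or PipelineConfig()
    n = seg.n_segments
    jp = np.zeros(n, dtype=bool)
    amp = np.zeros(n, dtype=bool)
    if method in ("jointprob", "both"):
        jp = reject_jointprob(seg, config.jp_sd)
    if method in ("amplitude", "both"):
        amp = reject_amplitude(
            seg, config.amp_min, config.amp_max, config.require_channels
        )
    mask = jp | amp
    reasons = [
        "both" if j and a else "jointprob" if j else "amplitude" if a else "none"
        for j, a in zip(jp, amp)
    ]
    if mask.all() and n > 0:
        raise RuntimeError("all segments rejected; file failed")
    keep = ~mask
    return SegmentedRecording(
        segments=seg.segments[keep],
        fs=seg.fs,
        labels=seg.labels,
        seg_len_s=seg.seg_len_s,
        overlap=seg.overlap,
        montage=seg.montage,
        reject_mask=np.zeros(int(keep.sum()), dtype=bool),
        reject_reason=[r for r, k in zip(reasons, keep) if k],
        interpolated=[il for il, k in zip(seg.interpolated, keep) if k],
        n_segments_pre=n,
    )
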