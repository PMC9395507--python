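"""Detection of channels that carry no usable brain signal.

Four criteria are applied in order, each optional parameter carrying the
optimised low-density default:

1. **Flatline** -- a run of near-constant samples longer than ``flatline_s``
   seconds (default 5 s) marks the channel bad.
2. **Line-noise ratio** -- the ratio of high-frequency residual to
   low-passed signal amplitude (robust, MAD-based) is z-scored across
   channels; channels above ``lnr_sd`` (default 2.5) are bad.
3. **Channel correlation** -- in consecutive 5 s windows a channel whose
   best absolute correlation with any other channel falls below
   ``min_corr`` (default 0.7) is "bad in window"; bad in more than 40% of
   windows marks the channel bad.
4. **Spectrum outliers** -- mean log PSD over 1-100 Hz is z-scored across
   channels; |z| above ``spectrum_z`` (default 2.75) marks the channel bad.

Flat channels are excluded from the statistics of the later criteria so a
dead channel cannot mask a merely noisy one. The legacy single-criterion
method (two iterations of 3-SD outlier removal on mean log power 1-125 Hz)
is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .recording import Recording

#: successive-difference tolerance below which samples count as flat (uV)
FLAT_TOL = 1e-8
#: low-pass split between "signal" and "line-noise residual" (Hz)
LNR_SPLIT_HZ = 45.0
#: correlation criterion window length (s) and broken-time fraction
CORR_WINDOW_S = 5.0
CORR_BROKEN_FRACTION = 0.4


@dataclass
class BadChannelReport:
    """Per-criterion flagged channels and their union."""

    flat: list[str] = field(default_factory=list)
    high_line_noise: list[str] = field(default_factory=list)
    low_correlation: list[str] = field(default_factory=list)
    spectrum_outlier: list[str] = field(default_factory=list)
    params_used: dict = field(default_factory=dict)

    @property
    def union(self) -> list[str]:
        seen: list[str] = []
        for group in (self.flat, self.high_line_noise, self.low_correlation, self.spectrum_outlier):
            for lab in group:
                if lab not in seen:
                    seen.append(lab)
        return seen


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_flatline(rec: Recording, flatline_s: float = 5.0) -> list[str]:
    """Channels containing a near-constant run of at least ``flatline_s`` s."""
    if flatline_s >= rec.duration:
        raise ValueError("flatline_s must be shorter than the recording")
    min_run = int(round(flatline_s * rec.fs))
    flagged = []
    for lab, x in zip(rec.labels, rec.data):
        flat = np.abs(np.diff(x)) < FLAT_TOL
        # longest run of True in `flat`; a run of k diffs spans k+1 samples
        best = run = 0
        for v in flat:
            run = run + 1 if v else 0
            if run > best:
                best = run
                if best + 1 >= min_run:
                    break
        if best + 1 >= min_run:
            flagged.append(lab)
    return flagged


def _lnr_noisiness(data: np.ndarray, fs: float) -> np.ndarray:
    """Robust line-noise-to-signal amplitude ratio per channel."""
    if LNR_SPLIT_HZ >= fs / 2:
        # everything below Nyquist counts as signal; no residual band
        return np.zeros(data.shape[0])
    sos = sps.butter(4, LNR_SPLIT_HZ, btype="lowpass", fs=fs, output="sos")
    low = sps.sosfiltfilt(sos, data, axis=1)
    resid = data - low
    out = np.empty(data.shape[0])
    for i in range(data.shape[0]):
        denom = _mad(low[i])
        out[i] = _mad(resid[i]) / denom if denom > 0 else np.inf if _mad(resid[i]) > 0 else 0.0
    return out


def detect_line_noise_ratio(rec: Recording, sd: float = 2.5) -> list[str]:
    """Channels whose noise-to-signal ratio is a cross-channel outlier.

    The z-score uses robust centre and scale (median, 1.4826 MAD) so that
    several simultaneously noisy channels cannot mask each other.
    """
    if rec.n_channels < 3:
        return []
    noisiness = _lnr_noisiness(rec.data, rec.fs)
    center = np.median(noisiness)
    scale = 1.4826 * np.median(np.abs(noisiness - center))
    if scale == 0:
        return []
    z = (noisiness - center) / scale
    return [lab for lab, zi in zip(rec.labels, z) if zi > sd]


def detect_low_correlation(rec: Recording, min_corr: float = 0.7) -> list[str]:
    """Channels poorly correlated with every other channel in most windows."""
    if rec.n_channels < 3:
        return []
    nwin = int(round(CORR_WINDOW_S * rec.fs))
    if nwin > rec.n_samples:
        nwin = rec.n_samples  # single full-length window
    n_windows = rec.n_samples // nwin
    bad_counts = np.zeros(rec.n_channels, dtype=int)
    for w in range(n_windows):
        seg = rec.data[:, w * nwin : (w + 1) * nwin]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        c = np.nan_to_num(c, nan=0.0)
        np.fill_diagonal(c, 0.0)
        best = np.abs(c).max(axis=1)
        best[sd == 0] = 0.0  # a dead channel correlates with nothing
        bad_counts += best < min_corr
    frac = bad_counts / n_windows
    return [lab for lab, f in zip(rec.labels, frac) if f > CORR_BROKEN_FRACTION]


def _mean_log_power(data: np.ndarray, fs: float, fmin: float, fmax: float) -> np.ndarray:
    """Mean log10 Welch PSD per channel over [fmin, fmax] (capped at Nyquist)."""
    nperseg = min(int(2 * fs), data.shape[1])
    freqs, psd = sps.welch(data, fs, nperseg=nperseg, axis=1)
    band = (freqs >= fmin) & (freqs <= min(fmax, fs / 2))
    return np.log10(np.maximum(psd[:, band], 1e-30)).mean(axis=1)


def detect_spectrum_outliers(rec: Recording, z_thresh: float = 2.75) -> list[str]:
    """Channels whose mean log power (1-100 Hz) is a cross-channel outlier."""
    if rec.n_channels < 4:
        return []
    logp = _mean_log_power(rec.data, rec.fs, 1.0, 100.0)
    mu, sigma = logp.mean(), logp.std()
    if sigma == 0:
        return []
    z = (logp - mu) / sigma
    return [lab for lab, zi in zip(rec.labels, z) if abs(zi) > z_thresh]


def legacy_detect(rec: Recording, sd: float = 3.0) -> list[str]:
    """Two iterations of ``sd``-SD outlier removal on mean log power 1-125 Hz."""
    if rec.n_channels < 4:
        return []
    logp = _mean_log_power(rec.data, rec.fs, 1.0, 125.0)
    labels = list(rec.labels)
    flagged: list[str] = []
    values = dict(zip(labels, logp))
    for _ in range(2):
        survivors = [l for l in labels if l not in flagged]
        if len(survivors) < 4:
            break
        v = np.array([values[l] for l in survivors])
        mu, sigma = v.mean(), v.std()
        if sigma == 0:
            break
        newly = [l for l, vi in zip(survivors, v) if abs(vi - mu) / sigma > sd]
        if not newly:
            break
        flagged.extend(newly)
    return flagged


def detect_bad_channels(
    rec: Recording, config: PipelineConfig | None = None
) -> tuple[Recording, BadChannelReport]:
    """Run all criteria in order and drop the union from the recording.

    Returns the reduced recording (flagged channels removed, ready for
    later spherical-spline interpolation) and the per-criterion report.
    When ``config.run_bad_channels`` is false the recording is returned
    untouched with an empty report.
    """
    config = config or PipelineConfig()
    report = BadChannelReport(
        params_used={
            "flatline_s": config.flatline_s,
            "lnr_sd": config.lnr_sd,
            "min_corr": config.min_corr,
            "spectrum_z": config.spectrum_z,
            "legacy": config.legacy_bad_channels,
        }
    )
    if not config.run_bad_channels:
        return rec, report

    if config.legacy_bad_channels:
        report.spectrum_outlier = legacy_detect(rec)
    else:
        report.flat = detect_flatline(rec, config.flatline_s)
        keep = [l for l in rec.labels if l not in report.flat]
        sub = rec.subset(keep) if report.flat else rec
        report.high_line_noise = detect_line_noise_ratio(sub, config.lnr_sd)
        report.low_correlation = detect_low_correlation(sub, config.min_corr)
        report.spectrum_outlier = detect_spectrum_outliers(sub, config.spectrum_z)

    union = report.union
    if len(union) == rec.n_channels:
        raise RuntimeError("all channels flagged bad; file failed")
    good = [l for l in rec.labels if l not in union]
    out = rec.subset(good, stage=f"bad_channels: removed {union or 'none'}")
    return out, report
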