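"""Multitaper sinusoidal-regression removal of mains noise.

Rather than notch filtering (which distorts neighbouring frequencies), a
deterministic sinusoid is fitted within each sliding window using Thomson's
multitaper harmonic analysis and subtracted only where the fit is
statistically significant:

1. Slide a ``window_s`` window over each channel in ``step_s`` steps.
2. Within the window, scan a fine frequency grid spanning each target
   frequency +/- ``scan_bandwidth`` Hz; at each grid frequency compute the
   complex amplitude estimate ``mu(f)`` from the DPSS eigencoefficients and
   Thomson's F-statistic for a deterministic sinusoid.
3. Gate each window on Thomson's F-test at ``p_sig`` (F with 2 and 2K-2
   degrees of freedom); insignificant windows contribute nothing.
4. Re-express the significant windows' complex amplitudes at a common
   reference frequency and smooth them across windows with an exponential
   kernel of width ``smoothing_tau`` (in window steps). The deterministic
   tone is coherent from window to window and survives the average, while
   the background's same-frequency noise component is incoherent and
   averages out -- so the subtraction does not bite into the noise floor.
   Overlapping window tracks are then blended with a flat-top taper. The
   legacy mode skips the cross-window smoothing and blending (each
   window's raw estimate is used over its own step chunk), reproducing
   the behaviour of the original implementation before the overlap fix.

The fit/subtract construction is strictly subtractive: the returned
artifact track added back to the output reproduces the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .filters import bandpass_narrow
from .recording import Recording

#: QC probe offsets around the line frequency (Hz)
QC_OFFSETS = (-5.0, -2.0, -1.0, 0.0, 1.0, 2.0, 5.0)


@dataclass
class LineNoiseParams:
    """Sinusoidal-regression parameters (defaults follow common practice:
    +/-2 Hz scan, 4 s window, 1 s step, smoothing tau 100, p = 0.01)."""

    target_freqs: list[float] = field(default_factory=lambda: [60.0])
    scan_bandwidth: float = 2.0
    window_s: float = 4.0
    step_s: float = 1.0
    smoothing_tau: float = 100.0
    p_sig: float = 0.01
    taper_bandwidth: float = 2.0  # full analysis bandwidth in Hz
    legacy: bool = False

    def __post_init__(self) -> None:
        if self.step_s > self.window_s:
            raise ValueError("step_s must not exceed window_s")
        if not (0 < self.p_sig < 1):
            raise ValueError("p_sig must be in (0, 1)")


def _dpss_tapers(n: int, fs: float, bandwidth: float) -> np.ndarray:
    """DPSS tapers with time-half-bandwidth NW = T * bandwidth / 2."""
    nw = max(n / fs * bandwidth / 2.0, 1.0)
    k = max(int(2 * nw) - 1, 1)
    return sps.windows.dpss(n, nw, Kmax=k)  # (K, n)


def _harmonic_fit(
    xw: np.ndarray, fs: float, f0: float, scan_bw: float, tapers: np.ndarray
) -> tuple[float, complex, float]:
    """Thomson harmonic analysis of one window of one channel.

    Returns ``(f_hat, mu, f_stat)``: the peak frequency within
    ``f0 +/- scan_bw``, its complex amplitude (so the fitted sinusoid is
    ``2 Re(mu exp(2i pi f_hat t))``), and the F statistic at the peak.
    """
    n = xw.size
    k = tapers.shape[0]
    t = np.arange(n) / fs
    df = min(0.05, 1.0 / (4 * n / fs))
    freqs = np.arange(f0 - scan_bw, f0 + scan_bw + df / 2, df)
    # eigencoefficients J[k, f]
    phasor = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])  # (F, n)
    tapered = tapers * xw[None, :]  # (K, n)
    J = phasor @ tapered.T  # (F, K)
    h0 = tapers.sum(axis=1)  # (K,), zero for odd tapers
    denom_h = float(h0 @ h0)
    mu = (J @ h0) / denom_h  # (F,)
    resid = J - mu[:, None] * h0[None, :]
    ss_res = np.sum(np.abs(resid) ** 2, axis=1)
    ss_res = np.maximum(ss_res, 1e-300)
    fstat = (k - 1) * np.abs(mu) ** 2 * denom_h / ss_res
    i = int(np.argmax(fstat))
    return float(freqs[i]), complex(mu[i]), float(fstat[i])


def _window_weight(n: int, tau: float) -> np.ndarray:
    """Flat-top blending weight: product of two sigmoids of steepness tau."""
    u = (np.arange(n) + 0.5) / n
    return 1.0 / (1.0 + np.exp(-tau * u)) / (1.0 + np.exp(-tau * (1.0 - u)))


def estimate_line_artifact(rec: Recording, params: LineNoiseParams) -> np.ndarray:
    """Estimated deterministic line-noise track, same shape as the data."""
    fs = rec.fs
    for f in params.target_freqs:
        if f >= fs / 2:
            raise ValueError(f"target frequency {f} Hz >= Nyquist ({fs / 2} Hz)")
    nwin = int(round(params.window_s * fs))
    if nwin > rec.n_samples:
        raise ValueError("analysis window longer than the recording")
    step = max(int(round(params.step_s * fs)), 1)
    tapers = _dpss_tapers(nwin, fs, params.taper_bandwidth)
    k = tapers.shape[0]
    f_crit = stats.f.ppf(1.0 - params.p_sig, 2, 2 * k - 2)

    starts = list(range(0, rec.n_samples - nwin + 1, step))
    if starts[-1] != rec.n_samples - nwin:
        starts.append(rec.n_samples - nwin)  # cover the tail
    n_starts = len(starts)
    h0 = tapers.sum(axis=1)
    denom_h = float(h0 @ h0)
    k = tapers.shape[0]

    # kernel for smoothing complex amplitudes across windows: the tone is
    # coherent between windows, background noise is not, so averaging the
    # per-window estimates removes the deterministic component without
    # biting into the noise floor at the same frequency
    tau_windows = max(params.smoothing_tau, 1.0)
    lags = np.arange(n_starts)
    kernel = np.exp(-np.abs(lags[:, None] - lags[None, :]) / tau_windows)

    artifact = np.zeros_like(rec.data)
    weight = _window_weight(nwin, 25.0)
    for ci in range(rec.n_channels):
        x = rec.data[ci]
        est = np.zeros(rec.n_samples)
        wsum = np.zeros(rec.n_samples)
        fits = np.zeros((n_starts, nwin))
        for f0 in params.target_freqs:
            f_hats = np.zeros(n_starts)
            mus = np.zeros(n_starts, dtype=complex)
            sig = np.zeros(n_starts, dtype=bool)
            for wi, s in enumerate(starts):
                xw = x[s : s + nwin] - x[s : s + nwin].mean()
                f_hats[wi], mus[wi], fstat = _harmonic_fit(
                    xw, fs, f0, params.scan_bandwidth, tapers
                )
                sig[wi] = fstat > f_crit
            if not sig.any():
                continue
            amps = np.abs(mus[sig])
            f_ref = float(np.average(f_hats[sig], weights=amps))
            # complex amplitude at f_ref in the absolute time frame
            t_rel = np.arange(nwin) / fs
            phasor = np.exp(-2j * np.pi * f_ref * t_rel)
            mu_ref = np.zeros(n_starts, dtype=complex)
            for wi, s in enumerate(starts):
                xw = x[s : s + nwin] - x[s : s + nwin].mean()
                J = phasor @ (tapers * xw[None, :]).T  # (K,)
                mu_ref[wi] = (J @ h0) / denom_h * np.exp(
                    2j * np.pi * f_ref * (s / fs)
                )
            if params.legacy:
                smoothed = mu_ref  # no cross-window amplitude smoothing
            else:
                w_kernel = kernel * sig[None, :]
                denom = w_kernel.sum(axis=1)
                smoothed = np.where(
                    denom > 0, (w_kernel @ mu_ref) / np.maximum(denom, 1e-300), 0.0
                )
            for wi, s in enumerate(starts):
                # legacy: each window gates itself; otherwise the
                # significance decision is collective -- the smoothed
                # amplitude is already zero where no window in kernel
                # reach was significant, and gaps in an otherwise steady
                # tone would leave it untouched chunk-wise
                if params.legacy and not sig[wi]:
                    continue
                if smoothed[wi] == 0:
                    continue
                t_abs = (s + np.arange(nwin)) / fs
                fits[wi] += 2.0 * np.real(
                    smoothed[wi] * np.exp(2j * np.pi * f_ref * t_abs)
                )
        for wi, s in enumerate(starts):
            if params.legacy:
                lo = s if wi == 0 else max(s + (nwin - step), s)
                est[lo : s + nwin] = fits[wi][lo - s :]
                wsum[lo : s + nwin] = 1.0
            else:
                est[s : s + nwin] += weight * fits[wi]
                wsum[s : s + nwin] += weight
        good = wsum > 0
        artifact[ci, good] = est[good] / wsum[good]
    return artifact


def remove_line_noise(
    rec: Recording, params: LineNoiseParams, return_artifact: bool = False
):
    """Subtract the fitted line-noise sinusoid track from every channel."""
    artifact = estimate_line_artifact(rec, params)
    out = rec.with_data(
        rec.data - artifact,
        f"line_noise: targets {params.target_freqs} Hz"
        + (" (legacy)" if params.legacy else ""),
    )
    if return_artifact:
        return out, artifact
    return out


def linenoise_qc(
    pre: Recording,
    post: Recording,
    line_freq: float,
    offsets: tuple[float, ...] = QC_OFFSETS,
) -> dict[float, float]:
    """Channel-averaged narrowband Pearson r between pre and post at the
    line frequency and neighbouring probes.

    Each probe is extracted with a zero-phase +/-1 Hz band-pass before
    correlating. Low r at the line frequency with high r at neighbours
    indicates selective removal; uniformly high r indicates little line
    noise was present (itself a useful acquisition flag). Probes at or
    above Nyquist are skipped.
    """
    if pre.data.shape != post.data.shape:
        raise ValueError("pre/post recordings differ in shape")
    # discard one second at each end: narrowband filtering rings at the
    # recording edges and would otherwise dominate the comparison
    edge = int(pre.fs) if pre.n_samples > 4 * int(pre.fs) else 0
    sl = slice(edge, pre.n_samples - edge if edge else None)
    out: dict[float, float] = {}
    for off in offsets:
        f = line_freq + off
        if f <= 0 or f + 1.0 >= pre.fs / 2:
            continue
        a = bandpass_narrow(pre.data, pre.fs, f)[:, sl]
        b = bandpass_narrow(post.data, post.fs, f)[:, sl]
        rs = []
        for ci in range(pre.n_channels):
            sa, sb = a[ci].std(), b[ci].std()
            rs.append(
                1.0 if sa == 0 and sb == 0
                else float(np.corrcoef(a[ci], b[ci])[0, 1]) if sa > 0 and sb > 0
                else 0.0
            )
        out[f] = float(np.mean(rs))
    return out
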