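"""Zero-phase Hamming-windowed sinc FIR filtering.

The preliminary band-pass (1-100 Hz for resting/time-frequency data, or
low-pass 100 Hz only in the ERP hand-off mode) runs before bad-channel
detection and artifact correction so those stages see the relevant
frequency range. Kernels are odd-length linear-phase designs applied in a
single pass with group-delay compensation, which is exactly zero-phase.
Edges are reflect-padded by one kernel length to avoid onset transients.

Transition widths default to 1 Hz at the low edge (keeps the 1 Hz edge
sharp) and 5 Hz at the high edge (bounds kernel length); the quoted cutoff
is the half-amplitude point, centred in the transition band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording

#: Hamming-window normalized transition width (Harris): numtaps ~ 3.3 / df
_HAMMING_TW = 3.3


@dataclass(frozen=True)
class FilterSpec:
    """FIR band edges in Hz; ``None`` disables that edge.

    ``low_cut``/``high_cut`` are half-amplitude cutoffs. ``low_tw`` and
    ``high_tw`` are full transition widths in Hz.
    """

    low_cut: float | None = 1.0
    high_cut: float | None = 100.0
    low_tw: float = 1.0
    high_tw: float = 5.0

    def __post_init__(self) -> None:
        if self.low_cut is None and self.high_cut is None:
            raise ValueError("at least one of low_cut/high_cut must be set")
        if (
            self.low_cut is not None
            and self.high_cut is not None
            and self.low_cut >= self.high_cut
        ):
            raise ValueError("low_cut must be below high_cut")


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the odd-length Hamming-windowed sinc kernel for ``spec``."""
    if spec.high_cut is not None and spec.high_cut >= fs / 2:
        raise ValueError(f"high_cut {spec.high_cut} Hz >= Nyquist ({fs / 2} Hz)")
    tw = min(
        spec.low_tw if spec.low_cut is not None else np.inf,
        spec.high_tw if spec.high_cut is not None else np.inf,
    )
    numtaps = int(np.ceil(_HAMMING_TW * fs / tw))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    if spec.low_cut is not None and spec.high_cut is not None:
        cutoff = [spec.low_cut, spec.high_cut]
        pass_zero = False
    elif spec.low_cut is not None:
        cutoff, pass_zero = [spec.low_cut], False
    else:
        cutoff, pass_zero = [spec.high_cut], True
    return sps.firwin(numtaps, cutoff, window="hamming", pass_zero=pass_zero, fs=fs)


def _filter_matrix(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel with reflect padding, zero phase."""
    half = (len(kernel) - 1) // 2
    pad = min(len(kernel), data.shape[1] - 1)
    padded = np.pad(data, [(0, 0), (pad, pad)], mode="reflect")
    out = sps.fftconvolve(padded, kernel[np.newaxis, :], mode="same", axes=1)
    return out[:, pad : pad + data.shape[1]]


def fir_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase FIR filter of every channel; shape preserved."""
    kernel = design_fir(spec, rec.fs)
    out = _filter_matrix(rec.data, kernel)
    stage = (
        f"fir_filter: {spec.low_cut or 'DC'}-{spec.high_cut or 'Nyq'} Hz, "
        f"{len(kernel)} taps"
    )
    return rec.with_data(out, stage)


def bandpass_narrow(data: np.ndarray, fs: float, center: float, half_width: float = 1.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``center`` +/- ``half_width`` Hz.

    Shared helper for the narrowband pre/post correlation QC metrics.
    """
    lo = max(center - half_width, 1e-3)
    hi = min(center + half_width, fs / 2 * 0.999)
    if lo >= hi:
        raise ValueError(f"probe {center} Hz not resolvable at fs {fs}")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)
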