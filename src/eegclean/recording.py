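"""Core in-memory containers: multichannel recordings and electrode montages.

All signal data is held as a channels x samples float64 matrix in microvolts.
Every processing stage returns a new :class:`Recording` with one entry
appended to ``history``, so the provenance of any intermediate file is
recoverable from the object itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class Montage:
    """Electrode positions: label -> (x, y, z) head-centred coordinates.

    Units are arbitrary but must be consistent; positions are normalised to
    the unit sphere by consumers (spline interpolation, REST) that need a
    spherical geometry.
    """

    positions: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for lab, pos in self.positions.items():
            p = np.asarray(pos, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"montage position for {lab!r} is not a finite 3-vector")
            if np.linalg.norm(p) == 0:
                raise ValueError(f"montage position for {lab!r} has zero norm")

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def unit_positions(self, labels: list[str]) -> np.ndarray:
        """Positions for ``labels`` projected onto the unit sphere, (n, 3)."""
        try:
            pos = np.array([self.positions[l] for l in labels], dtype=float)
        except KeyError as e:
            raise KeyError(f"montage is missing a position for channel {e.args[0]!r}") from e
        return pos / np.linalg.norm(pos, axis=1, keepdims=True)


@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names, one per row of ``data``, unique.
    montage : Montage, optional
        Electrode locations. Location-dependent stages (bad-channel
        detection, interpolation, re-referencing) refuse to run without one.
    online_reference : str, optional
        Label of the acquisition reference channel, if its (all-zero) trace
        should be reinstated before re-referencing.
    history : list of str
        One descriptor per processing stage applied so far.
    source : str
        Identifier of the file this recording came from.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    montage: Montage | None = None
    online_reference: str | None = None
    history: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    # -- basic properties -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def has_montage(self) -> bool:
        """Whether location-dependent stages (bad channels, interpolation,
        re-referencing) can run."""
        return self.montage is not None and all(l in self.montage for l in self.labels)

    # -- functional updates ----------------------------------------------
    def with_data(self, data: np.ndarray, stage: str) -> "Recording":
        """Recording with replaced data and ``stage`` appended to history."""
        return replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            history=self.history + [stage],
            labels=list(self.labels),
        )

    def subset(self, labels: list[str], stage: str | None = None) -> "Recording":
        """Recording restricted to ``labels`` (kept in the given order)."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [self.labels.index(l) for l in labels]
        hist = self.history + [stage] if stage else list(self.history)
        return replace(self, data=self.data[idx].copy(), labels=list(labels), history=hist)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Resample to ``target_fs`` with polyphase filtering.

    Anti-alias filtering is applied automatically when downsampling
    (``scipy.signal.resample_poly``). Duration is preserved to within one
    sample. Upsampling is supported (band-limited interpolation).
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec.with_data(rec.data.copy(), f"resample: {rec.fs} Hz (no-op)")
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    new = replace(
        rec,
        data=out,
        fs=float(target_fs),
        history=rec.history + [f"resample: {rec.fs} -> {target_fs} Hz"],
    )
    return new
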