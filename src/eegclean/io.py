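"""Readers and writers for recordings and montages.

Supported formats:

* ``edf`` -- European Data Format, read via :mod:`mne` and converted to
  microvolts. Reading only; there is no EDF writer in this package.
* ``txt`` -- delimited numeric text (channels x samples, or transposed when
  declared), with an optional JSON sidecar ``<file>.json`` carrying ``fs``,
  ``labels``, ``transposed`` and ``online_reference``.
* ``native`` -- a single-file JSON container holding data, sampling rate,
  labels, montage, online reference and processing history; portable and
  lossless to float64 precision.

A montage file is plain text, one channel per line: ``label x y z``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import Montage, Recording

FORMATS = ("edf", "txt", "native")


# ---------------------------------------------------------------------------
# montage files
# ---------------------------------------------------------------------------

def read_montage(path: str | Path) -> Montage:
    """Read a ``label x y z`` montage file (blank lines and # comments ok)."""
    positions: dict[str, tuple[float, float, float]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 'label x y z', got {line!r}")
        try:
            positions[parts[0]] = (float(parts[1]), float(parts[2]), float(parts[3]))
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: non-numeric coordinate") from e
    if not positions:
        raise ValueError(f"montage file {path} is empty")
    return Montage(positions)


def write_montage(montage: Montage, path: str | Path) -> None:
    lines = [f"{lab} {x:.10g} {y:.10g} {z:.10g}" for lab, (x, y, z) in montage.positions.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        source=str(path),
    )


def _sidecar(path: Path) -> dict:
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _read_txt(
    path: Path,
    fs: float | None,
    labels: list[str] | None,
    transposed: bool,
) -> Recording:
    meta = _sidecar(path)
    fs = meta.get("fs", fs)
    labels = meta.get("labels", labels)
    transposed = meta.get("transposed", transposed)
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given (argument or sidecar)")
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric samples") from e
    if transposed:
        data = data.T
    if labels is None:
        labels = [f"ch{i + 1}" for i in range(data.shape[0])]
    return Recording(
        data=data,
        fs=float(fs),
        labels=list(labels),
        online_reference=meta.get("online_reference"),
        source=str(path),
    )


def _read_native(path: Path) -> Recording:
    obj = json.loads(Path(path).read_text())
    montage = Montage({k: tuple(v) for k, v in obj["montage"].items()}) if obj.get("montage") else None
    return Recording(
        data=np.asarray(obj["data"], dtype=np.float64),
        fs=float(obj["fs"]),
        labels=list(obj["labels"]),
        montage=montage,
        online_reference=obj.get("online_reference"),
        history=list(obj.get("history", [])),
        source=str(path),
    )


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    montage_path: str | Path | None = None,
    *,
    fs: float | None = None,
    labels: list[str] | None = None,
    transposed: bool = False,
) -> Recording:
    """Read a recording, attaching a montage if ``montage_path`` is given.

    ``fmt`` is one of ``edf``/``txt``/``native``; inferred from the file
    extension when omitted. Without a montage, location-dependent stages
    (bad-channel detection, interpolation, re-referencing) are unavailable,
    which :meth:`Recording.has_montage` reports.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".edf": "edf", ".json": "native"}.get(path.suffix.lower(), "txt")
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")

    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "native":
        rec = _read_native(path)
    else:
        rec = _read_txt(path, fs, labels, transposed)

    if montage_path is not None:
        montage = read_montage(montage_path)
        missing = [l for l in rec.labels if l not in montage]
        if missing:
            raise ValueError(f"montage lacks positions for channels: {missing}")
        rec.montage = montage
    return rec


def write_recording(rec: Recording, path: str | Path, fmt: str = "native") -> Path:
    """Write a recording as ``native`` (JSON) or ``txt`` (+ JSON sidecar).

    EDF output is not supported; use the native container or delimited text.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "native":
        obj = {
            "fs": rec.fs,
            "labels": rec.labels,
            "online_reference": rec.online_reference,
            "history": rec.history,
            "montage": {k: list(v) for k, v in rec.montage.positions.items()}
            if rec.montage
            else None,
            "data": rec.data.tolist(),
        }
        path.write_text(json.dumps(obj))
    elif fmt == "txt":
        np.savetxt(path, rec.data, fmt="%.10g", delimiter="\t")
        sidecar = {
            "fs": rec.fs,
            "labels": rec.labels,
            "transposed": False,
            "online_reference": rec.online_reference,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    elif fmt == "edf":
        raise NotImplementedError(
            "EDF writing is not supported; choose 'native' or 'txt'"
        )
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path
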