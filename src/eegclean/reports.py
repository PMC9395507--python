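"""Data-quality and pipeline-quality report tables.

Each batch run produces two CSVs in a ``quality_assessment_outputs``
folder, one row per input file:

* the **data quality** table: file length, channel counts, bad-channel
  identities, percent variance retained through wavelet thresholding,
  per-segment interpolation log, and segment counts pre/post rejection;
* the **pipeline quality** table: channel-averaged pre/post correlations
  around the line frequency and at the fixed waveleting probe
  frequencies (broadband plus 0.5, 1, 2, 5, 8, 12, 20, 30, 45, 70 Hz).

Percent metrics are always recomputed from the raw counts, never carried;
metrics of stages that did not run are written as the string sentinel
``NA`` so the CSVs stay parseable. Probes above Nyquist are ``NA`` too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .wavelet import WAVELET_QC_PROBES

NA = "NA"

DATA_QUALITY_COLUMNS = [
    "file",
    "file_length_s",
    "n_user_channels",
    "n_good_channels",
    "pct_good_channels",
    "bad_channel_ids",
    "pct_var_retained_post_wavelet",
    "channels_interpolated_per_segment",
    "n_segments_pre",
    "n_segments_post",
    "pct_segments_post",
    "error",
]


def pipeline_quality_columns(line_probes: list[float]) -> list[str]:
    cols = ["file"]
    cols += [f"r_linenoise_{f:g}Hz" for f in line_probes]
    cols += ["r_wavelet_all"] + [f"r_wavelet_{f:g}Hz" for f in WAVELET_QC_PROBES]
    return cols


@dataclass
class DataQualityRow:
    """One file's data-quality metrics (``None`` -> NA sentinel)."""

    file: str
    file_length_s: float | None = None
    n_user_channels: int | None = None
    n_good_channels: int | None = None
    bad_channel_ids: list[str] = field(default_factory=list)
    pct_var_retained_post_wavelet: float | None = None
    channels_interpolated_per_segment: list[list[str]] | None = None
    n_segments_pre: int | None = None
    n_segments_post: int | None = None
    error: str | None = None

    def to_record(self) -> dict:
        pct_good = (
            round(100.0 * self.n_good_channels / self.n_user_channels, 1)
            if self.n_good_channels is not None and self.n_user_channels
            else None
        )
        pct_seg = (
            100.0 * self.n_segments_post / self.n_segments_pre
            if self.n_segments_post is not None and self.n_segments_pre
            else None
        )
        interp = (
            ";".join(
                f"{i}:{','.join(labs)}"
                for i, labs in enumerate(self.channels_interpolated_per_segment)
                if labs
            )
            if self.channels_interpolated_per_segment is not None
            else None
        )
        rec = {
            "file": self.file,
            "file_length_s": self.file_length_s,
            "n_user_channels": self.n_user_channels,
            "n_good_channels": self.n_good_channels,
            "pct_good_channels": pct_good,
            "bad_channel_ids": ",".join(self.bad_channel_ids) if self.bad_channel_ids else "",
            "pct_var_retained_post_wavelet": self.pct_var_retained_post_wavelet,
            "channels_interpolated_per_segment": interp,
            "n_segments_pre": self.n_segments_pre,
            "n_segments_post": self.n_segments_post,
            "pct_segments_post": pct_seg,
            "error": self.error,
        }
        return {k: (NA if v is None else v) for k, v in rec.items()}


@dataclass
class PipelineQualityRow:
    """One file's pipeline-quality metrics."""

    file: str
    r_prepost_linenoise: dict[float, float] = field(default_factory=dict)
    r_prepost_wavelet: dict[str, float] = field(default_factory=dict)
    line_probes: list[float] = field(default_factory=list)

    def to_record(self) -> dict:
        rec: dict = {"file": self.file}
        for f in self.line_probes:
            v = self.r_prepost_linenoise.get(f)
            rec[f"r_linenoise_{f:g}Hz"] = NA if v is None else v
        v = self.r_prepost_wavelet.get("all")
        rec["r_wavelet_all"] = NA if v is None else v
        for f in WAVELET_QC_PROBES:
            v = self.r_prepost_wavelet.get(f"{f:g}")
            rec[f"r_wavelet_{f:g}Hz"] = NA if v is None or v != v else v
        return rec


def build_reports(
    data_rows: list[DataQualityRow],
    pipeline_rows: list[PipelineQualityRow],
    line_probes: list[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the two report tables with fixed column order."""
    dq = pd.DataFrame(
        [r.to_record() for r in data_rows], columns=DATA_QUALITY_COLUMNS
    )
    pq = pd.DataFrame(
        [r.to_record() for r in pipeline_rows],
        columns=pipeline_quality_columns(line_probes),
    )
    return dq, pq


def write_reports(
    dq: pd.DataFrame, pq: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write both CSVs into ``out_dir / quality_assessment_outputs``.

    Re-running with identical inputs reproduces byte-identical files.
    """
    out = Path(out_dir) / "quality_assessment_outputs"
    out.mkdir(parents=True, exist_ok=True)
    dq_path = out / "data_quality_assessment.csv"
    pq_path = out / "pipeline_quality_assessment.csv"
    dq.to_csv(dq_path, index=False, float_format="%.10g")
    pq.to_csv(pq_path, index=False, float_format="%.10g")
    return dq_path, pq_path
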