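"""Batch runner: sequence every stage over a folder of recordings.

Each file is read, optionally resampled and channel-subset, filtered,
line-noise corrected, bad-channel screened, wavelet corrected, segmented,
optionally within-segment interpolated, segment rejected, bad-channel
interpolated, and re-referenced. Intermediate recordings are saved into
stage-named subfolders so any step can be inspected, and the two quality
CSVs are written to ``quality_assessment_outputs``. A file that fails any
stage is logged and skipped; the batch continues.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .badchannels import detect_bad_channels
from .config import PipelineConfig
from .filters import FilterSpec, fir_filter
from .io import FORMATS, read_recording, write_recording
from .linenoise import LineNoiseParams, linenoise_qc, remove_line_noise
from .recording import Recording, resample
from .reference import rereference, spline_interpolate
from .reports import DataQualityRow, PipelineQualityRow, build_reports, write_reports
from .segments import faster_interpolate_segments, reject_segments, segment_fixed
from .simulate import default_montage
from .wavelet import percent_variance_retained, wavelet_correct, wavelet_qc

logger = logging.getLogger("eegclean")

STAGE_DIRS = [
    "1_filtered_linenoise",
    "2_bad_channels",
    "3_wavelet",
    "4_segmented",
    "5_interpolated",
    "6_rejected",
]


def _save_stage(rec: Recording, out_dir: Path, stage_dir: str, name: str, fmt: str) -> None:
    ext = {"native": ".json", "delimited-text": ".txt"}.get(fmt, ".json")
    wfmt = "txt" if fmt == "delimited-text" else "native"
    write_recording(rec, out_dir / stage_dir / (name + ext), wfmt)


def _segments_to_recording(seg, template: Recording, stage: str) -> Recording:
    data = np.concatenate(list(seg.segments), axis=1) if seg.n_segments else np.zeros((seg.n_channels, 0))
    return Recording(
        data=data,
        fs=seg.fs,
        labels=list(seg.labels),
        montage=seg.montage,
        online_reference=template.online_reference,
        history=template.history + [stage],
        source=template.source,
    )


def line_probe_frequencies(line_freq: float) -> list[float]:
    return [line_freq + off for off in (-5.0, -2.0, -1.0, 0.0, 1.0, 2.0, 5.0)]


def process_file(
    path: Path,
    config: PipelineConfig,
    fmt: str,
    out_dir: Path,
    montage_path: Path | None = None,
) -> tuple[DataQualityRow, PipelineQualityRow]:
    """Run the full stage sequence on one file."""
    name = path.stem
    rec = read_recording(path, fmt, montage_path, fs=config.fs_hint,
                         transposed=config.text_transposed)
    if rec.montage is None and fmt != "edf":
        labels_known = all(l in default_montage().positions for l in rec.labels)
        if labels_known:
            rec.montage = default_montage(rec.labels)
    dq = DataQualityRow(
        file=path.name,
        file_length_s=rec.duration,
        n_user_channels=rec.n_channels,
    )
    pq = PipelineQualityRow(file=path.name, line_probes=line_probe_frequencies(config.line_freq))

    if config.channel_subset:
        rec = rec.subset(config.channel_subset, stage="channel subset")
        dq.n_user_channels = rec.n_channels
    if config.resample_hz:
        rec = resample(rec, config.resample_hz)

    # filtering + line noise
    rec = fir_filter(rec, FilterSpec(config.filter_low, config.filter_high))
    pre_line = rec
    rec = remove_line_noise(
        rec,
        LineNoiseParams(
            target_freqs=[config.line_freq] + list(config.extra_line_freqs),
            legacy=config.legacy_linenoise,
        ),
    )
    pq.r_prepost_linenoise = linenoise_qc(pre_line, rec, config.line_freq)
    _save_stage(rec, out_dir, STAGE_DIRS[0], name, config.output_format)

    # bad channels
    if config.run_bad_channels and rec.has_montage():
        rec, bc_report = detect_bad_channels(rec, config)
        dq.bad_channel_ids = bc_report.union
    dq.n_good_channels = rec.n_channels
    _save_stage(rec, out_dir, STAGE_DIRS[1], name, config.output_format)

    # wavelet artifact correction
    pre_wav = rec
    rec = wavelet_correct(rec, config.wavelet)
    dq.pct_var_retained_post_wavelet = percent_variance_retained(pre_wav, rec)
    pq.r_prepost_wavelet = wavelet_qc(pre_wav, rec)
    _save_stage(rec, out_dir, STAGE_DIRS[2], name, config.output_format)

    # segmentation / interpolation / rejection
    seg = segment_fixed(rec, config.segment_len_s, config.segment_overlap)
    _save_stage(_segments_to_recording(seg, rec, "segmented"), out_dir, STAGE_DIRS[3], name, config.output_format)
    if config.interp_within_segments and seg.montage is not None and seg.n_channels >= 4:
        seg = faster_interpolate_segments(seg)
        dq.channels_interpolated_per_segment = [
            [l for l in labs] for labs in seg.interpolated
        ]
        _save_stage(_segments_to_recording(seg, rec, "interpolated"), out_dir, STAGE_DIRS[4], name, config.output_format)
    seg = reject_segments(seg, config.rejection_method, config)
    dq.n_segments_pre = seg.n_segments_pre
    dq.n_segments_post = seg.n_segments
    rec = _segments_to_recording(seg, rec, f"reject_segments: {config.rejection_method}")
    _save_stage(rec, out_dir, STAGE_DIRS[5], name, config.output_format)

    # whole-file interpolation of detected bad channels, then re-reference
    if dq.bad_channel_ids and rec.montage is not None:
        restored = np.vstack(
            [rec.data, np.zeros((len(dq.bad_channel_ids), rec.n_samples))]
        )
        rec = Recording(
            data=restored,
            fs=rec.fs,
            labels=rec.labels + dq.bad_channel_ids,
            montage=rec.montage,
            online_reference=rec.online_reference,
            history=rec.history,
            source=rec.source,
        )
        rec = spline_interpolate(rec, dq.bad_channel_ids)
    if config.reref_mode != "none" and rec.has_montage():
        rec = rereference(rec, config.reref_mode, config.reref_subset)
    write_recording(
        rec,
        out_dir / "processed" / (name + (".txt" if config.output_format == "delimited-text" else ".json")),
        "txt" if config.output_format == "delimited-text" else "native",
    )
    return dq, pq


def run_batch(
    config: PipelineConfig,
    input_dir: str | Path,
    fmt: str = "txt",
    out_dir: str | Path | None = None,
    montage_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every recording in ``input_dir``; returns the two report
    tables (also written as CSVs)."""
    input_dir = Path(input_dir)
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}")
    ext = {"edf": ".edf", "native": ".json", "txt": ".txt"}[fmt]
    files = sorted(p for p in input_dir.glob(f"*{ext}") if not p.name.endswith(".txt.json"))
    if not files:
        raise FileNotFoundError(f"no {ext} files in {input_dir}")
    out_dir = Path(out_dir) if out_dir else input_dir / "eegclean_output"
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out_dir / "batch.log", level=logging.INFO, force=False
    )

    layout: list[str] | None = None
    dq_rows: list[DataQualityRow] = []
    pq_rows: list[PipelineQualityRow] = []
    for path in files:
        t0 = time.time()
        try:
            probe = read_recording(path, fmt, fs=config.fs_hint,
                                   transposed=config.text_transposed)
            if layout is None:
                layout = list(probe.labels)
            elif set(probe.labels) != set(layout):
                raise ValueError(
                    f"{path.name}: channel layout differs from the batch layout"
                )
            dq, pq = process_file(path, config, fmt, out_dir, montage_path)
            dq_rows.append(dq)
            pq_rows.append(pq)
            logger.info("%s ok (%.1fs)", path.name, time.time() - t0)
        except Exception as e:  # failed file: log and continue
            logger.warning("%s failed: %s", path.name, e)
            dq_rows.append(DataQualityRow(file=path.name, error=str(e)))
            pq_rows.append(
                PipelineQualityRow(
                    file=path.name, line_probes=line_probe_frequencies(config.line_freq)
                )
            )
    dq_tab, pq_tab = build_reports(dq_rows, pq_rows, line_probe_frequencies(config.line_freq))
    write_reports(dq_tab, pq_tab, out_dir)
    return dq_tab, pq_tab
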