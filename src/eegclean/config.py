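"""Run configuration for batch preprocessing.

Defaults follow the pipeline's optimised values for low-density recordings:
coif4 stationary wavelet transform at depth 10 with level-dependent
empirical-Bayes hard thresholding; flatline 5 s, line-noise ratio 2.5 SD,
channel correlation 0.7, spectrum z +/-2.75 for bad channels; 2 SD joint
probability and +/-150 uV for segment rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

VALID_RULES = ("hard", "soft", "median")
VALID_METHODS = ("bayes", "sure", "universal", "minimax")
VALID_NOISE = ("level-dependent", "level-independent")
VALID_REJECTION = ("none", "jointprob", "amplitude", "both")
VALID_REREF = ("none", "average", "subset", "REST")
VALID_OUTPUT = ("delimited-text", "native", "EDF")


@dataclass
class WaveletParams:
    """Wavelet artifact-correction parameter bundle.

    family : wavelet name (orthogonal; default ``coif4``)
    level : decomposition depth; detail band ``l`` spans roughly
        fs/2**(l+1) .. fs/2**l Hz, so depth 10 reaches ~1 Hz at common
        sampling rates. Auto-capped to the padded signal length.
    noise_estimate : ``level-dependent`` fits a separate noise scale and
        threshold per detail level; ``level-independent`` reuses the finest
        level's scale everywhere.
    method : threshold selection (``bayes``, ``sure``, ``universal``,
        ``minimax``).
    rule : how supra/sub-threshold coefficients are treated (``hard``,
        ``soft``, ``median``); ``median`` is only defined for ``bayes``.
    """

    family: str = "coif4"
    level: int = 10
    noise_estimate: str = "level-dependent"
    method: str = "bayes"
    rule: str = "hard"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.noise_estimate not in VALID_NOISE:
            raise ValueError(f"noise_estimate must be one of {VALID_NOISE}")
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}")
        if self.rule not in VALID_RULES:
            raise ValueError(f"rule must be one of {VALID_RULES}")
        if self.rule == "median" and self.method != "bayes":
            raise ValueError("the median rule is specific to the 'bayes' method")


@dataclass
class PipelineConfig:
    """Full batch-run configuration; defaults are the optimised settings."""

    # line noise
    line_freq: float = 60.0
    extra_line_freqs: list[float] = field(default_factory=list)
    legacy_linenoise: bool = False
    # input handling
    resample_hz: float | None = None
    channel_subset: list[str] | None = None
    text_transposed: bool = False
    fs_hint: float | None = None
    # bad channels
    run_bad_channels: bool = True
    legacy_bad_channels: bool = False
    flatline_s: float = 5.0
    lnr_sd: float = 2.5
    min_corr: float = 0.7
    spectrum_z: float = 2.75
    # filtering
    filter_low: float | None = 1.0
    filter_high: float | None = 100.0
    # wavelet
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    # segmentation / rejection
    segment_len_s: float = 2.0
    segment_overlap: float = 0.0
    interp_within_segments: bool = False
    rejection_method: str = "jointprob"
    jp_sd: float = 2.0
    amp_min: float = -150.0
    amp_max: float = 150.0
    require_channels: list[str] | None = None
    # re-referencing
    reref_mode: str = "none"
    reref_subset: list[str] = field(default_factory=list)
    # output
    output_format: str = "delimited-text"

    def __post_init__(self) -> None:
        if isinstance(self.wavelet, dict):
            self.wavelet = WaveletParams(**self.wavelet)
        if self.amp_min >= self.amp_max:
            raise ValueError("amp_min must be < amp_max")
        if self.jp_sd <= 0:
            raise ValueError("jp_sd must be positive")
        if not (0 < self.min_corr < 1):
            raise ValueError("min_corr must be in (0, 1)")
        if self.segment_len_s <= 0:
            raise ValueError("segment_len_s must be positive")
        if not (0 <= self.segment_overlap < 1):
            raise ValueError("segment_overlap must be in [0, 1)")
        if self.rejection_method not in VALID_REJECTION:
            raise ValueError(f"rejection_method must be one of {VALID_REJECTION}")
        if self.reref_mode not in VALID_REREF:
            raise ValueError(f"reref_mode must be one of {VALID_REREF}")
        if self.output_format not in VALID_OUTPUT:
            raise ValueError(f"output_format must be one of {VALID_OUTPUT}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat YAML config file; unknown keys raise."""
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
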