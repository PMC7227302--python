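"""Pipeline configuration.

Every numeric constant used by the pipeline lives here so that a single
YAML/JSON file fully determines a run.  Defaults encode the published
data-handling rules (0.5-8 Hz passband, 125 Hz analysis rate, 60-s
segments, 90% signal-quality gate, 1-h session minimum with a 30-min
grace trim) plus the implementation choices the rules leave open
(filter order, beat-template correlation threshold, traversal step).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidParameterError

#: Severity of lower-extremity obstruction in the synthetic cohort at which
#: the simulator reproduces the qualitative clinical signature (pre-op
#: upper-minus-lower MRF difference highly significant, MRR difference not,
#: normalisation after repair).  Calibrated once against the generator's
#: default between-patient variability and then frozen.
SEVERITY_STAR = 0.20


@dataclass
class PipelineConfig:
    """All tunable constants of the screening pipeline."""

    # --- sampling / filtering -------------------------------------------
    fs_target: float = 125.0          # Hz, analysis rate
    band_low: float = 0.5             # Hz, high-pass edge (baseline drift)
    band_high: float = 8.0            # Hz, low-pass edge (broadband noise)
    filter_order: int = 4             # Butterworth order (per passband edge)

    # --- session assembly ------------------------------------------------
    grace_period_s: float = 1800.0    # trim after a documented site change
    min_session_s: float = 3600.0     # 1-h minimum, applied after trimming
    trim_at_record_start: bool = False  # also trim grace at t=0 (charting data)

    # --- segment selection ----------------------------------------------
    segment_s: float = 60.0           # clean-segment length
    slide_s: float = 10.0             # traversal increment
    sqi_threshold: float = 0.90       # fraction of template-consistent beats
    beat_corr_threshold: float = 0.80  # per-beat template correlation gate
    min_beats_per_segment: int = 10

    # --- beat delineation -------------------------------------------------
    beat_period_min_s: float = 0.25   # 240 bpm, neonatal plausibility band
    beat_period_max_s: float = 1.00   # 60 bpm
    prominence_iqr_factor: float = 0.2

    # --- slope features ---------------------------------------------------
    slope_window_s: float = 0.040     # rolling window for MRR/MRF
    chord_low: float = 0.2            # lower amplitude level for ARR/ARF
    chord_high: float = 0.8           # upper amplitude level for ARR/ARF

    # --- statistics / classifier -----------------------------------------
    alpha_preop: float = 0.01         # significance flag, pre-op group contrast
    alpha_postop: float = 0.05        # significance flag, post-op group contrast
    alpha_paired: float = 0.05        # significance flag, pre-vs-post contrast
    bh_correction: bool = False       # Benjamini-Hochberg across features
    classifier_features: tuple[str, ...] = ("mrf_u", "mrf_l")
    min_specificity: float = 0.90     # operating-point constraint
    lda_ridge: float = 1e-6           # diagonal loading if covariance singular

    # --- simulator calibration -------------------------------------------
    severity_star: float = SEVERITY_STAR

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise InvalidParameterError("require 0 < band_low < band_high")
        if self.fs_target < 125:
            raise InvalidParameterError("analysis rate must be >= 125 Hz")
        if not 0 < self.sqi_threshold <= 1:
            raise InvalidParameterError("sqi_threshold must be in (0, 1]")
        if not 0 < self.chord_low < self.chord_high < 1:
            raise InvalidParameterError("require 0 < chord_low < chord_high < 1")

    # --- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "classifier_features" in d:
            d = {**d, "classifier_features": tuple(d["classifier_features"])}
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        d["classifier_features"] = list(d["classifier_features"])
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
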