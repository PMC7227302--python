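"""Waveform record I/O and session assembly.

A :class:`WaveformRecord` is one continuous single-site PPG recording
with its acquisition metadata.  On disk a record is a two-column CSV
(``time_s, amplitude``) plus a JSON sidecar carrying the metadata; this
plain-text pair is the package's interchange format.

Session assembly applies the study's data-handling rules: after each
documented probe-site change a 30-min grace period is discarded (the
charting of site changes is imprecise), and only sites with at least
1 h of continuous data after trimming are retained for analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AnnotationConflictError,
    FidelityError,
    FormatError,
    MetadataError,
)

logger = logging.getLogger(__name__)

MIN_FS = 125.0  # Hz, fidelity floor for waveform-morphology analysis

SITES = ("upper", "lower")
PHASES = ("pre", "post", "none")


@dataclass
class WaveformRecord:
    """One continuous single-site PPG recording.

    Parameters
    ----------
    samples
        Raw amplitude samples (arbitrary units, finite).
    fs
        Sampling rate in Hz; must be >= 125.
    patient_id, site, phase, group
        Acquisition metadata.  ``phase`` is ``pre``/``post`` for surgical
        patients and ``none`` for controls; ``group`` is ``coa``/``control``
        when known.
    start_time
        Recording start in seconds on the patient's clock (used only for
        overlap detection between records of the same probe).
    site_changes
        Times (s, relative to record start) of documented probe-site
        changes affecting this record; data following each change is
        subject to the grace-period trim.
    ground_truth
        Optional simulator-provided truth (beat trough indices, periods);
        never serialised, used only by tests and oracles.
    """

    samples: np.ndarray
    fs: float
    patient_id: str
    site: str
    phase: str = "none"
    group: str | None = None
    start_time: float = 0.0
    site_changes: tuple[float, ...] = ()
    source_path: str | None = None
    ground_truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("samples must be a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples must be finite")
        if self.fs < MIN_FS:
            raise FidelityError(
                f"sampling rate {self.fs} Hz below the {MIN_FS:.0f} Hz floor"
            )
        if self.site not in SITES:
            raise MetadataError(f"site must be one of {SITES}, got {self.site!r}")
        if self.phase not in PHASES:
            raise MetadataError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self.samples) / self.fs


@dataclass
class SiteSession:
    """A record after the duration gate, with its accept/reject outcome."""

    record: WaveformRecord
    accepted: bool
    rejection_reason: str = "none"  # none | too_short | no_clean_segment


def write_record(record: WaveformRecord, base: str | Path) -> Path:
    """Write ``<base>.csv`` (time_s, amplitude) and ``<base>.json`` sidecar."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"time_s": t, "amplitude": record.samples}).to_csv(
        base.with_suffix(".csv"), index=False, float_format="%.17g"
    )
    sidecar = {
        "patient_id": record.patient_id,
        "site": record.site,
        "phase": record.phase,
        "group": record.group,
        "fs": record.fs,
        "start_time": record.start_time,
        "site_changes": list(record.site_changes),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return base.with_suffix(".csv")


def read_record(path: str | Path, format: str = "csv") -> WaveformRecord:
    """Read a waveform record from ``path`` (CSV + JSON sidecar).

    The CSV time column must be uniformly sampled to within one part in
    10^6 of the sidecar's sampling interval; the sampling rate must be at
    least 125 Hz.
    """
    if format != "csv":
        raise FormatError(
            f"unsupported format {format!r}: this build reads CSV + JSON sidecar"
        )
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MetadataError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("patient_id", "site", "phase", "fs"):
        if key not in meta:
            raise MetadataError(f"sidecar missing required key {key!r}")
    fs = float(meta["fs"])
    if fs < MIN_FS:
        raise FidelityError(f"sidecar fs={fs} Hz below the {MIN_FS:.0f} Hz floor")
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise FormatError("CSV must have columns time_s, amplitude")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.max(np.abs(dt - 1.0 / fs)) > 1e-6 / fs:
            raise FormatError("time axis not uniformly sampled at sidecar fs")
    return WaveformRecord(
        samples=df["amplitude"].to_numpy(float),
        fs=fs,
        patient_id=str(meta["patient_id"]),
        site=meta["site"],
        phase=meta.get("phase", "none"),
        group=meta.get("group"),
        start_time=float(meta.get("start_time", 0.0)),
        site_changes=tuple(meta.get("site_changes", ())),
        source_path=str(path),
    )


def _check_overlaps(records: list[WaveformRecord]) -> None:
    by_probe: dict[tuple[str, str, str], list[WaveformRecord]] = {}
    for r in records:
        by_probe.setdefault((r.patient_id, r.site, r.phase), []).append(r)
    for key, recs in by_probe.items():
        recs = sorted(recs, key=lambda r: r.start_time)
        for a, b in zip(recs, recs[1:]):
            if b.start_time < a.start_time + a.duration:
                raise AnnotationConflictError(
                    f"overlapping annotations for probe {key}"
                )


def assemble_sessions(
    records: list[WaveformRecord],
    grace_period_s: float = 1800.0,
    min_session_s: float = 3600.0,
    trim_at_record_start: bool = False,
) -> list[SiteSession]:
    """Apply grace-period trimming and the minimum-duration gate.

    After each documented site change, ``grace_period_s`` of signal is
    discarded (documentation of the change time is imprecise, so the
    first half hour cannot be trusted to come from the annotated site).
    A record with no documented changes is a single session from t=0;
    ``trim_at_record_start`` additionally applies the trim at t=0, for
    charted clinical data whose recording start is itself an annotation.
    Sessions shorter than ``min_session_s`` after trimming are rejected
    with reason ``too_short``.  Never fabricates samples: retained
    duration <= raw duration.
    """
    _check_overlaps(records)
    sessions: list[SiteSession] = []
    for rec in records:
        cut_s = 0.0
        if rec.site_changes:
            cut_s = max(rec.site_changes) + grace_period_s
        elif trim_at_record_start:
            cut_s = grace_period_s
        cut = min(len(rec.samples), int(round(cut_s * rec.fs)))
        trimmed = replace(
            rec,
            samples=rec.samples[cut:],
            start_time=rec.start_time + cut / rec.fs,
            site_changes=(),
            ground_truth=rec.ground_truth if cut == 0 else None,
        )
        if trimmed.duration < min_session_s:
            logger.info(
                "session rejected (too_short): patient=%s site=%s phase=%s "
                "retained=%.0fs", rec.patient_id, rec.site, rec.phase,
                trimmed.duration,
            )
            sessions.append(SiteSession(trimmed, accepted=False,
                                        rejection_reason="too_short"))
        else:
            sessions.append(SiteSession(trimmed, accepted=True))
    return sessions
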