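"""End-to-end orchestration: records -> patient feature table -> results.

`extract_patient_features` runs the full preprocessing and feature
chain on a set of waveform records and returns the per-patient table
(one row per patient x phase: eight site medians, four upper-minus-lower
deltas, group label) that the inference stage consumes.  A QC table of
per-segment gate decisions is available alongside for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .features import aggregate_site, build_patient_vector, segment_features
from .io import SiteSession, WaveformRecord, assemble_sessions
from .preprocess import (
    bandpass,
    normalize_amplitude,
    resample_to_125,
    select_clean_segments,
)

logger = logging.getLogger(__name__)


@dataclass
class ExtractionResult:
    """Per-patient feature table plus per-segment QC provenance."""

    features: pd.DataFrame
    qc: pd.DataFrame
    rejected_sessions: list[SiteSession] = field(default_factory=list)


def process_session(
    record: WaveformRecord, cfg: PipelineConfig
) -> tuple[dict | None, list[dict]]:
    """One accepted session -> site feature medians (or None) + QC rows."""
    rec = resample_to_125(record)
    rec = bandpass(rec, cfg)
    segments = select_clean_segments(rec, cfg)
    qc_rows = []
    tables = []
    for seg in segments:
        seg = normalize_amplitude(seg)
        table = segment_features(seg, cfg)
        tables.append(table)
        qc_rows.append(
            {
                "patient_id": rec.patient_id,
                "site": rec.site,
                "phase": rec.phase,
                "start_index": seg.start_index,
                "sqi": seg.sqi,
                "n_beats": len(seg.beats),
                "n_valid_beats": len(table),
            }
        )
    site_medians = aggregate_site(tables, cfg) if tables else None
    return site_medians, qc_rows


def extract_patient_features(
    records: list[WaveformRecord],
    cfg: PipelineConfig | None = None,
) -> ExtractionResult:
    """Run session assembly, preprocessing and feature extraction.

    Sessions failing the duration gate or yielding no clean segment are
    logged and excluded; a patient missing one site keeps the present
    site's medians with NaN deltas.
    """
    cfg = cfg or PipelineConfig()
    sessions = assemble_sessions(
        records,
        grace_period_s=cfg.grace_period_s,
        min_session_s=cfg.min_session_s,
        trim_at_record_start=cfg.trim_at_record_start,
    )
    rejected = [s for s in sessions if not s.accepted]
    per_site: dict[tuple[str, str], dict[str, dict]] = {}
    groups: dict[str, str | None] = {}
    qc_rows: list[dict] = []
    for sess in sessions:
        if not sess.accepted:
            continue
        rec = sess.record
        medians, rows = process_session(rec, cfg)
        qc_rows.extend(rows)
        if medians is None:
            sess.accepted = False
            sess.rejection_reason = "no_clean_segment"
            rejected.append(sess)
            logger.info(
                "session rejected (no_clean_segment): patient=%s site=%s phase=%s",
                rec.patient_id, rec.site, rec.phase,
            )
            continue
        key = (rec.patient_id, rec.phase)
        per_site.setdefault(key, {})[rec.site] = medians
        groups[rec.patient_id] = rec.group

    rows = [
        build_patient_vector(
            pid, phase, groups.get(pid) or "unknown",
            sites.get("upper"), sites.get("lower"),
        )
        for (pid, phase), sites in sorted(per_site.items())
    ]
    features = pd.DataFrame(rows)
    qc = pd.DataFrame(
        qc_rows,
        columns=["patient_id", "site", "phase", "start_index", "sqi",
                 "n_beats", "n_valid_beats"],
    )
    return ExtractionResult(features=features, qc=qc, rejected_sessions=rejected)
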