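"""Filtering, resampling, beat delineation and quality gating.

The raw session is reduced to clean 60-s analysis segments in four
steps, mirroring the study's data-handling rules:

1. resample 250 Hz recordings to the 125 Hz analysis rate (polyphase
   decimation with anti-alias filtering);
2. zero-phase 0.5-8 Hz Butterworth band-pass to remove baseline drift
   and high-frequency noise without distorting rise/fall slopes;
3. slide a 60-s window along the session in 10-s increments, delineate
   beats (trough/peak local extrema, neonatal plausibility band on the
   period), and score each window with a beat-template-correlation
   signal quality index (SQI);
4. admit non-overlapping windows with SQI >= 90%, then rescale each
   beat to trough 0, peak 1 so that slope features are device- and
   gain-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .errors import (
    SegmentUnusableError,
    TooShortError,
    UnsupportedRateError,
)
from .io import WaveformRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Beat:
    """One delineated beat: trough -> peak -> next trough."""

    trough_index: int
    peak_index: int
    next_trough_index: int
    fs: float
    template_correlation: float = float("nan")

    def __post_init__(self) -> None:
        if not self.trough_index < self.peak_index < self.next_trough_index:
            raise ValueError("require trough < peak < next trough")

    @property
    def period(self) -> float:
        """Beat period in seconds."""
        return (self.next_trough_index - self.trough_index) / self.fs

    @property
    def instantaneous_hr(self) -> float:
        """Instantaneous heart rate in beats per second."""
        return 1.0 / self.period


@dataclass
class CleanSegment:
    """A 60-s window that passed the SQI gate, with delineated beats.

    ``samples`` hold the band-passed (and, after
    :func:`normalize_amplitude`, per-beat rescaled) signal; ``start_index``
    is the window's offset into the session for provenance.
    """

    samples: np.ndarray
    fs: float
    start_index: int
    sqi: float
    beats: list[Beat]
    normalized: bool = False


def bandpass(record: WaveformRecord, cfg: PipelineConfig | None = None) -> WaveformRecord:
    """Zero-phase Butterworth band-pass (default 0.5-8 Hz).

    Forward-backward filtering keeps rise and fall slopes undistorted
    (a causal filter would bias them asymmetrically).  DC and sub-0.5 Hz
    baseline wander are removed; the pulse band (1-4 Hz fundamentals)
    passes essentially unattenuated.
    """
    cfg = cfg or PipelineConfig()
    # settling requirement: ten time constants of the slowest (high-pass) pole
    min_dur = 10.0 / (2 * np.pi * cfg.band_low)
    if record.duration < min_dur:
        raise TooShortError(
            f"record of {record.duration:.1f}s shorter than {min_dur:.1f}s "
            "filter settling time"
        )
    sos = signal.butter(
        cfg.filter_order,
        [cfg.band_low, cfg.band_high],
        btype="bandpass",
        fs=record.fs,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, record.samples)
    return replace(record, samples=filtered)


def resample_to_125(record: WaveformRecord) -> WaveformRecord:
    """Resample a 250 Hz record to 125 Hz; pass 125 Hz through unchanged.

    Decimation is polyphase with an anti-alias low-pass; only the two
    clinically used rates are supported.
    """
    if record.fs == 125:
        return record
    if record.fs != 250:
        raise UnsupportedRateError(
            f"only 125 and 250 Hz supported, got {record.fs} Hz"
        )
    down = signal.resample_poly(record.samples, 1, 2)
    truth = None
    if record.ground_truth is not None:
        truth = dict(record.ground_truth)
        truth["trough_indices"] = truth["trough_indices"] // 2
    return replace(record, samples=down, fs=125.0, ground_truth=truth)


def delineate_beats(x: np.ndarray, fs: float, cfg: PipelineConfig | None = None) -> list[Beat]:
    """Find alternating trough/peak beat boundaries in a band-passed signal.

    Troughs are local minima with prominence >= ``prominence_iqr_factor``
    times the segment's interquartile amplitude; each beat's peak is the
    maximum between consecutive troughs.  Beats with period outside the
    neonatal plausibility band (default 0.25-1.0 s) are discarded.
    Raises :class:`SegmentUnusableError` if fewer than 10 beats survive
    in the window.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(x, float)
    q75, q25 = np.percentile(x, [75, 25])
    prominence = cfg.prominence_iqr_factor * (q75 - q25)
    if prominence <= 0:
        raise SegmentUnusableError("flat signal: no beats")
    troughs, _ = signal.find_peaks(
        -x, prominence=prominence, distance=max(1, int(cfg.beat_period_min_s * fs))
    )
    beats: list[Beat] = []
    for t0, t1 in zip(troughs, troughs[1:]):
        period = (t1 - t0) / fs
        if not cfg.beat_period_min_s <= period <= cfg.beat_period_max_s:
            continue
        peak = t0 + int(np.argmax(x[t0:t1]))
        if peak == t0 or peak == t1:
            continue
        beats.append(Beat(int(t0), int(peak), int(t1), fs))
    if len(beats) < cfg.min_beats_per_segment:
        raise SegmentUnusableError(
            f"only {len(beats)} plausible beats in window"
        )
    return beats


def _beat_matrix(x: np.ndarray, beats: list[Beat], length: int) -> np.ndarray:
    """Each beat linearly time-warped to ``length`` samples (rows)."""
    grid = np.linspace(0.0, 1.0, length)
    out = np.empty((len(beats), length))
    for i, b in enumerate(beats):
        seg = x[b.trough_index : b.next_trough_index + 1]
        out[i] = np.interp(grid, np.linspace(0.0, 1.0, len(seg)), seg)
    return out


def _corr_rows(mat: np.ndarray, template: np.ndarray) -> np.ndarray:
    m = mat - mat.mean(axis=1, keepdims=True)
    t = template - template.mean()
    denom = np.sqrt((m**2).sum(axis=1) * (t**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (m @ t) / denom
    return np.where(np.isfinite(r), r, 0.0)


def compute_sqi(
    beats: list[Beat], x: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[float, list[Beat]]:
    """Template-correlation signal quality index.

    Every beat is linearly time-warped to the median beat length and
    Pearson-correlated with the mean-beat template.  The template is
    computed twice: first from all beats, then excluding beats whose
    first-pass correlation fell below the threshold (so artifacts do not
    contaminate the template).  The SQI is the fraction of beats whose
    final correlation meets the threshold; it is invariant to overall
    amplitude scaling.
    """
    cfg = cfg or PipelineConfig()
    if len(beats) < cfg.min_beats_per_segment:
        raise SegmentUnusableError("need >= 10 beats for an SQI")
    lengths = [b.next_trough_index - b.trough_index + 1 for b in beats]
    target = int(np.median(lengths))
    mat = _beat_matrix(x, beats, target)

    template = mat.mean(axis=0)
    corr = _corr_rows(mat, template)
    good = corr >= cfg.beat_corr_threshold
    if good.any():  # second pass with artifact-free template
        template = mat[good].mean(axis=0)
        corr = _corr_rows(mat, template)
    sqi = float(np.mean(corr >= cfg.beat_corr_threshold))
    annotated = [
        replace(b, template_correlation=float(c)) for b, c in zip(beats, corr)
    ]
    return sqi, annotated


def select_clean_segments(
    record: WaveformRecord, cfg: PipelineConfig | None = None
) -> list[CleanSegment]:
    """Traverse a band-passed session and emit clean 60-s segments.

    The window slides in ``slide_s`` increments; acceptance is greedy and
    non-overlapping (after accepting a window, traversal resumes at its
    end) so no beat is counted twice in the median-of-medians.  A window
    is accepted when it has >= 10 plausible beats and SQI >= the 90%
    gate.  Returns an empty list when no window qualifies (the caller
    rejects the session with reason ``no_clean_segment``).
    """
    cfg = cfg or PipelineConfig()
    x = record.samples
    n = int(round(cfg.segment_s * record.fs))
    step = int(round(cfg.slide_s * record.fs))
    segments: list[CleanSegment] = []
    i = 0
    while i + n <= len(x):
        window = x[i : i + n]
        try:
            beats = delineate_beats(window, record.fs, cfg)
            sqi, beats = compute_sqi(beats, window, cfg)
        except SegmentUnusableError:
            i += step
            continue
        if sqi >= cfg.sqi_threshold:
            segments.append(
                CleanSegment(window.copy(), record.fs, i, sqi, beats)
            )
            i += n
        else:
            i += step
    logger.info(
        "segments: patient=%s site=%s phase=%s accepted=%d",
        record.patient_id, record.site, record.phase, len(segments),
    )
    return segments


def normalize_amplitude(segment: CleanSegment) -> CleanSegment:
    """Rescale each beat to trough 0, peak 1.

    Per-beat min/max normalisation makes every downstream slope feature
    independent of acquisition device gain and DC offset.  Beats with
    zero amplitude (peak == trough) are discarded.  The single boundary
    sample two consecutive beats share is written on the later beat's
    scale; feature extraction re-normalises each beat slice exactly, so
    this one-sample overlap never reaches the features.
    """
    orig = np.asarray(segment.samples, float)
    x = orig.copy()
    kept: list[Beat] = []
    for b in segment.beats:
        seg = orig[b.trough_index : b.next_trough_index + 1]
        lo, hi = seg.min(), seg.max()
        if hi <= lo:
            continue
        x[b.trough_index : b.next_trough_index + 1] = (seg - lo) / (hi - lo)
        kept.append(b)
    return CleanSegment(
        x, segment.fs, segment.start_index, segment.sqi, kept, normalized=True
    )
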