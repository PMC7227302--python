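"""Per-beat slope features and their aggregation.

Four features summarise each normalised beat (trough 0, peak 1):

- **ARR / ARF** (average rate of rise / fall): the chord slope between
  the 20% and 80% amplitude crossings on the upslope / downslope, with
  crossing times found by linear interpolation between samples.
- **MRR / MRF** (maximum rate of rise / fall): the extreme endpoint
  slope over all 40-ms windows slid one sample at a time along the
  beat.

Raw slopes (normalised amplitude per second) are divided by the beat's
instantaneous heart rate (beats/s), yielding normalised amplitude per
cardiac cycle; this removes the near-linear heart-rate dependence of the
raw slopes and makes a time-stretched copy of a beat score identically.

Aggregation is a median of medians: per 60-s segment the median over
valid beats, per site the median over segment medians (beats in noisy
segments never dominate a site summary).  Per-patient vectors carry the
upper- and lower-extremity summaries plus the upper-minus-lower deltas:
obstruction of the descending aorta flattens lower-extremity falling
slopes while leaving the upper extremity as an internal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InvalidParameterError
from .preprocess import Beat, CleanSegment

FEATURES = ("arr", "arf", "mrr", "mrf")

#: Columns of the per-patient feature table consumed by the inference stage.
SITE_COLUMNS = tuple(f"{f}_{s}" for f in FEATURES for s in ("u", "l"))
DELTA_COLUMNS = tuple(f"d_{f}" for f in FEATURES)


class BeatInvalidError(InvalidParameterError):
    """Beat excluded from medians (no crossing, or shorter than window)."""


@dataclass(frozen=True)
class BeatSlopeFeatures:
    """Heart-rate-normalised slope features of one beat."""

    arr: float
    arf: float
    mrr: float
    mrf: float
    hr: float  # beats/s


def _cross_up(v: np.ndarray, level: float, first: bool) -> float | None:
    """Interpolated index of an upward crossing of ``level``; None if absent."""
    idx = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    if len(idx) == 0:
        return None
    i = idx[0] if first else idx[-1]
    return i + (level - v[i]) / (v[i + 1] - v[i])


def _cross_down(v: np.ndarray, level: float) -> float | None:
    """Interpolated index of the first downward crossing of ``level``."""
    idx = np.nonzero((v[:-1] >= level) & (v[1:] < level))[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    return i + (v[i] - level) / (v[i] - v[i + 1])


def average_rates(
    beat_samples: np.ndarray,
    peak_offset: int,
    fs: float,
    cfg: PipelineConfig | None = None,
) -> tuple[float, float]:
    """Chord slopes between the 20% and 80% crossings (raw, per second).

    ``beat_samples`` is one normalised beat (trough 0, peak 1) and
    ``peak_offset`` the peak's index within it.  The upslope chord uses
    the last upward 20% crossing and the first upward 80% crossing
    before the peak; the downslope chord uses the first downward 80% and
    first downward 20% crossings after the peak.  A beat whose falling
    limb never reaches the 20% level before the next trough (high
    dicrotic plateau) is invalid.
    """
    cfg = cfg or PipelineConfig()
    lo, hi = cfg.chord_low, cfg.chord_high
    rise = beat_samples[: peak_offset + 1]
    fall = beat_samples[peak_offset:]
    t20 = _cross_up(rise, lo, first=False)
    t80 = _cross_up(rise, hi, first=True)
    if t20 is None or t80 is None or t80 <= t20:
        raise BeatInvalidError("no 20-80% upslope chord")
    f80 = _cross_down(fall, hi)
    f20 = _cross_down(fall, lo)
    if f80 is None or f20 is None or f20 <= f80:
        raise BeatInvalidError("falling limb never reaches the 20% level")
    arr_raw = (hi - lo) / ((t80 - t20) / fs)
    arf_raw = (lo - hi) / ((f20 - f80) / fs)
    return arr_raw, arf_raw


def max_rates(
    beat_samples: np.ndarray,
    fs: float,
    window_s: float = 0.040,
) -> tuple[float, float]:
    """Extreme endpoint slopes over all sliding windows (raw, per second).

    The window is ``round(window_s * fs)`` samples (5 at 125 Hz) and
    slides one sample at a time; the slope of window ``i`` is
    ``(x[i+w] - x[i]) / (w/fs)``.  Returns (max, min) over all windows.
    """
    w = int(round(window_s * fs))
    if w < 2:
        raise InvalidParameterError("window must span >= 2 samples")
    x = np.asarray(beat_samples, float)
    if len(x) <= w:
        raise BeatInvalidError("beat shorter than the slope window")
    slopes = (x[w:] - x[:-w]) * (fs / w)
    return float(slopes.max()), float(slopes.min())


def hr_normalize(
    arr_raw: float, arf_raw: float, mrr_raw: float, mrf_raw: float, hr: float
) -> BeatSlopeFeatures:
    """Divide raw slopes by the instantaneous heart rate (beats/s).

    Equivalent to rescaling the beat's time axis to one cardiac cycle:
    a self-similar beat at any heart rate maps to the same features.
    """
    if hr <= 0:
        raise InvalidParameterError("heart rate must be positive")
    return BeatSlopeFeatures(
        arr=arr_raw / hr,
        arf=arf_raw / hr,
        mrr=mrr_raw / hr,
        mrf=mrf_raw / hr,
        hr=hr,
    )


def beat_features(
    segment: CleanSegment,
    beat: Beat,
    cfg: PipelineConfig | None = None,
) -> BeatSlopeFeatures:
    """All four HR-normalised features of one beat of a clean segment."""
    cfg = cfg or PipelineConfig()
    x = np.asarray(segment.samples[beat.trough_index : beat.next_trough_index + 1], float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise BeatInvalidError("zero-amplitude beat")
    x = (x - lo) / (hi - lo)  # no-op if the segment is already normalised
    peak_offset = beat.peak_index - beat.trough_index
    arr_raw, arf_raw = average_rates(x, peak_offset, segment.fs, cfg)
    mrr_raw, mrf_raw = max_rates(x, segment.fs, cfg.slope_window_s)
    return hr_normalize(arr_raw, arf_raw, mrr_raw, mrf_raw, beat.instantaneous_hr)


def segment_features(
    segment: CleanSegment, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-beat feature table for one segment (invalid beats dropped)."""
    rows = []
    for b in segment.beats:
        try:
            f = beat_features(segment, b, cfg)
        except BeatInvalidError:
            continue
        rows.append({"arr": f.arr, "arf": f.arf, "mrr": f.mrr, "mrf": f.mrf,
                     "hr": f.hr})
    return pd.DataFrame(rows, columns=["arr", "arf", "mrr", "mrf", "hr"])


def aggregate_site(
    segment_tables: list[pd.DataFrame],
    cfg: PipelineConfig | None = None,
) -> dict[str, float] | None:
    """Median of per-segment medians for each feature.

    Both levels use the midpoint convention for even counts
    (``numpy.median``).  Returns ``None`` when no segment has enough
    valid beats, in which case the patient is dropped from analyses that
    need this site.
    """
    cfg = cfg or PipelineConfig()
    per_segment = [
        t[list(FEATURES)].median()
        for t in segment_tables
        if len(t) >= cfg.min_beats_per_segment
    ]
    if not per_segment:
        return None
    medians = pd.concat(per_segment, axis=1).T.median()
    return {f: float(medians[f]) for f in FEATURES}


def build_patient_vector(
    patient_id: str,
    phase: str,
    group: str,
    upper: dict[str, float] | None,
    lower: dict[str, float] | None,
) -> dict:
    """One row of the patient feature table: site values plus deltas.

    Deltas are upper minus lower for each feature; if either site is
    missing, the present site's values are kept and the deltas are NaN.
    """
    row: dict = {"patient_id": patient_id, "phase": phase, "group": group}
    for f in FEATURES:
        u = upper[f] if upper else math.nan
        l = lower[f] if lower else math.nan
        row[f"{f}_u"] = u
        row[f"{f}_l"] = l
        row[f"d_{f}"] = u - l
    return row
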