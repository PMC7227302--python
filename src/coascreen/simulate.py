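"""Synthetic multi-site neonatal PPG generator.

Clinical PPG from neonates with coarctation of the aorta (COA) is not
publicly available, so this module generates waveform cohorts with known
ground truth.  The pulse model is phenomenological: a raised-cosine
systolic upstroke over a fixed fraction of the beat period, followed by
an exponential diastolic decay with a Gaussian dicrotic bump.  A
coarctation ``severity`` knob acts only on lower-extremity beats —
obstruction proximal to the descending aorta slows run-off distal to it
(the echocardiographic "diastolic tailing" pattern) — by stretching the
decay time constant by ``(1 + s)`` and mildly damping the upstroke slope
by ``1 / (1 + 0.1 s)``.  The magnitude of the maximum 40-ms falling
slope of a lower-extremity beat is therefore monotonically decreasing in
severity, while upper-extremity beats are unaffected.

Records add per-beat heart-rate variability, sinusoidal baseline wander
below the analysis passband, Gaussian broadband noise, and Poisson-placed
clipped-noise motion artifacts, so every downstream quality gate is
exercised.  Between-patient and between-site morphology variability is
log-normal on the decay constant and upstroke rate: the decay constant
(peripheral run-off) is tightly shared between a patient's two sites,
while the upstroke rate (contractility, probe coupling) varies more site
to site — which is what makes the upper-minus-lower fall-slope difference
a low-variance screening signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import WaveformRecord

__all__ = [
    "PulseModelParams",
    "CohortConfig",
    "synth_beat",
    "synth_record",
    "synth_cohort",
]


@dataclass(frozen=True)
class PulseModelParams:
    """Beat-morphology parameters of the phenomenological pulse model.

    Defaults are neonatal: heart rate 140 +/- 15 bpm, ~0.13 s systolic
    rise at 140 bpm, 0.15 s diastolic decay constant, modest dicrotic
    bump mid-diastole.
    """

    heart_rate_mean: float = 140.0       # bpm
    heart_rate_sd: float = 15.0          # bpm, beat-to-beat
    systolic_rise_fraction: float = 0.30  # fraction of beat period
    decay_time_constant: float = 0.15    # s
    dicrotic_amplitude: float = 0.12     # fraction of systolic amplitude
    dicrotic_delay_fraction: float = 0.45  # fraction of beat period
    amplitude_scale: float = 1.0         # arbitrary units

    def __post_init__(self) -> None:
        if not 0 < self.systolic_rise_fraction < 1:
            raise InvalidParameterError("systolic_rise_fraction must be in (0,1)")
        if not 0 <= self.dicrotic_amplitude < 1:
            raise InvalidParameterError("dicrotic_amplitude must be in [0,1)")
        if self.heart_rate_mean <= 0:
            raise InvalidParameterError("heart_rate_mean must be positive")
        if self.decay_time_constant <= 0:
            raise InvalidParameterError("decay_time_constant must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, noise conditions and reproducibility seed.

    ``severity`` applies to lower-extremity, pre-operative COA records
    only; post-operative and control records are generated at severity 0
    so that a repaired or unobstructed circulation has exchangeable
    upper/lower morphology.  The ``*_cv`` fields are log-normal
    coefficients of variation of the pulse-model decay constant and
    upstroke rate, at the patient level (shared by both sites) and the
    site level (independent per record).
    """

    n_coa: int = 18
    n_control: int = 18
    severity: float = 0.20
    noise_sd: float = 0.02            # fraction of pulse amplitude
    drift_amplitude: float = 0.3      # fraction of pulse amplitude
    drift_frequency: float = 0.2      # Hz, below the 0.5 Hz passband edge
    artifact_rate: float = 1.0        # artifacts per minute
    fs: float = 125.0                 # Hz
    duration_per_site: float = 4500.0  # s (75 min; exceeds the 1-h gate)
    seed: int = 0
    phases: tuple[str, ...] = ("pre", "post")
    tau_patient_cv: float = 0.10
    tau_site_cv: float = 0.025
    rise_patient_cv: float = 0.10
    rise_site_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.fs not in (125.0, 250.0, 125, 250):
            raise InvalidParameterError("fs must be 125 or 250 Hz")
        if self.duration_per_site < 60:
            raise InvalidParameterError("duration_per_site must be >= 60 s")
        if self.severity < 0:
            raise InvalidParameterError("severity must be >= 0")
        if self.n_coa < 0 or self.n_control < 0:
            raise InvalidParameterError("cohort sizes must be >= 0")
        for name in ("noise_sd", "drift_amplitude", "artifact_rate"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def synth_beat(
    params: PulseModelParams,
    beat_period: float,
    severity: float = 0.0,
    site: str = "upper",
    fs: float = 125.0,
) -> np.ndarray:
    """Sample one beat of the pulse model at ``fs``.

    The beat rises from 0 to its maximum over the (possibly
    severity-damped) systolic rise time, then decays exponentially with
    the (possibly severity-stretched) time constant, with a Gaussian
    dicrotic bump superposed on the decay.  Severity affects the beat
    only when ``site == "lower"``.
    """
    if beat_period <= 0:
        raise InvalidParameterError("beat_period must be positive")
    if severity < 0:
        raise InvalidParameterError("severity must be >= 0")
    if site not in ("upper", "lower"):
        raise InvalidParameterError(f"site must be upper|lower, got {site!r}")

    tau = params.decay_time_constant
    rise_time = params.systolic_rise_fraction * beat_period
    if site == "lower":
        tau *= 1.0 + severity
        # mild secondary damping of the upstroke: obstruction chiefly slows
        # diastolic run-off; the systolic leak must stay an order weaker or
        # the rise-slope features would separate the groups as strongly as
        # the fall-slope ones, which is not the clinical pattern.
        rise_time *= 1.0 + 0.1 * severity  # slope damped by 1/(1+0.1s)
    rise_time = min(rise_time, 0.9 * beat_period)

    n = int(round(beat_period * fs))
    t = np.arange(n) / fs
    x = np.empty(n)
    rising = t < rise_time
    # raised-cosine upstroke: monotone, sigmoid-shaped, peak slope pi/(2*Tr)
    x[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / rise_time))
    # exponential decay, baseline-anchored so the beat ends exactly at 0:
    # x = (exp(-u/tau) - C) / (1 - C), an affine image of exp(-u/tau).
    # Without the anchor the truncated exponential leaves a step at the
    # beat boundary whose height grows with tau, which would corrupt the
    # maximum-fall-slope features severity is meant to drive.
    residual = np.exp(-(beat_period - rise_time) / tau)
    x[~rising] = (np.exp(-(t[~rising] - rise_time) / tau) - residual) / (
        1.0 - residual
    )
    if params.dicrotic_amplitude > 0:
        # dicrotic bump anchored to end of systole, mid-diastole by default
        diastole = beat_period - rise_time
        centre = rise_time + params.dicrotic_delay_fraction * diastole
        width = 0.10 * diastole
        bump = params.dicrotic_amplitude * np.exp(
            -0.5 * ((t - centre) / width) ** 2
        )
        x[~rising] += bump[~rising]  # bump rides on the decay only
    return params.amplitude_scale * x


def _record_rng(seed: int, patient_id: str, site: str, phase: str) -> np.random.Generator:
    """Deterministic per-record generator derived from the cohort seed."""
    key = zlib.crc32(f"{patient_id}|{site}|{phase}".encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key)))


def synth_record(
    config: CohortConfig,
    params: PulseModelParams,
    patient_id: str,
    site: str,
    phase: str = "none",
    severity: float = 0.0,
    group: str | None = None,
    rng: np.random.Generator | None = None,
) -> WaveformRecord:
    """Generate one continuous single-site recording.

    Beats are concatenated with per-beat period drawn from the normal
    heart-rate distribution (clipped to 90-220 bpm); sinusoidal baseline
    wander, Gaussian broadband noise and Poisson-placed clipped-noise
    artifacts (0.5-2 s each) are added on top.  The record carries the
    generator's ground-truth beat boundaries for oracle tests.
    """
    if rng is None:
        rng = _record_rng(config.seed, patient_id, site, phase)
    fs = float(config.fs)
    n_total = int(round(config.duration_per_site * fs))

    pieces: list[np.ndarray] = []
    trough_indices = [0]
    periods: list[float] = []
    n_done = 0
    while n_done < n_total:
        hr = rng.normal(params.heart_rate_mean, params.heart_rate_sd)
        hr = float(np.clip(hr, 90.0, 220.0))
        period = 60.0 / hr
        beat = synth_beat(params, period, severity=severity, site=site, fs=fs)
        pieces.append(beat)
        n_done += len(beat)
        trough_indices.append(n_done)
        periods.append(len(beat) / fs)
    x = np.concatenate(pieces)[:n_total]

    amp = params.amplitude_scale
    if config.drift_amplitude > 0:
        t = np.arange(n_total) / fs
        phase0 = rng.uniform(0, 2 * np.pi)
        x = x + config.drift_amplitude * amp * np.sin(
            2 * np.pi * config.drift_frequency * t + phase0
        )
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd * amp, n_total)
    if config.artifact_rate > 0:
        n_art = rng.poisson(config.artifact_rate * config.duration_per_site / 60.0)
        for _ in range(n_art):
            length = int(rng.uniform(0.5, 2.0) * fs)
            start = rng.integers(0, max(1, n_total - length))
            burst = rng.normal(0.0, 3.0 * amp, length)
            x[start : start + length] = np.clip(burst, -2.5 * amp, 2.5 * amp)

    truth = {
        "trough_indices": np.array(trough_indices[:-1], dtype=int),
        "periods": np.array(periods),
        "severity": severity,
    }
    return WaveformRecord(
        samples=x,
        fs=fs,
        patient_id=patient_id,
        site=site,
        phase=phase,
        group=group,
        ground_truth=truth,
    )


def _jitter_params(
    params: PulseModelParams,
    rng: np.random.Generator,
    tau_cv: float,
    rise_cv: float,
) -> PulseModelParams:
    """Log-normal morphology jitter on decay constant and rise fraction."""
    tau = params.decay_time_constant * np.exp(rng.normal(0.0, tau_cv))
    rise = params.systolic_rise_fraction * np.exp(rng.normal(0.0, rise_cv))
    return replace(
        params,
        decay_time_constant=float(tau),
        systolic_rise_fraction=float(np.clip(rise, 0.05, 0.6)),
    )


def synth_cohort(
    config: CohortConfig,
    params: PulseModelParams | None = None,
) -> tuple[list[WaveformRecord], pd.DataFrame]:
    """Generate a full cohort of records plus its ground-truth label table.

    Each COA patient contributes upper+lower records per phase in
    ``config.phases`` (pre-operative at ``config.severity``, post-operative
    at severity 0); each control contributes one upper+lower session
    (phase ``none``, severity 0).  Patient-level morphology jitter is
    shared across a patient's records; site-level jitter is drawn per
    record.
    """
    if params is None:
        params = PulseModelParams()
    records: list[WaveformRecord] = []
    labels: list[dict] = []

    def make_patient(pid: str, group: str, phases: tuple[str, ...]) -> None:
        prng = _record_rng(config.seed, pid, "patient", "jitter")
        p_pat = _jitter_params(
            params, prng, config.tau_patient_cv, config.rise_patient_cv
        )
        for phase in phases:
            for site in ("upper", "lower"):
                srng = _record_rng(config.seed, pid, site, phase)
                p_site = _jitter_params(
                    p_pat, srng, config.tau_site_cv, config.rise_site_cv
                )
                sev = (
                    config.severity
                    if group == "coa" and phase == "pre" and site == "lower"
                    else 0.0
                )
                records.append(
                    synth_record(
                        config, p_site, pid, site, phase,
                        severity=sev, group=group, rng=srng,
                    )
                )
            labels.append({"patient_id": pid, "group": group, "phase": phase})

    for i in range(config.n_coa):
        make_patient(f"coa{i:02d}", "coa", tuple(config.phases))
    for i in range(config.n_control):
        make_patient(f"ctl{i:02d}", "control", ("none",))
    return records, pd.DataFrame(labels)
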