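"""Rule-based ST-elevation (STEMI) criteria comparator.

Pipeline: detect R peaks on lead II, build a per-lead median beat, measure
ST deviation at a configurable offset past the J point relative to the PR
baseline, then apply the guideline thresholds — new ST elevation in at least
two contiguous leads of 0.1 mV, except V2–V3 where the threshold is 0.25 mV
for men under 40, 0.2 mV for men 40 and over, and 0.15 mV for women
(1 mm = 0.1 mV calibration).  The criteria are undefined for left bundle
branch block, left ventricular hypertrophy and ventricular pacing; such
ECGs receive a ``not_applicable`` verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .types import (
    EcgSignal,
    InputError,
    MeasurementError,
    PatientCase,
    TWELVE_LEADS,
)

# Contiguity groups (standard clinical convention).
CONTIGUOUS_GROUPS: dict[str, tuple[str, ...]] = {
    "inferior": ("II", "III", "aVF"),
    "lateral": ("I", "aVL", "V5", "V6"),
    "anterior": ("V1", "V2", "V3", "V4"),
}

# Median-beat window around the R peak.
BEAT_WINDOW_S = (-0.300, 0.500)
# PR-segment baseline window relative to R.
PR_WINDOW_S = (-0.120, -0.060)
# Search range for the J point (QRS offset) after R.
J_SEARCH_S = (0.015, 0.160)

DEFAULT_J_OFFSET_MS = 60.0


def st_elevation_threshold(lead: str, age: float, sex: str) -> float:
    """Guideline ST-elevation threshold in mV for one lead.

    V2–V3 use sex- and age-specific cut points; all other leads use 0.1 mV.
    """
    if lead not in TWELVE_LEADS:
        raise InputError(f"unknown lead {lead!r}")
    if lead in ("V2", "V3"):
        if sex == "male":
            return 0.25 if age < 40 else 0.20
        return 0.15
    return 0.10


@dataclass
class MedianBeat:
    samples: np.ndarray          # (n_leads, window) mV
    lead_names: tuple[str, ...]
    sampling_rate_hz: float
    r_peak_index: int
    baseline_mv: np.ndarray      # per-lead PR reference
    n_beats_used: int

    def __post_init__(self) -> None:
        if self.n_beats_used < 3:
            raise MeasurementError(
                f"median beat needs >= 3 beats, got {self.n_beats_used}"
            )


@dataclass
class StMeasurements:
    st_mv: dict[str, float]
    j_offset_ms: float
    j_index: int = 0


@dataclass
class StemiVerdict:
    verdict: str                       # positive | negative | not_applicable
    leads_meeting: frozenset[str] = frozenset()
    contiguous_group: Optional[str] = None

    @property
    def positive(self) -> bool:
        return self.verdict == "positive"


def detect_r_peaks(signal: EcgSignal, lead: str = "II") -> np.ndarray:
    """Indices of R peaks on one lead (amplitude + refractory peak picker)."""
    x = signal.lead(lead)
    amp = float(np.max(x) - np.min(x))
    if amp < 0.2:  # flatline or near-flat: no QRS of plausible size
        raise MeasurementError("no detectable QRS activity")
    height = np.min(x) + 0.6 * amp
    min_dist = max(1, int(round(0.25 * signal.sampling_rate_hz)))
    peaks, _ = find_peaks(x, height=height, distance=min_dist)
    return peaks


def compute_median_beat(signal: EcgSignal) -> MedianBeat:
    """Median beat across R-aligned windows (−300 ms … +500 ms around R)."""
    if signal.duration_s < 5:
        raise InputError("signal must be at least 5 s for a median beat")
    fs = signal.sampling_rate_hz
    peaks = detect_r_peaks(signal)
    lo = int(round(BEAT_WINDOW_S[0] * fs))
    hi = int(round(BEAT_WINDOW_S[1] * fs))
    windows = []
    for p in peaks:
        if p + lo >= 0 and p + hi < signal.n_samples:
            windows.append(signal.samples[:, p + lo : p + hi])
    if len(windows) < 3:
        raise MeasurementError(f"only {len(windows)} usable beats detected")
    median = np.median(np.stack(windows, axis=0), axis=0)
    r_idx = -lo
    pr_lo = r_idx + int(round(PR_WINDOW_S[0] * fs))
    pr_hi = r_idx + int(round(PR_WINDOW_S[1] * fs))
    baseline = median[:, pr_lo:pr_hi].mean(axis=1)
    return MedianBeat(
        samples=median,
        lead_names=signal.lead_names,
        sampling_rate_hz=fs,
        r_peak_index=r_idx,
        baseline_mv=baseline,
        n_beats_used=len(windows),
    )


def _locate_j_point(beat: MedianBeat, lead: str = "II") -> int:
    """QRS offset on the median beat: first sample after R where the slope
    magnitude stays below 10% of the peak QRS slope."""
    fs = beat.sampling_rate_hz
    x = beat.samples[beat.lead_names.index(lead)]
    deriv = np.gradient(x) * fs  # mV/s
    r = beat.r_peak_index
    lo = r + int(round(J_SEARCH_S[0] * fs))
    hi = min(len(x) - 1, r + int(round(J_SEARCH_S[1] * fs)))
    qrs_slope = np.max(np.abs(deriv[max(0, r - int(0.06 * fs)) : hi]))
    if qrs_slope <= 0:
        raise MeasurementError("J point not locatable: flat derivative")
    thresh = 0.10 * qrs_slope
    quiet = np.abs(deriv[lo:hi]) < thresh
    # require the slope to stay quiet for 10 ms
    run = max(1, int(round(0.010 * fs)))
    for i in range(len(quiet) - run + 1):
        if quiet[i : i + run].all():
            return lo + i
    raise MeasurementError("J point not locatable within search window")


def measure_st(
    beat: MedianBeat, j_offset_ms: float = DEFAULT_J_OFFSET_MS
) -> StMeasurements:
    """Per-lead ST deviation (mV) at J + offset relative to the PR baseline."""
    fs = beat.sampling_rate_hz
    j_idx = _locate_j_point(beat)
    idx = j_idx + int(round(j_offset_ms / 1000.0 * fs))
    if idx >= beat.samples.shape[1]:
        raise MeasurementError("ST measurement point beyond beat window")
    values = beat.samples[:, idx] - beat.baseline_mv
    if not np.all(np.isfinite(values)):
        raise MeasurementError("non-finite ST measurement")
    st = {name: float(v) for name, v in zip(beat.lead_names, values)}
    return StMeasurements(st_mv=st, j_offset_ms=j_offset_ms, j_index=j_idx)


def evaluate_stemi(
    st: StMeasurements,
    age: float,
    sex: str,
    morphology_flags: frozenset[str] = frozenset(),
) -> StemiVerdict:
    """Apply the ST-elevation criteria to measured per-lead ST deviations.

    Returns ``not_applicable`` for LBBB/LVH/ventricular pacing, otherwise
    ``positive`` iff at least two leads within one contiguous group meet
    their lead/age/sex-specific threshold.
    """
    unknown = set(st.st_mv) - set(TWELVE_LEADS)
    if unknown:
        raise InputError(f"unknown lead names: {sorted(unknown)}")
    if morphology_flags:
        return StemiVerdict(verdict="not_applicable")
    meeting = frozenset(
        lead
        for lead, value in st.st_mv.items()
        if value >= st_elevation_threshold(lead, age, sex)
    )
    for group_name, group in CONTIGUOUS_GROUPS.items():
        if len(meeting.intersection(group)) >= 2:
            return StemiVerdict(
                verdict="positive",
                leads_meeting=meeting,
                contiguous_group=group_name,
            )
    return StemiVerdict(verdict="negative", leads_meeting=meeting)


def stemi_verdict_for_case(
    case: PatientCase, j_offset_ms: float = DEFAULT_J_OFFSET_MS
) -> StemiVerdict:
    """Evaluate the STEMI criteria on a visit's index ECG.

    Convenience wrapper used by the pipeline: morphology-flagged ECGs are
    ``not_applicable``; a failed measurement yields a ``negative`` verdict
    (no demonstrable ST elevation) rather than an exception.
    """
    ecg = case.index_ecg
    if ecg.morphology_flags:
        return StemiVerdict(verdict="not_applicable")
    try:
        beat = compute_median_beat(ecg)
        st = measure_st(beat, j_offset_ms=j_offset_ms)
    except MeasurementError:
        return StemiVerdict(verdict="negative")
    return evaluate_stemi(st, case.age, case.sex, ecg.morphology_flags)
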