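"""Synthetic ED chest-pain cohort generator.

Emulates the statistical structure the downstream analysis assumes: ~2%
occlusion-MI (OMI) prevalence among chest-pain visits, 12-lead 10 s ECGs in
which OMI induces ST elevation of variable subtlety in one contiguous lead
group, confounder morphologies (LBBB/LVH/ventricular pacing), tabular
history and medication flags, point-of-care labs with small
missing-at-random rates, strongly right-shifted troponin in MI, and registry
outcomes (discharge diagnosis, angiography with TIMI flow and culprit
status, revascularization within a week, echo wall motion, arrest,
mortality, time to angiography) that are consistent with the annotation
rules downstream.

The class-conditional probabilities for demographics, comorbidity and
medication flags and the troponin log-normals are taken from the printed
cohort-characteristics counts of the study population (467 OMI / 1122
non-occlusion MI / 22,922 others among 24,511 visits).

Waveforms are built from a per-beat sum of five Gaussians (P, Q, R, S, T)
with a fixed per-lead gain table over the 8 independent channels
(I, II, V1–V6); the four remaining limb leads are derived exactly via the
Einthoven/Goldberger identities.  The ST offset is realized as a smooth
plateau from the J point to the T-wave onset so that median-beat ST
measurement recovers the configured offset on noiseless signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DERIVED_LEADS,
    EIGHT_LEADS,
    EcgSignal,
    HISTORY_FLAGS,
    InputError,
    MEDICATION_FLAGS,
    MORPHOLOGIES,
    POC_LABS,
    PatientCase,
    RegistryOutcome,
    TWELVE_LEADS,
)
from .stemi_criteria import st_elevation_threshold

# ---------------------------------------------------------------------------
# Printed cohort-characteristics counts: (all, OMI, NOMI) out of
# (24511, 467, 1122).  The residual class is everyone without an MI.
# ---------------------------------------------------------------------------
_N_ALL, _N_OMI, _N_NOMI = 24511, 467, 1122
_N_NOAMI = _N_ALL - _N_OMI - _N_NOMI

TABLE_COUNTS: dict[str, tuple[int, int, int]] = {
    "female": (11802, 119, 418),
    "ischemic_heart_disease": (3624, 66, 277),
    "prior_ami": (1491, 34, 158),
    "angina_pectoris": (1587, 25, 125),
    "unstable_angina": (546, 14, 39),
    "heart_failure": (1456, 17, 91),
    "diabetes": (2086, 42, 163),
    "hypertension": (5015, 93, 330),
    "pulmonary_embolism": (302, 1, 14),
    "cerebrovascular_disease": (890, 15, 53),
    "copd": (925, 9, 40),
    "prior_cabg": (252, 4, 21),
    "prior_pci": (1417, 31, 114),
    "antithrombotics": (5721, 116, 467),
    "statin": (6685, 120, 452),
    "other_lipid_lowering": (652, 11, 51),
    "antihypertensive": (8968, 196, 621),
    "beta_blockers": (7373, 139, 474),
    "anticoagulants": (1321, 16, 57),
    "insulin": (1393, 41, 136),
    "other_antidiabetics": (2418, 61, 190),
    "diuretics": (3621, 60, 240),
    "thiazide": (1115, 22, 72),
    "ace_aii_antagonists": (7625, 161, 539),
}


def _class_prob(flag: str, latent: str) -> float:
    c_all, c_omi, c_nomi = TABLE_COUNTS[flag]
    if latent == "OMI":
        return c_omi / _N_OMI
    if latent == "NOMI":
        return c_nomi / _N_NOMI
    return (c_all - c_omi - c_nomi) / _N_NOAMI


# Age: overall mean 59 (sd 18.7); OMI 68 (13.4); NOMI 71 (12.9); the
# residual-class mean follows from the overall mean.
_AGE_PARAMS = {"OMI": (68.0, 13.4), "NOMI": (71.0, 12.9), "NO_AMI": (58.2, 18.9)}

# Initial hs-cTnT (ng/L), log-normal matched to printed median (IQR):
# 7 (4–15) without MI, 105 (29–441) OMI, 51 (24–120) NOMI.  Assay floor 3.
_TNT_PARAMS = {
    "OMI": (math.log(105.0), 2.018),
    "NOMI": (math.log(51.0), 1.193),
    "NO_AMI": (math.log(7.0), 0.980),
}
_TNT_FLOOR = 3.0

# Hours until angiography, log-normal matched to median (IQR):
# OMI 6 (3–24), NOMI 28 (19–53), 29 (17–60) overall.
_ANGIO_HOURS = {
    "OMI": (math.log(6.0), 1.542),
    "NOMI": (math.log(28.0), 0.760),
    "NO_AMI": (math.log(29.0), 0.930),
}

# Mortality, cumulative at 30/180/365 days by class.
_MORTALITY = {
    "OMI": (0.066, 0.094, 0.103),
    "NOMI": (0.033, 0.063, 0.085),
    "NO_AMI": (0.0094, 0.0258, 0.0380),
}

# ---------------------------------------------------------------------------
# Waveform template: per-beat sum of 5 Gaussians (amplitude mV, center s
# relative to the R peak, width s), with per-lead gains for the 8
# independent channels.
# ---------------------------------------------------------------------------
WAVE_NAMES = ("P", "Q", "R", "S", "T")
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.12, -0.180, 0.020),
    "Q": (-0.05, -0.040, 0.008),
    "R": (1.00, 0.000, 0.012),
    "S": (-0.15, 0.028, 0.008),
    "T": (0.30, 0.300, 0.050),
}
# Gains per channel for (P, Q, R, S, T); V1–V3 show the rS pattern via a
# large S gain, chest-lead T amplitudes grow toward V3–V4.
LEAD_WAVE_GAIN: dict[str, tuple[float, float, float, float, float]] = {
    "I": (0.6, 0.6, 0.7, 0.5, 0.6),
    "II": (1.0, 1.0, 1.0, 1.0, 1.0),
    "V1": (0.3, 0.0, 0.25, 8.0, -0.5),
    "V2": (0.3, 0.0, 0.50, 10.0, 1.2),
    "V3": (0.35, 0.2, 0.90, 7.0, 1.4),
    "V4": (0.4, 0.5, 1.40, 4.0, 1.2),
    "V5": (0.45, 0.7, 1.30, 2.0, 1.0),
    "V6": (0.45, 0.7, 1.00, 1.0, 0.8),
}
# ST plateau (seconds after R): cosine ramp up, flat top, cosine ramp down.
_ST_RAMP_UP = (0.030, 0.050)
_ST_FLAT_END = 0.240
_ST_RAMP_DOWN_END = 0.320

# Which synthesized channels carry the ischemic ST shift per territory.
# Elevation in II propagates to III and aVF through the lead identities,
# yielding the classic inferior pattern.
TERRITORY_CHANNELS: dict[str, tuple[str, ...]] = {
    "inferior": ("II",),
    "anterior": ("V2", "V3"),
    "lateral": ("I", "V5", "V6"),
}
# Representative lead used to pick the applicable STEMI threshold.
_TERRITORY_THRESHOLD_LEAD = {"inferior": "II", "anterior": "V2", "lateral": "V5"}


@dataclass
class EcgMorphParams:
    """Morphology parameters for one synthetic ECG."""

    heart_rate: float = 72.0
    wave_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    st_offset_mv: Mapping[str, float] = field(default_factory=dict)
    noise_sd_mv: float = 0.0
    baseline_wander_amp_mv: float = 0.0
    morphology: str = "normal"

    def __post_init__(self) -> None:
        if not 30 <= self.heart_rate <= 220:
            raise InputError(f"heart_rate {self.heart_rate} outside [30, 220]")
        for name, (_, _, width) in self.wave_params.items():
            if width <= 0:
                raise InputError(f"wave {name} width must be > 0")
        if self.morphology not in ("normal",) + MORPHOLOGIES:
            raise InputError(f"unknown morphology {self.morphology!r}")
        unknown = set(self.st_offset_mv) - set(EIGHT_LEADS)
        if unknown:
            raise InputError(f"st_offset_mv for unknown channels: {sorted(unknown)}")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 3000
    omi_prevalence: float = 0.019
    nomi_prevalence: float = 0.046
    subtle_omi_fraction: float = 0.6
    ecg_silent_given_subtle: float = 0.25
    confounder_rates: Mapping[str, float] = field(
        default_factory=lambda: {"LBBB": 0.02, "LVH": 0.04, "VP": 0.01}
    )
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "hs_ctnt_initial_ng_l": 0.008,
            "hemoglobin": 0.02,
            "creatinine": 0.02,
            "glucose": 0.05,
        }
    )
    extra_ecg_rate: float = 0.5
    benign_st_elevation_rate: float = 0.025
    nomi_st_elevation_rate: float = 0.04
    no_ecg_rate: float = 0.004
    poor_quality_rate: float = 0.008
    unclear_timi_rate: float = 0.01
    unclear_outcome_rate: float = 0.002
    sampling_rate_hz: float = 500.0
    duration_s: float = 10.0
    noise_sd_mv: float = 0.02
    baseline_wander_amp_mv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InputError("n_patients must be positive")
        fractions = {
            "omi_prevalence": self.omi_prevalence,
            "nomi_prevalence": self.nomi_prevalence,
            "subtle_omi_fraction": self.subtle_omi_fraction,
            "ecg_silent_given_subtle": self.ecg_silent_given_subtle,
            "extra_ecg_rate": self.extra_ecg_rate,
            "benign_st_elevation_rate": self.benign_st_elevation_rate,
            "nomi_st_elevation_rate": self.nomi_st_elevation_rate,
            "no_ecg_rate": self.no_ecg_rate,
            "poor_quality_rate": self.poor_quality_rate,
            "unclear_timi_rate": self.unclear_timi_rate,
            "unclear_outcome_rate": self.unclear_outcome_rate,
            **{f"confounder[{k}]": v for k, v in self.confounder_rates.items()},
            **{f"missingness[{k}]": v for k, v in self.missingness_rates.items()},
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name}={value} outside [0, 1]")
        if self.omi_prevalence + self.nomi_prevalence >= 1.0:
            raise InputError("prevalences must sum to < 1")


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def derive_limb_leads(
    samples: np.ndarray, lead_names: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Append the four derived limb leads to an 8-channel signal.

    III = II − I, aVR = −(I + II)/2, aVL = I − II/2, aVF = II − I/2.
    Returns the 12 leads in canonical order.
    """
    names = list(lead_names)
    missing = [l for l in EIGHT_LEADS if l not in names]
    if missing:
        raise InputError(f"missing required leads: {missing}")
    samples = np.asarray(samples, dtype=float)
    lead = {name: samples[names.index(name)] for name in EIGHT_LEADS}
    i, ii = lead["I"], lead["II"]
    derived = {
        "III": ii - i,
        "aVR": -(i + ii) / 2.0,
        "aVL": i - ii / 2.0,
        "aVF": ii - i / 2.0,
    }
    out = np.stack([lead.get(n, derived.get(n)) for n in TWELVE_LEADS])
    return out, TWELVE_LEADS


def _st_plateau(t: np.ndarray) -> np.ndarray:
    """Unit ST-plateau shape as a function of time after the R peak."""
    y = np.zeros_like(t)
    up0, up1 = _ST_RAMP_UP
    rise = (t >= up0) & (t < up1)
    y[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - up0) / (up1 - up0)))
    y[(t >= up1) & (t <= _ST_FLAT_END)] = 1.0
    fall = (t > _ST_FLAT_END) & (t < _ST_RAMP_DOWN_END)
    span = _ST_RAMP_DOWN_END - _ST_FLAT_END
    y[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - _ST_FLAT_END) / span))
    return y


def _beat_template(params: EcgMorphParams, fs: float) -> tuple[np.ndarray, int]:
    """8-channel beat template on a window around the R peak.

    Returns (template of shape (8, W), index of the R peak in the window).
    """
    t = np.arange(-0.35, 0.55, 1.0 / fs)
    waves = {k: list(v) for k, v in params.wave_params.items()}
    if params.morphology in ("LBBB", "VP"):
        for w in ("Q", "R", "S"):
            waves[w][2] *= 2.5  # widened QRS
    if params.morphology == "LVH":
        waves["R"][0] *= 1.8  # high-voltage R
    plateau = _st_plateau(t)
    template = np.zeros((len(EIGHT_LEADS), t.size))
    for li, lead in enumerate(EIGHT_LEADS):
        gains = LEAD_WAVE_GAIN[lead]
        y = np.zeros_like(t)
        for gain, wave in zip(gains, WAVE_NAMES):
            amp, center, width = waves[wave]
            y += gain * amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        y += params.st_offset_mv.get(lead, 0.0) * plateau
        template[li] = y
    r_index = int(round(0.35 * fs))
    return template, r_index


def synthesize_ecg(
    params: EcgMorphParams,
    seed: int,
    sampling_rate_hz: float = 500.0,
    duration_s: float = 10.0,
    recorded_at: float = 0.0,
    quality_ok: bool = True,
) -> EcgSignal:
    """Synthesize one 12-lead ECG from morphology parameters.

    Eight channels (I, II, V1–V6) are built independently from the beat
    template plus noise and baseline wander; the four remaining limb leads
    are derived exactly, so the lead identities hold by construction.
    """
    rng = np.random.default_rng(seed)
    fs = sampling_rate_hz
    n = int(round(duration_s * fs))
    template, r_index = _beat_template(params, fs)
    width = template.shape[1]
    period = 60.0 / params.heart_rate
    x = np.zeros((len(EIGHT_LEADS), n))
    r_time = 0.40
    while r_time < duration_s + 0.40:
        start = int(round(r_time * fs)) - r_index
        lo, hi = max(0, start), min(n, start + width)
        if hi > lo:
            x[:, lo:hi] += template[:, lo - start : hi - start]
        r_time += period
    if params.noise_sd_mv > 0:
        x += rng.normal(0.0, params.noise_sd_mv, size=x.shape)
    if params.baseline_wander_amp_mv > 0:
        t = np.arange(n) / fs
        for li in range(x.shape[0]):
            phase = rng.uniform(0, 2 * np.pi)
            x[li] += params.baseline_wander_amp_mv * np.sin(
                2 * np.pi * 0.25 * t + phase
            )
    twelve, names = derive_limb_leads(x, EIGHT_LEADS)
    flags = frozenset() if params.morphology == "normal" else frozenset(
        {params.morphology}
    )
    return EcgSignal(
        samples=twelve,
        lead_names=names,
        sampling_rate_hz=fs,
        quality_ok=quality_ok,
        morphology_flags=flags,
        recorded_at=recorded_at,
    )


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def _draw_latent(rng: np.random.Generator, config: CohortConfig) -> str:
    u = rng.random()
    if u < config.omi_prevalence:
        return "OMI"
    if u < config.omi_prevalence + config.nomi_prevalence:
        return "NOMI"
    return "NO_AMI"


def _draw_st_pattern(
    latent: str, age: float, sex: str, config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, float], Optional[bool]]:
    """Per-channel ST offsets and, for OMI, whether the case is subtle.

    Subtle OMI has its peak ST elevation between 0.05 mV and the applicable
    STEMI threshold, so the rule-based comparator is structurally blind to
    it while the waveform still carries signal.
    """
    territory = ("inferior", "anterior", "lateral")[rng.integers(3)]
    channels = TERRITORY_CHANNELS[territory]
    thr = st_elevation_threshold(_TERRITORY_THRESHOLD_LEAD[territory], age, sex)
    if latent == "OMI":
        subtle = rng.random() < config.subtle_omi_fraction
        if subtle:
            # a fraction of subtle occlusions is ECG-occult: no ST shift at
            # all, detectable only through troponin and clinical context
            if rng.random() < config.ecg_silent_given_subtle:
                return {}, subtle
            peak = rng.uniform(0.05, 0.95 * thr)
        else:
            peak = thr + rng.uniform(0.05, 0.30)
        return {c: peak for c in channels}, subtle
    if latent == "NOMI":
        u = rng.random()
        if u < config.nomi_st_elevation_rate:
            peak = thr + rng.uniform(0.05, 0.25)
        elif u < 0.30:
            peak = rng.uniform(0.02, 0.06)
        else:
            return {}, None
        return {c: peak for c in channels}, None
    # benign early-repolarization ST elevation in a small fraction of
    # MI-negative patients keeps the comparator's specificity below 1
    if rng.random() < config.benign_st_elevation_rate:
        peak = thr + rng.uniform(0.0, 0.15)
        return {c: peak for c in channels}, None
    return {}, None


def _draw_morphology(config: CohortConfig, rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for morph in MORPHOLOGIES:
        acc += config.confounder_rates.get(morph, 0.0)
        if u < acc:
            return morph
    return "normal"


def _draw_registry(
    latent: str,
    tnt_initial: float,
    subtle: Optional[bool],
    st_above_threshold: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[RegistryOutcome, Optional[str]]:
    """Registry outcome consistent with the annotation tree.

    Every latent OMI case is constructed to satisfy at least one OMI branch
    (R1 registry-ACO, R2 troponin+revascularization, R3 angiographic
    TIMI 0/1 culprit, R4 no-angiography criteria); latent NOMI cases are
    guarded against satisfying any, except a small unclear-TIMI fraction
    that ends in needs-review.
    """
    p30, p180, p365 = _MORTALITY[latent]
    u_death = rng.random()
    deaths = dict(
        died_30d=u_death < p30, died_180d=u_death < p180, died_1y=u_death < p365
    )
    if latent == "OMI":
        branch = ("R1", "R2", "R3", "R4")[
            rng.choice(4, p=[0.70, 0.10, 0.12, 0.08])
        ]
        max_tnt = tnt_initial * max(1.0, float(np.exp(rng.normal(1.8, 0.9))))
        stemi_ecg = bool(st_above_threshold and rng.random() < 0.6)
        arrest = rng.random() < 0.08
        if branch == "R4":
            max_tnt = max(max_tnt, 1000.0 * float(np.exp(rng.uniform(0.05, 2.0))))
            rwma = rng.random() < 0.7
            if not rwma:
                stemi_ecg, arrest = True, True
            return RegistryOutcome(
                discharge_ami=True,
                angiography_performed=False,
                max_hs_ctnt_24h_ng_l=max_tnt,
                new_rwma=rwma,
                stemi_ecg_present=stemi_ecg,
                cardiac_arrest_before_angio=arrest,
                **deaths,
            ), branch
        hours = float(np.exp(rng.normal(*_ANGIO_HOURS["OMI"])))
        if branch == "R1":
            return RegistryOutcome(
                discharge_ami=True,
                scaar_aco=True,
                angiography_performed=True,
                hours_to_angiography=hours,
                culprit_lesion=True,
                timi_flow=int(rng.integers(2)),
                urgent_pci=rng.random() < 0.92,
                cabg=rng.random() < 0.05,
                max_hs_ctnt_24h_ng_l=max_tnt,
                new_rwma=rng.random() < 0.5,
                stemi_ecg_present=stemi_ecg,
                cardiac_arrest_before_angio=arrest,
                **deaths,
            ), branch
        if branch == "R2":
            max_tnt = max(max_tnt, 1000.0 * float(np.exp(rng.uniform(0.05, 2.0))))
            pci = rng.random() < 0.85
            angio = rng.random() < 0.9
            return RegistryOutcome(
                discharge_ami=True,
                angiography_performed=angio,
                hours_to_angiography=hours if angio else None,
                culprit_lesion=(rng.random() < 0.6) if angio else None,
                timi_flow=int(rng.integers(4)) if angio else None,
                urgent_pci=pci,
                cabg=not pci,
                max_hs_ctnt_24h_ng_l=max_tnt,
                new_rwma=rng.random() < 0.5,
                stemi_ecg_present=stemi_ecg,
                cardiac_arrest_before_angio=arrest,
                **deaths,
            ), branch
        # R3: angiographic culprit with TIMI flow 0 or 1
        return RegistryOutcome(
            discharge_ami=True,
            angiography_performed=True,
            hours_to_angiography=hours,
            culprit_lesion=True,
            timi_flow=int(rng.integers(2)),
            urgent_pci=rng.random() < 0.9,
            max_hs_ctnt_24h_ng_l=max_tnt,
            new_rwma=rng.random() < 0.5,
            stemi_ecg_present=stemi_ecg,
            cardiac_arrest_before_angio=arrest,
            **deaths,
        ), branch
    if latent == "NOMI":
        if rng.random() < config.unclear_outcome_rate:
            # outcome not determinable from the registry: excluded downstream
            return RegistryOutcome(discharge_ami=True, **deaths), "unclear"
        max_tnt = tnt_initial * max(1.0, float(np.exp(rng.normal(1.0, 0.7))))
        angio = rng.random() < 0.85
        pci = cabg = False
        hours = culprit = timi = None
        branch = None
        if angio:
            hours = float(np.exp(rng.normal(*_ANGIO_HOURS["NOMI"])))
            culprit = rng.random() < 0.25
            if culprit and rng.random() < config.unclear_timi_rate:
                timi, branch = "unclear", "needs_review"
            else:
                timi = int(2 + rng.integers(2))
            pci = rng.random() < 0.35
            cabg = rng.random() < 0.03
        if max_tnt > 1000.0 and (pci or cabg):
            max_tnt = 990.0  # guard: would otherwise satisfy the troponin branch
        rwma = rng.random() < 0.25
        arrest = rng.random() < 0.01
        stemi_ecg = bool(st_above_threshold or rng.random() < 0.02)
        if not angio and max_tnt > 1000.0:
            rwma, arrest = False, False  # guard against the no-angiography branch
        return RegistryOutcome(
            discharge_ami=True,
            angiography_performed=angio,
            hours_to_angiography=hours,
            culprit_lesion=culprit,
            timi_flow=timi,
            urgent_pci=pci,
            cabg=cabg,
            max_hs_ctnt_24h_ng_l=max_tnt,
            new_rwma=rwma,
            stemi_ecg_present=stemi_ecg,
            cardiac_arrest_before_angio=arrest,
            **deaths,
        ), branch
    # No MI: all branches require the discharge diagnosis, so none can fire.
    angio = rng.random() < 0.02
    max_tnt = (
        tnt_initial * float(np.exp(rng.normal(0.05, 0.2)))
        if rng.random() < 0.6
        else None
    )
    return RegistryOutcome(
        discharge_ami=False,
        angiography_performed=angio,
        hours_to_angiography=(
            float(np.exp(rng.normal(*_ANGIO_HOURS["NO_AMI"]))) if angio else None
        ),
        culprit_lesion=False if angio else None,
        timi_flow=3 if angio else None,
        max_hs_ctnt_24h_ng_l=max_tnt,
        stemi_ecg_present=bool(st_above_threshold),
        **deaths,
    ), None


def _generate_case(
    patient_id: str, config: CohortConfig, rng: np.random.Generator
) -> PatientCase:
    latent = _draw_latent(rng, config)
    sex = "female" if rng.random() < _class_prob("female", latent) else "male"
    mean, sd = _AGE_PARAMS[latent]
    age = float(np.clip(rng.normal(mean, sd), 18.0, 100.0))
    history = {f: bool(rng.random() < _class_prob(f, latent)) for f in HISTORY_FLAGS}
    meds = {f: bool(rng.random() < _class_prob(f, latent)) for f in MEDICATION_FLAGS}

    mu, sigma = _TNT_PARAMS[latent]
    tnt = max(_TNT_FLOOR, float(np.exp(rng.normal(mu, sigma))))
    mi = latent in ("OMI", "NOMI")
    labs: dict[str, Optional[float]] = {
        "hemoglobin": float(rng.normal(140.0, 15.0)),
        "creatinine": float(np.exp(rng.normal(math.log(85.0 if mi else 80.0), 0.3))),
        "glucose": float(np.exp(rng.normal(math.log(7.5 if mi else 6.0), 0.25))),
    }

    morphology = _draw_morphology(config, rng)
    st_offsets, subtle = _draw_st_pattern(latent, age, sex, config, rng)
    st_above = bool(st_offsets) and subtle is not True and (
        latent != "NOMI" or max(st_offsets.values(), default=0.0) > 0.1
    )
    registry, branch = _draw_registry(latent, tnt, subtle, st_above, config, rng)

    heart_rate = float(np.clip(rng.normal(75.0, 12.0), 45.0, 140.0))
    params = EcgMorphParams(
        heart_rate=heart_rate,
        st_offset_mv=st_offsets,
        noise_sd_mv=config.noise_sd_mv,
        baseline_wander_amp_mv=config.baseline_wander_amp_mv,
        morphology=morphology,
    )
    u_ecg = rng.random()
    quality_ok = True
    ecgs: list[EcgSignal] = []
    if u_ecg < config.no_ecg_rate:
        pass  # visit without any ECG: excluded downstream
    else:
        if u_ecg < config.no_ecg_rate + config.poor_quality_rate:
            quality_ok = False
        ecgs.append(
            synthesize_ecg(
                params,
                seed=int(rng.integers(2**31)),
                sampling_rate_hz=config.sampling_rate_hz,
                duration_s=config.duration_s,
                recorded_at=0.2,
                quality_ok=quality_ok,
            )
        )
        if rng.random() < config.extra_ecg_rate:
            ecgs.append(
                synthesize_ecg(
                    params,
                    seed=int(rng.integers(2**31)),
                    sampling_rate_hz=config.sampling_rate_hz,
                    duration_s=config.duration_s,
                    recorded_at=0.2 + float(rng.uniform(0.3, 2.0)),
                )
            )
    return PatientCase(
        patient_id=patient_id,
        age=age,
        sex=sex,
        history_flags=history,
        medication_flags=meds,
        poc_labs=labs,
        hs_ctnt_initial_ng_l=tnt,
        ecgs=ecgs,
        registry=registry,
        latent_truth=latent,
        latent_branch=(
            branch + (":subtle" if subtle else "") if branch else None
        ),
    )


def generate_cohort(config: CohortConfig) -> list[PatientCase]:
    """Generate a deterministic synthetic cohort of ED chest-pain visits."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases = [
        _generate_case(f"P{i:06d}", config, rng) for i in range(config.n_patients)
    ]
    apply_missingness(
        cases, config.missingness_rates, seed=int(rng.integers(2**31))
    )
    return cases


def apply_missingness(
    cases: list[PatientCase], rates: Mapping[str, float], seed: int
) -> list[PatientCase]:
    """Mask labs missing-at-random, independently of the latent outcome.

    Masking is in place; the list is returned for chaining.
    """
    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise InputError(f"missingness rate for {name} outside [0, 1]")
    rng = np.random.default_rng(seed)
    for case in cases:
        for name, rate in rates.items():
            if rng.random() < rate:
                if name == "hs_ctnt_initial_ng_l":
                    case.hs_ctnt_initial_ng_l = None
                elif name in case.poc_labs:
                    case.poc_labs[name] = None
    return cases


# ---------------------------------------------------------------------------
# On-disk interchange: CSV tables + one array store for waveforms
# ---------------------------------------------------------------------------

def save_cohort(cases: list[PatientCase], out_dir: str | Path) -> None:
    """Write cases.csv, registry.csv, latent.csv, ecg_index.csv, waveforms.npz.

    The latent ground truth goes to its own file, never into the
    model-facing cases table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case_rows, reg_rows, latent_rows, index_rows = [], [], [], []
    waveforms: dict[str, np.ndarray] = {}
    fs = None
    for case in cases:
        row = {"patient_id": case.patient_id, "age": case.age, "sex": case.sex}
        row.update(case.history_flags)
        row.update(case.medication_flags)
        row.update(case.poc_labs)
        row["hs_ctnt_initial_ng_l"] = case.hs_ctnt_initial_ng_l
        case_rows.append(row)
        reg = {"patient_id": case.patient_id}
        reg.update(vars(case.registry))
        reg_rows.append(reg)
        latent_rows.append(
            {
                "patient_id": case.patient_id,
                "latent_truth": case.latent_truth,
                "latent_branch": case.latent_branch,
            }
        )
        for k, ecg in enumerate(case.ecgs):
            record = f"{case.patient_id}_{k}"
            waveforms[record] = ecg.samples.astype(np.float32)
            fs = ecg.sampling_rate_hz
            index_rows.append(
                {
                    "patient_id": case.patient_id,
                    "record": record,
                    "recorded_at": ecg.recorded_at,
                    "is_index": k == 0,
                    "quality_ok": ecg.quality_ok,
                    "morphology_flags": "|".join(sorted(ecg.morphology_flags)),
                }
            )
    pd.DataFrame(case_rows).to_csv(out / "cases.csv", index=False)
    pd.DataFrame(reg_rows).to_csv(out / "registry.csv", index=False)
    pd.DataFrame(latent_rows).to_csv(out / "latent.csv", index=False)
    pd.DataFrame(index_rows).to_csv(out / "ecg_index.csv", index=False)
    np.savez_compressed(
        out / "waveforms.npz", __sampling_rate_hz__=np.array([fs or 0.0]), **waveforms
    )


def load_cohort(in_dir: str | Path) -> list[PatientCase]:
    """Load a cohort written by :func:`save_cohort`."""
    src = Path(in_dir)
    cases_df = pd.read_csv(src / "cases.csv")
    reg_df = pd.read_csv(src / "registry.csv").set_index("patient_id")
    index_df = pd.read_csv(src / "ecg_index.csv")
    latent_path = src / "latent.csv"
    latent_df = (
        pd.read_csv(latent_path).set_index("patient_id")
        if latent_path.exists()
        else None
    )
    store = np.load(src / "waveforms.npz")
    fs = float(store["__sampling_rate_hz__"][0])

    def _opt(v):
        return None if pd.isna(v) else v

    def _opt_bool(v):
        return None if pd.isna(v) else bool(v)

    ecgs_by_patient: dict[str, list[EcgSignal]] = {}
    for row in index_df.itertuples():
        flags = (
            frozenset(str(row.morphology_flags).split("|"))
            if isinstance(row.morphology_flags, str) and row.morphology_flags
            else frozenset()
        )
        ecgs_by_patient.setdefault(row.patient_id, []).append(
            EcgSignal(
                samples=store[row.record].astype(float),
                lead_names=TWELVE_LEADS,
                sampling_rate_hz=fs,
                quality_ok=bool(row.quality_ok),
                morphology_flags=flags,
                recorded_at=float(row.recorded_at),
            )
        )
    cases = []
    for row in cases_df.itertuples():
        pid = row.patient_id
        reg = reg_df.loc[pid]
        timi = _opt(reg["timi_flow"])
        if timi is not None and timi != "unclear":
            timi = int(float(timi))
        registry = RegistryOutcome(
            discharge_ami=bool(reg["discharge_ami"]),
            scaar_aco=bool(reg["scaar_aco"]),
            angiography_performed=bool(reg["angiography_performed"]),
            hours_to_angiography=_opt(reg["hours_to_angiography"]),
            culprit_lesion=_opt_bool(reg["culprit_lesion"]),
            timi_flow=timi,
            urgent_pci=bool(reg["urgent_pci"]),
            cabg=bool(reg["cabg"]),
            max_hs_ctnt_24h_ng_l=_opt(reg["max_hs_ctnt_24h_ng_l"]),
            new_rwma=_opt_bool(reg["new_rwma"]),
            cardiac_arrest_before_angio=bool(reg["cardiac_arrest_before_angio"]),
            stemi_ecg_present=bool(reg["stemi_ecg_present"]),
            died_30d=bool(reg["died_30d"]),
            died_180d=bool(reg["died_180d"]),
            died_1y=bool(reg["died_1y"]),
        )
        latent_truth = latent_branch = None
        if latent_df is not None and pid in latent_df.index:
            latent_truth = _opt(latent_df.loc[pid, "latent_truth"])
            latent_branch = _opt(latent_df.loc[pid, "latent_branch"])
        cases.append(
            PatientCase(
                patient_id=pid,
                age=float(row.age),
                sex=row.sex,
                history_flags={f: bool(getattr(row, f)) for f in HISTORY_FLAGS},
                medication_flags={
                    f: bool(getattr(row, f)) for f in MEDICATION_FLAGS
                },
                poc_labs={f: _opt(getattr(row, f)) for f in POC_LABS},
                hs_ctnt_initial_ng_l=_opt(row.hs_ctnt_initial_ng_l),
                ecgs=ecgs_by_patient.get(pid, []),
                registry=registry,
                latent_truth=latent_truth,
                latent_branch=latent_branch,
            )
        )
    return cases
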