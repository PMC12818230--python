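"""Core domain containers shared across the pipeline.

An emergency-department (ED) chest-pain visit is represented by a
:class:`PatientCase`: demographics, history/medication flags, point-of-care
labs, the initial high-sensitivity troponin T, one or more 12-lead ECGs, and
a :class:`RegistryOutcome` holding the post-visit facts (discharge diagnosis,
angiography, revascularization, echo, mortality).  Registry facts are used
only to annotate the occlusion-MI (OMI) outcome — never as model inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

# Canonical lead orderings.  The four derived limb leads (III, aVR, aVL, aVF)
# are linear combinations of I and II and carry no extra information.
EIGHT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
DERIVED_LEADS: tuple[str, ...] = ("III", "aVR", "aVL", "aVF")
TWELVE_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

MORPHOLOGIES: tuple[str, ...] = ("LBBB", "LVH", "VP")

TimiFlow = Union[int, str]  # 0..3 or the literal "unclear"


class InputError(ValueError):
    """Invalid or inconsistent input to a pipeline operation."""


class MeasurementError(RuntimeError):
    """An ECG measurement could not be made (too few beats, flatline, ...)."""


@dataclass
class EcgSignal:
    """A multichannel ECG waveform in millivolts.

    ``samples`` has shape ``(len(lead_names), n_samples)``.  ``recorded_at``
    is hours since ED arrival; the index ECG of a visit is the earliest one.
    """

    samples: np.ndarray
    lead_names: tuple[str, ...] = TWELVE_LEADS
    sampling_rate_hz: float = 500.0
    quality_ok: bool = True
    morphology_flags: frozenset[str] = frozenset()
    recorded_at: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.lead_names):
            raise InputError(
                f"samples shape {self.samples.shape} does not match "
                f"{len(self.lead_names)} leads"
            )
        if self.sampling_rate_hz <= 0:
            raise InputError("sampling_rate_hz must be positive")
        unknown = set(self.morphology_flags) - set(MORPHOLOGIES)
        if unknown:
            raise InputError(f"unknown morphology flags: {sorted(unknown)}")
        self.morphology_flags = frozenset(self.morphology_flags)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise InputError(f"lead {name!r} not present") from None


@dataclass
class RegistryOutcome:
    """Post-visit registry facts, consumed only by outcome annotation.

    ``scaar_aco`` is a registered acute coronary occlusion in the national
    angiography registry; ``timi_flow`` is the angiographic perfusion grade
    (0 = no flow ... 3 = normal) or ``"unclear"`` when the report could not
    be graded.
    """

    discharge_ami: bool = False
    scaar_aco: bool = False
    angiography_performed: bool = False
    hours_to_angiography: Optional[float] = None
    culprit_lesion: Optional[bool] = None
    timi_flow: Optional[TimiFlow] = None
    urgent_pci: bool = False
    cabg: bool = False
    max_hs_ctnt_24h_ng_l: Optional[float] = None
    new_rwma: Optional[bool] = None
    cardiac_arrest_before_angio: bool = False
    stemi_ecg_present: bool = False
    died_30d: bool = False
    died_180d: bool = False
    died_1y: bool = False

    def __post_init__(self) -> None:
        if self.angiography_performed != (self.hours_to_angiography is not None):
            raise InputError(
                "hours_to_angiography must be present iff angiography_performed"
            )
        if self.timi_flow is not None and not self.angiography_performed:
            raise InputError("timi_flow requires angiography_performed")
        if self.timi_flow is not None and self.timi_flow != "unclear":
            if self.timi_flow not in (0, 1, 2, 3):
                raise InputError(f"invalid timi_flow {self.timi_flow!r}")
        if self.hours_to_angiography is not None and self.hours_to_angiography < 0:
            raise InputError("hours_to_angiography must be nonnegative")


REGISTRY_FIELDS: frozenset[str] = frozenset(
    f.name for f in dataclasses.fields(RegistryOutcome)
)

# History / medication flags mirroring the cohort-characteristics table rows.
HISTORY_FLAGS: tuple[str, ...] = (
    "ischemic_heart_disease",
    "prior_ami",
    "angina_pectoris",
    "unstable_angina",
    "heart_failure",
    "diabetes",
    "hypertension",
    "pulmonary_embolism",
    "cerebrovascular_disease",
    "copd",
    "prior_cabg",
    "prior_pci",
)
MEDICATION_FLAGS: tuple[str, ...] = (
    "antithrombotics",
    "statin",
    "other_lipid_lowering",
    "antihypertensive",
    "beta_blockers",
    "anticoagulants",
    "insulin",
    "other_antidiabetics",
    "diuretics",
    "thiazide",
    "ace_aii_antagonists",
)
POC_LABS: tuple[str, ...] = ("hemoglobin", "creatinine", "glucose")

LatentTruth = str  # "OMI" | "NOMI" | "NO_AMI"


@dataclass
class PatientCase:
    """One ED chest-pain visit.

    ``latent_truth`` (and ``latent_branch``) exist only on synthetic cohorts:
    they record the generator's ground truth and never enter model-facing
    feature tables.
    """

    patient_id: str
    age: float
    sex: str  # "female" | "male"
    history_flags: dict[str, bool] = field(default_factory=dict)
    medication_flags: dict[str, bool] = field(default_factory=dict)
    poc_labs: dict[str, Optional[float]] = field(default_factory=dict)
    hs_ctnt_initial_ng_l: Optional[float] = None
    ecgs: list[EcgSignal] = field(default_factory=list)
    registry: RegistryOutcome = field(default_factory=RegistryOutcome)
    latent_truth: Optional[LatentTruth] = None
    latent_branch: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        self.ecgs = sorted(self.ecgs, key=lambda e: e.recorded_at)

    @property
    def index_ecg(self) -> EcgSignal:
        if not self.ecgs:
            raise InputError(f"patient {self.patient_id} has no ECG")
        return self.ecgs[0]
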