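"""Exclusion flow, OMI outcome annotation, and cohort summaries.

The occlusion-MI (OMI) outcome is annotated from registry facts by a fixed
sequence of rules, first match wins:

* R1 — discharge AMI diagnosis and a registered acute coronary occlusion in
  the national angiography registry.
* R2 — discharge AMI, maximum 24 h hs-cTnT above 1000 ng/L, and urgent
  PCI or CABG within one week of the visit.
* R3 — discharge AMI with angiography showing an acute culprit lesion and
  TIMI flow 0 or 1.  An ungradable ("unclear") TIMI report ends in a
  terminal needs-review status, standing in for human adjudication.
* R4 — discharge AMI without angiography, hs-cTnT above 1000 ng/L, and
  either new regional wall-motion abnormality on echo, or a STEMI-indicative
  ECG with cardiac arrest before angiography could be performed.

Everything else with a discharge AMI diagnosis is NOMI; everything else is
NO_AMI.  Visits with no ECG, a technically poor index ECG, or a registry too
incomplete for any branch are excluded before annotation.  A STEMI discharge
diagnosis is NOT an exclusion: those visits are kept to reflect patient flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np

from .types import InputError, PatientCase, RegistryOutcome

OMI_STATUSES = ("OMI", "NOMI", "NO_AMI", "EXCLUDED", "NEEDS_REVIEW")


@dataclass
class AnnotationConfig:
    troponin_threshold_ng_l: float = 1000.0
    occlusive_timi: frozenset[int] = frozenset({0, 1})
    revasc_window_days: int = 7

    def __post_init__(self) -> None:
        if self.troponin_threshold_ng_l <= 0:
            raise InputError("troponin_threshold_ng_l must be > 0")


@dataclass
class OmiLabel:
    status: str
    rule_fired: Optional[str] = None      # R1..R4, only when status == OMI
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in OMI_STATUSES:
            raise InputError(f"unknown status {self.status!r}")
        if (self.rule_fired is not None) != (self.status == "OMI"):
            raise InputError("rule_fired must be set iff status is OMI")
        if (self.exclusion_reason is not None) != (self.status == "EXCLUDED"):
            raise InputError("exclusion_reason must be set iff status is EXCLUDED")


def apply_exclusions(case: PatientCase) -> Optional[OmiLabel]:
    """Return an EXCLUDED label, or None when the case passes through.

    Exclusions: no ECG at the visit, poor technical quality of the index
    ECG, or an unclear outcome (discharge AMI but a registry too incomplete
    for any annotation branch to be evaluated).
    """
    if not case.ecgs:
        return OmiLabel(status="EXCLUDED", exclusion_reason="no_ecg")
    if not case.index_ecg.quality_ok:
        return OmiLabel(status="EXCLUDED", exclusion_reason="poor_quality_ecg")
    reg = case.registry
    if (
        reg.discharge_ami
        and not reg.scaar_aco
        and not reg.angiography_performed
        and reg.max_hs_ctnt_24h_ng_l is None
    ):
        return OmiLabel(status="EXCLUDED", exclusion_reason="unclear_outcome")
    return None


def annotate_omi(
    registry: RegistryOutcome, config: AnnotationConfig = AnnotationConfig()
) -> OmiLabel:
    """Annotate one registry outcome.  Total and deterministic."""
    if registry.timi_flow is not None and not registry.angiography_performed:
        raise InputError("timi_flow without angiography is contradictory")
    reg = registry
    thr = config.troponin_threshold_ng_l
    high_tnt = (
        reg.max_hs_ctnt_24h_ng_l is not None and reg.max_hs_ctnt_24h_ng_l > thr
    )
    if not reg.discharge_ami:
        return OmiLabel(status="NO_AMI")
    if reg.scaar_aco:
        return OmiLabel(status="OMI", rule_fired="R1")
    if high_tnt and (reg.urgent_pci or reg.cabg):
        return OmiLabel(status="OMI", rule_fired="R2")
    if reg.angiography_performed and reg.culprit_lesion:
        if reg.timi_flow in config.occlusive_timi:
            return OmiLabel(status="OMI", rule_fired="R3")
        if reg.timi_flow == "unclear":
            return OmiLabel(status="NEEDS_REVIEW")
    if (
        not reg.angiography_performed
        and high_tnt
        and (
            bool(reg.new_rwma)
            or (reg.stemi_ecg_present and reg.cardiac_arrest_before_angio)
        )
    ):
        return OmiLabel(status="OMI", rule_fired="R4")
    return OmiLabel(status="NOMI")


def annotate_cohort(
    cases: list[PatientCase], config: AnnotationConfig = AnnotationConfig()
) -> list[OmiLabel]:
    """Exclusion flow followed by annotation, one label per case."""
    labels = []
    for case in cases:
        label = apply_exclusions(case)
        labels.append(label if label is not None else annotate_omi(case.registry, config))
    return labels


def round_pct(numerator: float, denominator: float) -> float:
    """Percentage to one decimal, rounding half away from zero."""
    if denominator == 0:
        raise InputError("percentage with zero denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _median_iqr(values: list[float]) -> Optional[tuple[float, float, float]]:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
    )


def cohort_summary(
    cases: list[PatientCase],
    labels: list[OmiLabel],
    stemi_positive: Optional[dict[str, bool]] = None,
) -> dict:
    """Cohort-characteristics summary in the layout of the study's Table 1.

    Counts, percentages (one decimal, half-away-from-zero), medians with
    IQR for hours until angiography, and early-angiography fractions, for
    the whole cohort and the OMI / NOMI subsets.  ``stemi_positive`` maps
    patient id to the comparator verdict (not-applicable treated negative).
    """
    if not cases:
        raise InputError("empty cohort")
    if len(cases) != len(labels):
        raise InputError("cases and labels length mismatch")
    keep = [
        (c, l) for c, l in zip(cases, labels) if l.status not in ("EXCLUDED",)
    ]
    n = len(keep)
    by = {"OMI": [], "NOMI": []}
    for c, l in keep:
        if l.status in by:
            by[l.status].append(c)
    n_omi, n_nomi = len(by["OMI"]), len(by["NOMI"])
    n_ami = n_omi + n_nomi
    n_excluded = len(cases) - n
    n_review = sum(1 for _, l in keep if l.status == "NEEDS_REVIEW")

    summary: dict = {
        "n_patients": n,
        "n_excluded": n_excluded,
        "n_needs_review": n_review,
        "n_omi": n_omi,
        "n_nomi": n_nomi,
        "n_ami": n_ami,
        "omi_pct": round_pct(n_omi, n),
        "nomi_pct": round_pct(n_nomi, n),
        "ami_pct": round_pct(n_ami, n),
        "omi_share_of_ami_pct": round_pct(n_omi, n_ami) if n_ami else None,
        "female_pct": round_pct(
            sum(1 for c, _ in keep if c.sex == "female"), n
        ),
    }
    for cls, subset in (("all", [c for c, _ in keep]),) + tuple(by.items()):
        m = len(subset)
        if m == 0:
            continue
        key = cls.lower()
        summary[f"{key}_n"] = m
        summary[f"{key}_female_pct"] = round_pct(
            sum(1 for c in subset if c.sex == "female"), m
        )
        for horizon, attr in (
            ("30d", "died_30d"),
            ("180d", "died_180d"),
            ("1y", "died_1y"),
        ):
            deaths = sum(1 for c in subset if getattr(c.registry, attr))
            summary[f"{key}_mortality_{horizon}_n"] = deaths
            summary[f"{key}_mortality_{horizon}_pct"] = round_pct(deaths, m)
        hours = [
            c.registry.hours_to_angiography
            for c in subset
            if c.registry.hours_to_angiography is not None
        ]
        med = _median_iqr(hours)
        summary[f"{key}_hours_to_angio_median_iqr"] = med
        for label_h, h in (("90min", 1.5), ("2h", 2.0), ("3h", 3.0), ("6h", 6.0)):
            k = sum(1 for t in hours if t <= h)
            summary[f"{key}_angio_within_{label_h}_n"] = k
            summary[f"{key}_angio_within_{label_h}_pct"] = round_pct(k, m)
    if stemi_positive is not None:
        pos_all = sum(
            1 for c, _ in keep if stemi_positive.get(c.patient_id, False)
        )
        summary["stemi_positive_n"] = pos_all
        summary["stemi_positive_pct"] = round_pct(pos_all, n)
        for cls in ("OMI", "NOMI"):
            subset = by[cls]
            if subset:
                k = sum(
                    1 for c in subset if stemi_positive.get(c.patient_id, False)
                )
                summary[f"{cls.lower()}_stemi_positive_n"] = k
                summary[f"{cls.lower()}_stemi_positive_pct"] = round_pct(
                    k, len(subset)
                )
    return summary
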