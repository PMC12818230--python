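"""End-to-end orchestration: simulate → annotate → STEMI comparator → split
→ encoder → embeddings → fusion → matched-specificity evaluation.

Two entry points:

* :func:`run_study` — an in-memory run returning a :class:`StudyResult`;
  used programmatically and by the reproduction script.
* :func:`run_pipeline` — a staged, resumable run against a directory, each
  stage reading and writing plain artifacts (CSV/JSON + one array store for
  waveforms) and recording digests, seeds and timings in a manifest.

All stage seeds are derived deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation, ecg_encoder, evaluation, fusion, stemi_criteria
from . import synthetic_cohort as sc
from .types import InputError, PatientCase

logger = logging.getLogger("omipipe")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[omipipe:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    annotation: annotation.AnnotationConfig = field(
        default_factory=annotation.AnnotationConfig
    )
    encoder: ecg_encoder.EncoderConfig = field(
        default_factory=ecg_encoder.EncoderConfig
    )
    split: evaluation.SplitConfig = field(default_factory=evaluation.SplitConfig)
    eval: evaluation.EvalConfig = field(default_factory=evaluation.EvalConfig)
    j_offset_ms: float = stemi_criteria.DEFAULT_J_OFFSET_MS
    masks: str = "cumulative"  # or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        # stage seeds derived from the master seed
        self.cohort.seed = derive_seed(self.seed, "simulate")
        self.split.seed = derive_seed(self.seed, "split")
        self.encoder.seed = derive_seed(self.seed, "encoder")
        self.eval.seed = derive_seed(self.seed, "eval")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "cohort": sc.CohortConfig,
            "annotation": annotation.AnnotationConfig,
            "encoder": ecg_encoder.EncoderConfig,
            "split": evaluation.SplitConfig,
            "eval": evaluation.EvalConfig,
        }
        for key, klass in sections.items():
            section = dict(raw.get(key, {}))
            for k in ("input_leads", "channels", "fractions"):
                if k in section:
                    section[k] = tuple(section[k])
            kwargs[key] = klass(**section)
        for key in ("j_offset_ms", "masks", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _ci_dict(ci: Optional[evaluation.MetricCI]) -> Optional[dict]:
    if ci is None:
        return None
    return {
        "point": ci.point,
        "lo": ci.lo,
        "hi": ci.hi,
        "n_undefined_resamples": ci.n_undefined_resamples,
    }


def report_to_dict(report: evaluation.MetricsReport) -> dict:
    return {
        "cohort": report.cohort,
        "n": report.n,
        "threshold": report.threshold,
        "auc": _ci_dict(report.auc),
        "sensitivity": _ci_dict(report.sensitivity),
        "specificity": _ci_dict(report.specificity),
        "ppv": _ci_dict(report.ppv),
        "npv": _ci_dict(report.npv),
    }


@dataclass
class StudyResult:
    config: PipelineConfig
    cases: list[PatientCase]
    labels: list[annotation.OmiLabel]
    stemi_verdicts: dict[str, stemi_criteria.StemiVerdict]
    summary: dict
    split_assignment: dict[str, str]          # patient_id -> split
    target_specificity: float
    mask_reports: dict[str, evaluation.MetricsReport]
    mask_models: dict[str, fusion.FusionModel]
    stemi_report_reduced: evaluation.MetricsReport
    stemi_report_full: evaluation.MetricsReport
    sensitivity_difference: evaluation.MetricCI
    subgroup_reports: dict[str, evaluation.MetricsReport]
    encoder_tuning_auc: Optional[float]


def _eligible(labels: list[annotation.OmiLabel]) -> list[bool]:
    return [l.status in ("OMI", "NOMI", "NO_AMI") for l in labels]


def run_study(config: PipelineConfig) -> StudyResult:
    """Run the whole study in memory and return every intermediate result."""
    t0 = time.time()
    _log("simulate", f"generating cohort of {config.cohort.n_patients} visits")
    cases = sc.generate_cohort(config.cohort)

    _log("annotate", "applying exclusions and the OMI annotation tree")
    labels = annotation.annotate_cohort(cases, config.annotation)

    _log("stemi", "evaluating the STEMI criteria on index ECGs")
    verdicts: dict[str, stemi_criteria.StemiVerdict] = {}
    for case, label in zip(cases, labels):
        if label.status == "EXCLUDED":
            continue
        verdicts[case.patient_id] = stemi_criteria.stemi_verdict_for_case(
            case, config.j_offset_ms
        )
    stemi_pos = {pid: v.positive for pid, v in verdicts.items()}
    summary = annotation.cohort_summary(cases, labels, stemi_pos)

    keep = _eligible(labels)
    eligible = [c for c, k in zip(cases, keep) if k]
    y = np.array(
        [l.status == "OMI" for l, k in zip(labels, keep) if k], dtype=int
    )
    label_map = {c.patient_id: int(v) for c, v in zip(eligible, y)}

    _log("split", "stratified train/tune/validate split")
    assignment = evaluation.stratified_split(y, config.split)
    split_of = {c.patient_id: a for c, a in zip(eligible, assignment)}
    by_split = {
        s: [c for c, a in zip(eligible, assignment) if a == s]
        for s in evaluation.SPLIT_NAMES
    }
    y_by_split = {
        s: np.array([label_map[c.patient_id] for c in by_split[s]])
        for s in evaluation.SPLIT_NAMES
    }

    _log("train-encoder", "training the residual ECG encoder")
    train_pairs = ecg_encoder.augment_training_set(
        by_split["train"], label_map, config.encoder.input_leads
    )
    tune_pairs = ecg_encoder.augment_training_set(
        by_split["tune"], label_map, config.encoder.input_leads
    )
    encoder = ecg_encoder.train_encoder(train_pairs, tune_pairs, config.encoder)

    _log("embed", "extracting crop-averaged embeddings for index ECGs")
    embeddings = {
        c.patient_id: ecg_encoder.embed(encoder, c.index_ecg).vector
        for c in eligible
    }

    # comparator specificity on the tuning set (not-applicable = negative)
    tune_y = y_by_split["tune"].astype(bool)
    tune_verdicts = np.array(
        [stemi_pos[c.patient_id] for c in by_split["tune"]], dtype=bool
    )
    neg = ~tune_y
    target_specificity = float(np.mean(~tune_verdicts[neg]))
    _log("evaluate", f"comparator tuning specificity {target_specificity:.4f}")

    mask_list = (
        fusion.all_masks() if config.masks == "all" else fusion.cumulative_masks()
    )
    grid = fusion.ablation_grid(
        fusion.AblationData(
            cases_by_split=by_split,
            labels_by_split=y_by_split,
            embeddings=embeddings,
            target_specificity=target_specificity,
            eval_config=config.eval,
        ),
        mask_list,
    )
    mask_models = {name: model for name, (model, _) in grid.items()}
    mask_reports = {name: report for name, (_, report) in grid.items()}

    # STEMI criteria on the validation set: reduced cohort (no LBBB/LVH/VP)
    # as the primary comparator analysis, full cohort treating
    # not-applicable as negative as the secondary one.
    val_cases = by_split["validate"]
    val_y = y_by_split["validate"].astype(bool)
    val_verdict_objs = [verdicts[c.patient_id] for c in val_cases]
    val_pred = np.array([v.positive for v in val_verdict_objs], dtype=bool)
    applicable = np.array(
        [v.verdict != "not_applicable" for v in val_verdict_objs], dtype=bool
    )
    stemi_full = evaluation.evaluate_binary(
        val_pred, val_y, config.eval, cohort="validation[stemi,full]"
    )
    stemi_reduced = evaluation.evaluate_binary(
        val_pred[applicable],
        val_y[applicable],
        config.eval,
        cohort="validation[stemi,no-LBBB/LVH/VP]",
    )

    # paired sensitivity difference: full-mask model vs STEMI criteria
    full_name = fusion.FeatureGroupMask(True, True, True, True).name
    full_model = mask_models[full_name]
    val_frame = fusion.build_feature_frame(
        val_cases, embeddings, full_model.mask
    )
    val_scores = fusion.predict_risk(full_model, val_frame)
    threshold = mask_reports[full_name].threshold

    def model_sens(idx: np.ndarray) -> Optional[float]:
        return evaluation.confusion_metrics(
            val_scores[idx] >= threshold, val_y[idx]
        ).sensitivity

    def stemi_sens(idx: np.ndarray) -> Optional[float]:
        return evaluation.confusion_metrics(val_pred[idx], val_y[idx]).sensitivity

    sens_diff = evaluation.bootstrap_difference(
        model_sens, stemi_sens, len(val_y), config.eval
    )

    # subgroup analyses with the global threshold: sex, reduced cohort
    female = np.array([c.sex == "female" for c in val_cases])
    subgroups = evaluation.subgroup_eval(
        val_scores,
        val_y,
        threshold,
        {
            "female": female,
            "male": ~female,
            "no-LBBB/LVH/VP": applicable,
        },
        config.eval,
    )
    _log("evaluate", f"finished in {time.time() - t0:.1f} s")
    return StudyResult(
        config=config,
        cases=cases,
        labels=labels,
        stemi_verdicts=verdicts,
        summary=summary,
        split_assignment=split_of,
        target_specificity=target_specificity,
        mask_reports=mask_reports,
        mask_models=mask_models,
        stemi_report_reduced=stemi_reduced,
        stemi_report_full=stemi_full,
        sensitivity_difference=sens_diff,
        subgroup_reports=subgroups,
        encoder_tuning_auc=encoder.tuning_auc_,
    )


# ---------------------------------------------------------------------------
# Staged, resumable directory-based run
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_ci(ci: Optional[dict], scale: float = 100.0) -> str:
    if ci is None or ci.get("point") is None:
        return "N/A"
    out = f"{scale * ci['point']:.1f}"
    if ci.get("lo") is not None:
        out += f" ({scale * ci['lo']:.1f}-{scale * ci['hi']:.1f})"
    return out


def make_report(result_dict: dict) -> str:
    """Human-readable summary: cohort table plus metrics-by-mask table."""
    lines = ["== Cohort =="]
    summary = result_dict["summary"]
    for key in (
        "n_patients",
        "n_excluded",
        "n_omi",
        "n_nomi",
        "n_ami",
        "omi_pct",
        "omi_share_of_ami_pct",
        "omi_mortality_30d_pct",
        "nomi_mortality_30d_pct",
        "omi_angio_within_90min_pct",
        "stemi_positive_n",
        "omi_stemi_positive_pct",
    ):
        if key in summary and summary[key] is not None:
            lines.append(f"{key}: {summary[key]}")
    lines.append("")
    lines.append("== Validation metrics (percent, bootstrap 95% CI) ==")
    header = f"{'inputs':<34}{'AUC':>20}{'Sens':>20}{'Spec':>20}{'PPV':>20}{'NPV':>20}"
    lines.append(header)
    for name, rep in result_dict["mask_reports"].items():
        lines.append(
            f"{name:<34}"
            f"{_fmt_ci(rep['auc']):>20}"
            f"{_fmt_ci(rep['sensitivity']):>20}"
            f"{_fmt_ci(rep['specificity']):>20}"
            f"{_fmt_ci(rep['ppv']):>20}"
            f"{_fmt_ci(rep['npv']):>20}"
        )
    for label, key in (
        ("STEMI criteria (no LBBB/LVH/VP)", "stemi_report_reduced"),
        ("STEMI criteria (full cohort)", "stemi_report_full"),
    ):
        rep = result_dict[key]
        lines.append(
            f"{label:<34}{'N/A':>20}"
            f"{_fmt_ci(rep['sensitivity']):>20}"
            f"{_fmt_ci(rep['specificity']):>20}"
            f"{_fmt_ci(rep['ppv']):>20}"
            f"{_fmt_ci(rep['npv']):>20}"
        )
    diff = result_dict["sensitivity_difference"]
    lines.append("")
    lines.append(
        "Sensitivity difference, full model minus STEMI criteria: "
        f"{_fmt_ci(diff)}"
    )
    lines.append(
        f"Comparator tuning specificity: "
        f"{100 * result_dict['target_specificity']:.1f}"
    )
    return "\n".join(lines)


def result_to_dict(result: StudyResult) -> dict:
    return {
        "summary": result.summary,
        "target_specificity": result.target_specificity,
        "mask_reports": {
            name: report_to_dict(rep) for name, rep in result.mask_reports.items()
        },
        "stemi_report_reduced": report_to_dict(result.stemi_report_reduced),
        "stemi_report_full": report_to_dict(result.stemi_report_full),
        "sensitivity_difference": _ci_dict(result.sensitivity_difference),
        "subgroup_reports": {
            name: report_to_dict(rep)
            for name, rep in result.subgroup_reports.items()
        },
        "encoder_tuning_auc": result.encoder_tuning_auc,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Staged run against a directory; completed stages are skipped.

    Returns the run manifest (config echo, seeds, artifact digests,
    timings).  Deleting an intermediate artifact and re-running resumes
    from that stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_echo(config),
        "seeds": {
            stage: derive_seed(config.seed, stage)
            for stage in ("simulate", "split", "encoder", "eval")
        },
        "stages": {},
    }

    def stage(name: str, outputs: list[str], fn) -> None:
        paths = [out / o for o in outputs]
        t0 = time.time()
        if all(p.exists() for p in paths):
            _log(name, "outputs exist, skipping")
            status = "skipped"
        else:
            fn()
            missing = [str(p) for p in paths if not p.exists()]
            if missing:
                raise InputError(f"stage {name} did not produce: {missing}")
            status = "run"
        manifest["stages"][name] = {
            "status": status,
            "seconds": round(time.time() - t0, 3),
            "outputs": {o: _digest(out / o) for o in outputs},
        }

    state: dict = {}

    def _load_cases() -> list[PatientCase]:
        if "cases" not in state:
            state["cases"] = sc.load_cohort(out)
        return state["cases"]

    stage(
        "simulate",
        ["cases.csv", "registry.csv", "ecg_index.csv", "waveforms.npz"],
        lambda: sc.save_cohort(sc.generate_cohort(config.cohort), out),
    )

    def do_annotate() -> None:
        cases = _load_cases()
        labels = annotation.annotate_cohort(cases, config.annotation)
        pd.DataFrame(
            {
                "patient_id": [c.patient_id for c in cases],
                "status": [l.status for l in labels],
                "rule_fired": [l.rule_fired for l in labels],
                "exclusion_reason": [l.exclusion_reason for l in labels],
            }
        ).to_csv(out / "labels.csv", index=False)

    stage("annotate", ["labels.csv"], do_annotate)

    def do_stemi() -> None:
        cases = _load_cases()
        rows = []
        for case in cases:
            if not case.ecgs:
                continue
            v = stemi_criteria.stemi_verdict_for_case(case, config.j_offset_ms)
            rows.append(
                {
                    "patient_id": case.patient_id,
                    "verdict": v.verdict,
                    "contiguous_group": v.contiguous_group,
                    "leads_meeting": "|".join(sorted(v.leads_meeting)),
                }
            )
        pd.DataFrame(rows).to_csv(out / "stemi.csv", index=False)

    stage("stemi", ["stemi.csv"], do_stemi)

    def do_split() -> None:
        labels_df = pd.read_csv(out / "labels.csv")
        elig = labels_df[labels_df.status.isin(["OMI", "NOMI", "NO_AMI"])]
        y = (elig.status == "OMI").to_numpy(dtype=int)
        assignment = evaluation.stratified_split(y, config.split)
        pd.DataFrame(
            {"patient_id": elig.patient_id, "split": assignment}
        ).to_csv(out / "split.csv", index=False)

    stage("split", ["split.csv"], do_split)

    def do_rest() -> None:
        # encoder training, embeddings, fusion and evaluation run off the
        # in-memory study to keep one code path
        result = run_study(config)
        state["result"] = result
        rd = result_to_dict(result)
        (out / "report.json").write_text(json.dumps(rd, indent=2))
        (out / "report.txt").write_text(make_report(rd))

    stage("evaluate", ["report.json", "report.txt"], do_rest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, frozenset)):
            return list(obj)
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(config)
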