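"""Feature assembly, leakage-free preprocessing, and the linear risk model.

Model inputs are grouped by when they become available at the ED: the
patient's history (age, sex, diagnosis/medication flags), the 50-dim ECG
embedding, point-of-care labs (hemoglobin, creatinine, glucose), and the
initial hs-cTnT.  Blocks are concatenated in a fixed order; missing labs are
mean-imputed with missingness-indicator features retained.  Troponin and
POC labs are Yeo-Johnson power-transformed then standardized; all other
scalars are standardized.  Every preprocessing statistic is fitted on the
training rows only.  The final model is an L2-regularized logistic
regression with the penalty strength chosen on tuning-set discrimination.

Registry-derived fields are firewalled: a feature vector that names any
registry outcome field is rejected at construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import PowerTransformer

from .evaluation import (
    EvalConfig,
    MetricsReport,
    evaluate_model,
    match_specificity_threshold,
    roc_auc,
)
from .types import (
    HISTORY_FLAGS,
    InputError,
    MEDICATION_FLAGS,
    PatientCase,
    POC_LABS,
    REGISTRY_FIELDS,
)

GROUPS = ("history", "ecg", "poc", "troponin")
# columns given the Yeo-Johnson transform (right-skewed labs)
SKEWED_FEATURES = set(POC_LABS) | {"hs_ctnt_initial_ng_l"}


@dataclass(frozen=True)
class FeatureGroupMask:
    history: bool = False
    ecg: bool = False
    poc: bool = False
    troponin: bool = False

    def __post_init__(self) -> None:
        if not any((self.history, self.ecg, self.poc, self.troponin)):
            raise InputError("at least one feature group must be enabled")

    @property
    def name(self) -> str:
        return "+".join(g for g in GROUPS if getattr(self, g))


def all_masks() -> list[FeatureGroupMask]:
    """All 15 non-empty feature-group combinations."""
    masks = []
    for bits in itertools.product((False, True), repeat=4):
        if any(bits):
            masks.append(FeatureGroupMask(*bits))
    return masks


def cumulative_masks() -> list[FeatureGroupMask]:
    """The availability-ordered combinations reported in the main comparison."""
    return [
        FeatureGroupMask(history=True),
        FeatureGroupMask(history=True, ecg=True),
        FeatureGroupMask(history=True, ecg=True, poc=True),
        FeatureGroupMask(history=True, ecg=True, troponin=True),
        FeatureGroupMask(history=True, ecg=True, poc=True, troponin=True),
    ]


@dataclass
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        leaked = set(self.names) & REGISTRY_FIELDS
        if leaked:
            raise InputError(
                f"registry-derived fields rejected from features: {sorted(leaked)}"
            )
        if len(self.names) != len(self.values):
            raise InputError("names/values length mismatch")


def build_features(
    case: PatientCase,
    embedding: Optional[np.ndarray],
    mask: FeatureGroupMask,
) -> FeatureVector:
    """Concatenate the enabled feature blocks for one visit.

    Missing labs are encoded as NaN with an indicator of 1; imputation
    happens later in the fitted preprocessor.
    """
    names: list[str] = []
    values: list[float] = []
    if mask.history:
        names += ["age", "sex_male"]
        values += [case.age, 1.0 if case.sex == "male" else 0.0]
        for flag in HISTORY_FLAGS:
            names.append(flag)
            values.append(float(case.history_flags.get(flag, False)))
        for flag in MEDICATION_FLAGS:
            names.append(flag)
            values.append(float(case.medication_flags.get(flag, False)))
    if mask.ecg:
        if embedding is None:
            raise InputError("mask.ecg is set but no embedding was provided")
        emb = np.asarray(embedding, dtype=float)
        names += [f"ecg_{i}" for i in range(emb.size)]
        values += list(emb)
    if mask.poc:
        for lab in POC_LABS:
            v = case.poc_labs.get(lab)
            names += [lab, f"{lab}_missing"]
            values += [np.nan if v is None else float(v), float(v is None)]
    if mask.troponin:
        v = case.hs_ctnt_initial_ng_l
        names += ["hs_ctnt_initial_ng_l", "hs_ctnt_initial_ng_l_missing"]
        values += [np.nan if v is None else float(v), float(v is None)]
    return FeatureVector(names=tuple(names), values=np.asarray(values, dtype=float))


def build_feature_frame(
    cases: Sequence[PatientCase],
    embeddings: Optional[dict[str, np.ndarray]],
    mask: FeatureGroupMask,
) -> pd.DataFrame:
    """Feature matrix (one row per visit, NaN for missing labs)."""
    rows = []
    for case in cases:
        emb = embeddings.get(case.patient_id) if (embeddings and mask.ecg) else None
        fv = build_features(case, emb, mask)
        rows.append(fv.values)
    names = fv.names
    return pd.DataFrame(
        np.vstack(rows), columns=names, index=[c.patient_id for c in cases]
    )


class Preprocessor:
    """Impute-then-transform chain fitted exclusively on training rows."""

    def __init__(self) -> None:
        self.columns: tuple[str, ...] = ()
        self.imputation_means: dict[str, float] = {}
        self.transforms: dict[str, tuple] = {}
        self.fitted = False

    def fit(self, frame: pd.DataFrame) -> "Preprocessor":
        if len(frame) < 2:
            raise InputError("need >= 2 training rows to fit the preprocessor")
        self.columns = tuple(frame.columns)
        for col in self.columns:
            x = frame[col].to_numpy(dtype=float)
            observed = x[np.isfinite(x)]
            mean = float(observed.mean()) if observed.size else 0.0
            self.imputation_means[col] = mean
            filled = np.where(np.isfinite(x), x, mean)
            if col.endswith("_missing"):
                self.transforms[col] = ("passthrough",)
                continue
            sd = float(filled.std())
            if sd < 1e-12:
                warnings.warn(f"zero-variance feature {col!r}: passthrough")
                self.transforms[col] = ("passthrough",)
            elif col in SKEWED_FEATURES:
                pt = PowerTransformer(method="yeo-johnson", standardize=True)
                pt.fit(filled.reshape(-1, 1))
                self.transforms[col] = ("yeo-johnson", pt)
            else:
                self.transforms[col] = ("standardize", float(filled.mean()), sd)
        self.fitted = True
        return self

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise InputError("preprocessor has not been fitted")
        if tuple(frame.columns) != self.columns:
            raise InputError("feature columns do not match the fitted preprocessor")
        out = np.empty((len(frame), len(self.columns)))
        for j, col in enumerate(self.columns):
            x = frame[col].to_numpy(dtype=float)
            x = np.where(np.isfinite(x), x, self.imputation_means[col])
            spec = self.transforms[col]
            if spec[0] == "passthrough":
                out[:, j] = x
            elif spec[0] == "yeo-johnson":
                out[:, j] = spec[1].transform(x.reshape(-1, 1))[:, 0]
            else:
                out[:, j] = (x - spec[1]) / spec[2]
        return out


def fit_preprocessor(training_frame: pd.DataFrame) -> Preprocessor:
    return Preprocessor().fit(training_frame)


@dataclass
class FusionModel:
    mask: FeatureGroupMask
    preprocessor: Preprocessor
    classifier: LogisticRegression
    regularization_c: float
    tuning_auc: Optional[float] = None


_C_GRID = np.logspace(-3, 3, 13)


def fit_classifier(
    train_frame: pd.DataFrame,
    train_labels: np.ndarray,
    tune_frame: pd.DataFrame,
    tune_labels: np.ndarray,
    mask: FeatureGroupMask,
) -> FusionModel:
    """L2 logistic regression; penalty strength selected on tuning AUC."""
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("training data must contain both classes")
    prep = fit_preprocessor(train_frame)
    X = prep.transform(train_frame)
    Xt = prep.transform(tune_frame)
    yt = np.asarray(tune_labels, dtype=int)
    tune_ok = len(np.unique(yt)) == 2
    best = (None, -np.inf, 1.0)
    for c in _C_GRID:
        # default penalty is the L2 ridge; the grid is expressed per 1000
        # training rows so the fit is invariant to row duplication
        clf = LogisticRegression(
            C=float(c) * 1000.0 / len(y), max_iter=5000, solver="lbfgs"
        )
        clf.fit(X, y)
        if not tune_ok:
            best = (clf, np.nan, float(c))
            break
        auc = roc_auc(clf.predict_proba(Xt)[:, 1], yt)
        if auc > best[1]:
            best = (clf, auc, float(c))
    clf, auc, c = best
    if not np.all(np.isfinite(clf.coef_)):
        raise InputError("non-finite coefficients in fitted classifier")
    return FusionModel(
        mask=mask,
        preprocessor=prep,
        classifier=clf,
        regularization_c=c,
        tuning_auc=None if not tune_ok else float(auc),
    )


def predict_risk(model: FusionModel, frame: pd.DataFrame) -> np.ndarray:
    """OMI risk in (0, 1) for each row of a feature frame."""
    X = model.preprocessor.transform(frame)
    return model.classifier.predict_proba(X)[:, 1]


@dataclass
class AblationData:
    """Split cohort plus precomputed embeddings for the ablation grid."""

    cases_by_split: dict[str, list[PatientCase]]
    labels_by_split: dict[str, np.ndarray]
    embeddings: Optional[dict[str, np.ndarray]]
    target_specificity: float
    eval_config: EvalConfig = field(default_factory=EvalConfig)


def ablation_grid(
    data: AblationData, masks: Optional[Sequence[FeatureGroupMask]] = None
) -> dict[str, tuple[FusionModel, MetricsReport]]:
    """Fit and evaluate one model per feature-group mask.

    Each model's decision threshold is matched to the target specificity on
    the tuning set; reports are computed on the validation split.
    """
    if masks is None:
        masks = all_masks()
    results: dict[str, tuple[FusionModel, MetricsReport]] = {}
    for mask in masks:
        frames = {
            split: build_feature_frame(
                data.cases_by_split[split], data.embeddings, mask
            )
            for split in ("train", "tune", "validate")
        }
        model = fit_classifier(
            frames["train"],
            data.labels_by_split["train"],
            frames["tune"],
            data.labels_by_split["tune"],
            mask,
        )
        tune_scores = predict_risk(model, frames["tune"])
        threshold, _ = match_specificity_threshold(
            tune_scores,
            data.labels_by_split["tune"],
            target_specificity=data.target_specificity,
        )
        val_scores = predict_risk(model, frames["validate"])
        report = evaluate_model(
            val_scores,
            data.labels_by_split["validate"],
            threshold,
            data.eval_config,
            cohort=f"validation[{mask.name}]",
        )
        results[mask.name] = (model, report)
    return results
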