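"""Clinical table handling and the GTV1-SliceNum feature.

The cohort CSV follows the Lung1 clinical schema (PatientID, age,
clinical.T.Stage, Clinical.N.Stage, Clinical.M.Stage, Overall.Stage,
Histology, gender, Survival.time, deadstatus.event).  Survival.time is days
from treatment start; deadstatus.event is 1 for an observed death and 0 for a
censored follow-up.

GTV1-SliceNum is the number of axial CT slices carrying a GTV-1 contour — a
discrete proxy for the tumour's cranio-caudal extent (slice thickness × slice
count), which tracks the tumour-thickness/survival association reported
across cancer sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TWO_YEARS_DAYS = 730

CLINICAL_COLUMNS = [
    "PatientID", "age", "clinical.T.Stage", "Clinical.N.Stage",
    "Clinical.M.Stage", "Overall.Stage", "Histology", "gender",
    "Survival.time", "deadstatus.event",
]

_MANDATORY = {"PatientID", "Survival.time", "deadstatus.event"}


@dataclass
class PatientRecord:
    patient_id: str
    age: float | None  # years
    t_stage: float | None
    n_stage: float | None
    m_stage: float | None
    overall_stage: str | None
    histology: str | None
    gender: str | None
    survival_time: float  # days from treatment start
    deadstatus_event: int  # 1 death observed, 0 censored
    gtv1_slice_num: int | None = None

    def __post_init__(self) -> None:
        if self.survival_time <= 0:
            raise ValueError(f"survival_time must be > 0, got {self.survival_time}")
        if self.deadstatus_event not in (0, 1):
            raise ValueError("deadstatus_event must be 0 or 1")


@dataclass
class LabeledCohort:
    records: list[PatientRecord]
    labels: np.ndarray  # 1 = survived beyond two years
    policy: str  # "discard_censored" | "include_censored"


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def _age_years(v) -> float | None:
    """Normalize age to years; values above 200 are taken as days."""
    a = _opt_float(v)
    if a is None:
        return None
    if a > 200:
        return a / 365.25
    return a


def load_clinical_csv(path: str | Path) -> list[PatientRecord]:
    """Read a Lung1-schema clinical CSV into typed records.

    Missing cells stay missing (None); a missing mandatory column raises a
    ``ValueError`` naming it.
    """
    df = pd.read_csv(path)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"clinical CSV is missing mandatory column {col!r}")
    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            patient_id=str(row["PatientID"]),
            age=_age_years(row.get("age")),
            t_stage=_opt_float(row.get("clinical.T.Stage")),
            n_stage=_opt_float(row.get("Clinical.N.Stage")),
            m_stage=_opt_float(row.get("Clinical.M.Stage")),
            overall_stage=_opt_str(row.get("Overall.Stage")),
            histology=_opt_str(row.get("Histology")),
            gender=_opt_str(row.get("gender")),
            survival_time=float(row["Survival.time"]),
            deadstatus_event=int(row["deadstatus.event"]),
        ))
    return records


def gtv1_slice_num(series, ss, *, roi_name: str = "GTV-1",
                   roi_regex: str | None = None) -> int:
    """Count of distinct CT slices carrying at least one GTV-1 contour."""
    from .dicom_io import gtv1_slice_uids

    return len(gtv1_slice_uids(series, ss, roi_name=roi_name, roi_regex=roi_regex))


def attach_gtv1_slice_num(records: list[PatientRecord],
                          counts: dict[str, int]) -> list[PatientRecord]:
    """Return records with the GTV1-SliceNum feature filled in.

    Patients without a count (no usable GTV-1 ROI) are dropped, mirroring the
    cohort-exclusion rule for unusable structure sets.
    """
    kept = []
    for r in records:
        if r.patient_id in counts:
            r.gtv1_slice_num = int(counts[r.patient_id])
            kept.append(r)
        else:
            warnings.warn(f"patient {r.patient_id} has no GTV-1 slice count; excluded",
                          stacklevel=2)
    return kept


def label_two_year(records: list[PatientRecord],
                   policy: str = "discard_censored") -> LabeledCohort:
    """Binary 2-year survival labels: 1 iff survival_time > 730 days (strict).

    ``discard_censored`` removes censored patients (their class is unknown).
    ``include_censored`` keeps them: censored follow-up beyond 730 days proves
    survival past two years (label 1); censored below 730 days is labeled 0
    even though the true class is unknowable — callers should treat that
    subset as noisy.
    """
    if policy not in ("discard_censored", "include_censored"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "discard_censored":
        kept = [r for r in records if r.deadstatus_event == 1]
    else:
        kept = list(records)
    labels = np.array([1 if r.survival_time > TWO_YEARS_DAYS else 0 for r in kept],
                      dtype=np.int64)
    return LabeledCohort(records=kept, labels=labels, policy=policy)


_ORDINAL = ["age", "t_stage", "n_stage", "m_stage", "gtv1_slice_num"]
_CATEGORICAL = ["overall_stage", "histology", "gender"]


def cohort_features(cohort: LabeledCohort, *, extra: dict[str, np.ndarray] | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Encode a labeled cohort as a numeric design matrix.

    Ordinal features get median imputation, categoricals get mode imputation
    and stable (sorted-category) integer codes; an ``extra`` mapping lets
    callers inject synthetic columns (e.g. a pure-noise control feature).
    """
    rows = {name: [getattr(r, name) for r in cohort.records] for name in _ORDINAL + _CATEGORICAL}
    df = pd.DataFrame(rows)
    for name in _ORDINAL:
        col = pd.to_numeric(df[name], errors="coerce")
        df[name] = col.fillna(col.median())
    for name in _CATEGORICAL:
        col = df[name].astype("object")
        mode = col.mode(dropna=True)
        fill = mode.iloc[0] if not mode.empty else "missing"
        col = col.fillna(fill)
        cats = sorted(col.unique())
        df[name] = col.map({c: i for i, c in enumerate(cats)}).astype(np.int64)
    if extra:
        for name, values in extra.items():
            df[name] = np.asarray(values)
    return df, cohort.labels.copy()


def feature_importance(cohort: LabeledCohort, model: str = "random_forest",
                       seed: int = 0, *, extra: dict[str, np.ndarray] | None = None
                       ) -> pd.DataFrame:
    """Impurity-based feature importances, normalized and ranked descending."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.tree import DecisionTreeClassifier

    X, y = cohort_features(cohort, extra=extra)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort has a single class; importances undefined")
    if model == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif model == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(X.values, y)
    imp = np.asarray(clf.feature_importances_, dtype=np.float64)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    out = pd.DataFrame({"feature": X.columns, "importance": imp})
    return out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


def write_augmented_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Clinical table with the GTV1-SliceNum column appended."""
    rows = []
    for r in records:
        rows.append({
            "PatientID": r.patient_id, "age": r.age,
            "clinical.T.Stage": r.t_stage, "Clinical.N.Stage": r.n_stage,
            "Clinical.M.Stage": r.m_stage, "Overall.Stage": r.overall_stage,
            "Histology": r.histology, "gender": r.gender,
            "Survival.time": r.survival_time, "deadstatus.event": r.deadstatus_event,
            "GTV1-SliceNum": r.gtv1_slice_num,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
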