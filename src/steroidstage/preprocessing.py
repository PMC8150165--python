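"""Feature construction from raw urinary steroid concentrations.

Pipeline order for the classifier features: creatinine correction
(ug steroid / g creatinine) → log10 transform with a per-feature detection
floor → optional appending of clinical covariates (age, BMI, sex) →
z-scoring with statistics fitted on the training subjects only.

Enzyme-activity ratios (11β-HSD1 = (THF+5αTHF)/THE, A-ring reductase =
5αTHF/THF) and total glucocorticoid metabolite excretion are computed on the
creatinine-corrected, non-log values; the creatinine factor cancels in the
ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "SteroidRatios",
    "TOTAL_F_METABOLITES",
    "creatinine_correct",
    "corrected_matrix",
    "half_min_positive_floor",
    "log10_transform",
    "zscore_fit_apply",
    "compute_ratios",
    "augment_covariates",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

# The 11 glucocorticoid metabolites summed as total cortisol (F) metabolites.
TOTAL_F_METABOLITES = (
    "6b_hydroxycortisol",
    "tetrahydrocortisol",
    "5a_tetrahydrocortisol",
    "a_cortol",
    "b_cortol",
    "11b_hydroxyetiocholanolone",
    "cortisone",
    "tetrahydrocortisone",
    "a_cortolone",
    "b_cortolone",
    "11_oxoetiocholanolone",
)

COVARIATE_NAMES = ("age", "bmi", "sex")


class DomainError(ValueError):
    """Input outside the operation's domain."""


@dataclass
class FeatureMatrix:
    """An n×d numeric feature table with labels.

    ``normalisation`` is ``None`` for raw/log-scale matrices and a
    ``(means, sds)`` pair (captured at fit time, population-SD convention)
    once the matrix has been z-scored.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: tuple[str, ...]
    normalisation: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = tuple(self.feature_names)
        self.labels = tuple(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.labels)} labels × {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SteroidRatios:
    """Glucocorticoid pathway summaries for one subject.

    ``flags`` names any ratio that could not be computed (zero denominator);
    the corresponding field is NaN rather than raising, so one degenerate
    subject does not abort a batch.
    """

    hsd11b1_activity: float
    a_ring_reductase_activity: float
    total_F_metabolites: float
    flags: tuple[str, ...] = ()


def creatinine_correct(concentration_ug_l, creatinine_mg_dl, subject_id=None):
    """ug steroid / g creatinine.  100 mg/dL = 1 g/L, hence the factor 100."""
    conc = np.asarray(concentration_ug_l, dtype=float)
    creat = np.asarray(creatinine_mg_dl, dtype=float)
    if np.any(creat <= 0):
        who = f" (subject {subject_id})" if subject_id is not None else ""
        raise DomainError(f"creatinine must be > 0{who}")
    if np.any(conc < 0):
        raise DomainError("steroid concentration must be >= 0")
    out = conc * 100.0 / creat
    return float(out) if out.ndim == 0 else out


def corrected_matrix(records: Sequence, panel: Sequence[str], corrected: bool = True) -> np.ndarray:
    """Stack per-subject corrected concentrations into an n×d array.

    ``corrected=False`` is the sensitivity mode: no creatinine correction,
    values expressed per 1000 mL urine (numerically equal to ug/L).
    """
    rows = []
    for r in records:
        conc = np.array([r.steroids_raw[m] for m in panel], dtype=float)
        if corrected:
            rows.append(creatinine_correct(conc, r.creatinine_mg_dl, r.subject_id))
        else:
            rows.append(conc)
    return np.vstack(rows)


def half_min_positive_floor(values: np.ndarray, fallback: float = 1.0) -> np.ndarray:
    """Per-feature floor: half the smallest positive value of each column.

    Columns with no positive entry fall back to ``fallback`` so the transform
    stays defined; such a column is constant after flooring and will be
    rejected by the z-scoring step.
    """
    values = np.asarray(values, dtype=float)
    d = values.shape[1]
    floor = np.full(d, fallback)
    for j in range(d):
        pos = values[:, j][values[:, j] > 0]
        if pos.size:
            floor[j] = 0.5 * pos.min()
    return floor


def log10_transform(values: np.ndarray, floor=None) -> np.ndarray:
    """Elementwise log10 with values below the floor raised to it.

    ``floor`` is a scalar, a per-feature vector, or ``None`` (half the
    smallest positive value per feature, computed from ``values`` itself —
    in a train/test pipeline pass the floor fitted on the training data).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise DomainError("log10 transform requires non-negative values")
    if floor is None:
        floor = half_min_positive_floor(np.atleast_2d(values))
    floor = np.asarray(floor, dtype=float)
    if np.any(floor <= 0):
        raise DomainError("floor must be > 0")
    return np.log10(np.maximum(values, floor))


def zscore_fit_apply(train: FeatureMatrix, *others: FeatureMatrix):
    """Standardise columns to mean 0, SD 1 (population SD convention).

    Statistics are fitted on ``train`` only and applied to every other
    matrix, so no information leaks from held-out subjects.  Matrices that
    already carry normalisation statistics are rejected: re-standardising a
    standardised matrix is a contract violation, not a no-op.

    Returns the transformed train matrix, or a tuple ``(train, *others)``
    when other matrices are supplied.
    """
    for fm in (train, *others):
        if fm.normalisation is not None:
            raise DomainError("matrix is already z-scored; refusing to re-standardise")
        if fm.feature_names != train.feature_names:
            raise DomainError("feature names differ between matrices")
    means = train.values.mean(axis=0)
    sds = train.values.std(axis=0)  # population (divide-by-n) SD
    bad = np.where(sds == 0)[0]
    if bad.size:
        names = ", ".join(train.feature_names[j] for j in bad)
        raise DomainError(f"zero-SD feature(s) in training data: {names}")
    norm = (means, sds)
    out = [
        replace(fm, values=(fm.values - means) / sds, normalisation=norm)
        for fm in (train, *others)
    ]
    return out[0] if not others else tuple(out)


def compute_ratios(corrected: Mapping[str, float]) -> SteroidRatios:
    """Enzyme-activity ratios and total glucocorticoid output for one subject.

    Expects creatinine-corrected (or per-litre) concentrations keyed by
    metabolite name.  Zero denominators flag the affected ratio as missing
    (NaN) instead of raising.
    """
    thf = corrected["tetrahydrocortisol"]
    athf = corrected["5a_tetrahydrocortisol"]
    the = corrected["tetrahydrocortisone"]
    missing = [m for m in TOTAL_F_METABOLITES if m not in corrected]
    if missing:
        raise DomainError(f"metabolites missing for total-F sum: {missing}")
    flags = []
    if the > 0:
        hsd11b1 = (thf + athf) / the
    else:
        hsd11b1 = math.nan
        flags.append("hsd11b1_activity")
    if thf > 0:
        a_ring = athf / thf
    else:
        a_ring = math.nan
        flags.append("a_ring_reductase_activity")
    total = float(sum(corrected[m] for m in TOTAL_F_METABOLITES))
    return SteroidRatios(
        hsd11b1_activity=float(hsd11b1),
        a_ring_reductase_activity=float(a_ring),
        total_F_metabolites=total,
        flags=tuple(flags),
    )


_COVARIATE_GETTERS = {
    "age": lambda r: r.age_years,
    "bmi": lambda r: r.bmi_kg_m2,
    "sex": lambda r: {"M": 1.0, "F": 0.0}[r.sex],
}


def augment_covariates(fm: FeatureMatrix, records: Sequence, covariates: Iterable[str]) -> FeatureMatrix:
    """Append clinical covariate columns (age in years, BMI in kg/m², sex
    coded F=0/M=1) to a steroid feature matrix.

    Columns are appended on the raw scale; they are standardised together
    with the steroid features by the downstream train-fitted z-scoring, so
    the fit/apply (no-leakage) discipline applies to them identically.
    """
    covariates = list(covariates)
    if not covariates:
        return fm
    if fm.normalisation is not None:
        raise DomainError("augment before z-scoring, not after")
    if len(records) != fm.n:
        raise DomainError("records and feature matrix row counts differ")
    unknown = [c for c in covariates if c not in _COVARIATE_GETTERS]
    if unknown:
        raise DomainError(f"unknown covariate(s): {unknown}")
    dup = [c for c in covariates if c in fm.feature_names]
    if dup or len(set(covariates)) != len(covariates):
        raise DomainError(f"duplicate covariate feature(s): {dup or covariates}")
    cols = []
    for c in covariates:
        get = _COVARIATE_GETTERS[c]
        vals = []
        bad_ids = []
        for r in records:
            v = get(r)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                bad_ids.append(r.subject_id)
            vals.append(v)
        if bad_ids:
            raise DomainError(f"missing {c} for subjects: {bad_ids}")
        cols.append(np.asarray(vals, dtype=float))
    values = np.column_stack([fm.values] + cols)
    return FeatureMatrix(
        values=values,
        feature_names=fm.feature_names + tuple(covariates),
        labels=fm.labels,
    )


def build_feature_matrix(
    records: Sequence,
    panel: Sequence[str],
    labels: Sequence[str] | None = None,
    covariates: Iterable[str] = (),
    corrected: bool = True,
    floor: np.ndarray | None = None,
) -> FeatureMatrix:
    """Raw records → log10 corrected steroid features (+ covariates).

    Output is on the log10/raw-covariate scale (``normalisation is None``);
    z-score with :func:`zscore_fit_apply` after train/test splitting.
    """
    mat = corrected_matrix(records, panel, corrected=corrected)
    logs = log10_transform(mat, floor=floor)
    fm = FeatureMatrix(
        values=logs,
        feature_names=tuple(panel),
        labels=tuple(labels if labels is not None else (r.stage for r in records)),
    )
    return augment_covariates(fm, records, covariates)


# ---------------------------------------------------------------------------
# Feature-matrix I/O: CSV of values + JSON sidecar with the normalisation.

def write_feature_matrix(fm: FeatureMatrix, csv_path, sidecar_path=None) -> None:
    df = pd.DataFrame(fm.values, columns=list(fm.feature_names))
    df.insert(0, "label", list(fm.labels))
    df.to_csv(csv_path, index=False)
    sidecar_path = sidecar_path or (str(csv_path) + ".json")
    doc = {
        "feature_names": list(fm.feature_names),
        "normalisation": None
        if fm.normalisation is None
        else {
            "means": [float(x) for x in fm.normalisation[0]],
            "sds": [float(x) for x in fm.normalisation[1]],
        },
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_feature_matrix(csv_path, sidecar_path=None) -> FeatureMatrix:
    df = pd.read_csv(csv_path)
    sidecar_path = sidecar_path or (str(csv_path) + ".json")
    with open(sidecar_path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    names = tuple(doc["feature_names"])
    norm = doc.get("normalisation")
    return FeatureMatrix(
        values=df[list(names)].to_numpy(dtype=float),
        feature_names=names,
        labels=tuple(df["label"].astype(str)),
        normalisation=None
        if norm is None
        else (np.asarray(norm["means"]), np.asarray(norm["sds"])),
    )
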