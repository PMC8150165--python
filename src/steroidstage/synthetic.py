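"""Synthetic urinary-steroid cohort generator.

The patient cohort behind the staging analysis (biopsy-staged NAFLD F0-F4,
alcohol-related cirrhosis, and healthy controls, each with a 32-metabolite
GC-MS urinary steroid panel, urinary creatinine and serum chemistry) is not
publicly deposited.  This module generates cohorts with the same statistical
structure so that every downstream stage — preprocessing, classification,
relevance ranking, panel reduction, comparator scores — can be exercised and
tested end to end.

Concentrations are simulated on the log10 scale and exponentiated, which
guarantees positivity and matches the log10 transform applied during
analysis.  Class-dependent signal enters as mean shifts (in units of the
within-class log10 SD) on contrast-specific lists of informative
metabolites; covariates and serum chemistry are drawn per class from the
published cohort demographics, so that e.g. mean FIB-4 is higher in advanced
(F3-F4) than early (F0-F2) fibrosis by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClassParams",
    "CohortSpec",
    "SubjectRecord",
    "generate_cohort",
    "ground_truth",
    "default_spec",
    "parse_contrast",
    "contrast_key",
    "cohort_to_dataframe",
    "dataframe_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "spec_to_yaml",
    "spec_from_yaml",
    "load_packaged_spec",
    "CLASS_LABELS",
    "DEFAULT_PANEL",
    "CONTRAST_F02_VS_F34",
    "CONTRAST_F03_VS_F4",
    "CONTRAST_CONTROL_VS_F04",
    "CONTRAST_CONTROL_VS_F34",
    "CONTRAST_CONTROL_VS_F4",
    "CONTRAST_F4_VS_ALCOHOL",
]

CLASS_LABELS = ("control", "F0", "F1", "F2", "F3", "F4", "alcohol_cirrhosis")

# Kleiner fibrosis stages grouped the way the binary contrasts use them.
EARLY_FIBROSIS = ("F0", "F1", "F2")
ADVANCED_FIBROSIS = ("F3", "F4")
NAFLD_STAGES = ("F0", "F1", "F2", "F3", "F4")

CONTRAST_F02_VS_F34 = "F0,F1,F2:F3,F4"
CONTRAST_F03_VS_F4 = "F0,F1,F2,F3:F4"
CONTRAST_CONTROL_VS_F04 = "control:F0,F1,F2,F3,F4"
CONTRAST_CONTROL_VS_F34 = "control:F3,F4"
CONTRAST_CONTROL_VS_F4 = "control:F4"
CONTRAST_F4_VS_ALCOHOL = "F4:alcohol_cirrhosis"

# The 26 metabolites named in the main analysis (androgen, glucocorticoid and
# mineralocorticoid metabolites) padded to the instrument's 32-steroid panel
# with configurable placeholders.
DEFAULT_PANEL = (
    "androsterone",
    "etiocholanolone",
    "dehydroepiandrosterone",
    "androstenedione",
    "11b_hydroxyetiocholanolone",
    "11_oxoetiocholanolone",
    "pregnanediol",
    "pregnanetriol",
    "pregnenediol",
    "pregnenetriol",
    "cortisol",
    "6b_hydroxycortisol",
    "cortisone",
    "tetrahydrocortisol",
    "5a_tetrahydrocortisol",
    "tetrahydrocortisone",
    "a_cortol",
    "b_cortol",
    "a_cortolone",
    "b_cortolone",
    "tetrahydrocorticosterone",
    "5a_tetrahydrocorticosterone",
    "tetrahydro_11_dehydrocorticosterone",
    "5a_tetrahydro_11_dehydrocorticosterone",
    "tetrahydro_11_deoxycorticosterone",
    "tetrahydroaldosterone",
    "steroid_27",
    "steroid_28",
    "steroid_29",
    "steroid_30",
    "steroid_31",
    "steroid_32",
)

# Typical adult spot-urine abundances, log10 ug/L.  Major glucocorticoid and
# androgen metabolites are excreted in the high hundreds to thousands of
# ug/day; corticosterone/mineralocorticoid metabolites one to two orders of
# magnitude lower.
_BASELINE_LOG10 = {
    "androsterone": 3.3,
    "etiocholanolone": 3.3,
    "dehydroepiandrosterone": 2.3,
    "androstenedione": 1.7,
    "11b_hydroxyetiocholanolone": 2.6,
    "11_oxoetiocholanolone": 2.7,
    "pregnanediol": 2.9,
    "pregnanetriol": 2.9,
    "pregnenediol": 2.2,
    "pregnenetriol": 2.3,
    "cortisol": 1.9,
    "6b_hydroxycortisol": 2.5,
    "cortisone": 2.0,
    "tetrahydrocortisol": 3.1,
    "5a_tetrahydrocortisol": 3.1,
    "tetrahydrocortisone": 3.4,
    "a_cortol": 2.5,
    "b_cortol": 2.6,
    "a_cortolone": 2.9,
    "b_cortolone": 2.8,
    "tetrahydrocorticosterone": 2.2,
    "5a_tetrahydrocorticosterone": 2.3,
    "tetrahydro_11_dehydrocorticosterone": 2.3,
    "5a_tetrahydro_11_dehydrocorticosterone": 2.2,
    "tetrahydro_11_deoxycorticosterone": 1.4,
    "tetrahydroaldosterone": 1.8,
}
_BASELINE_DEFAULT = 2.0  # placeholders


def _rank_effects(names: Sequence[str], top: float = 1.0, tail_frac: float = 0.7):
    """Effect sizes decaying linearly with discriminatory rank from ``top``
    to ``top * tail_frac``, in log10-SD units."""
    step = top * (1.0 - tail_frac) / max(len(names) - 1, 1)
    return tuple((m, round(top - step * i, 10)) for i, m in enumerate(names))


# Discriminatory rankings (most → least) reported per clinical contrast.
_TOP10_F02_VS_F34 = (
    "etiocholanolone",
    "dehydroepiandrosterone",
    "5a_tetrahydro_11_dehydrocorticosterone",
    "androstenedione",
    "5a_tetrahydrocorticosterone",
    "pregnenetriol",
    "tetrahydro_11_deoxycorticosterone",
    "tetrahydroaldosterone",
    "cortisone",
    "11_oxoetiocholanolone",
)
_TOP10_F03_VS_F4 = (
    "etiocholanolone",
    "tetrahydrocorticosterone",
    "5a_tetrahydro_11_dehydrocorticosterone",
    "tetrahydro_11_deoxycorticosterone",
    "dehydroepiandrosterone",
    "androsterone",
    "tetrahydrocortisone",
    "tetrahydrocortisol",
    "pregnenetriol",
    "5a_tetrahydrocorticosterone",
)
_TOP10_CONTROL_VS_F34 = (
    "5a_tetrahydro_11_dehydrocorticosterone",
    "11_oxoetiocholanolone",
    "etiocholanolone",
    "cortisone",
    "pregnenediol",
    "pregnanetriol",
    "tetrahydro_11_deoxycorticosterone",
    "11b_hydroxyetiocholanolone",
    "pregnanediol",
    "5a_tetrahydrocorticosterone",
)
_TOP10_CONTROL_VS_F4 = (
    "5a_tetrahydro_11_dehydrocorticosterone",
    "11_oxoetiocholanolone",
    "etiocholanolone",
    "cortisone",
    "tetrahydro_11_deoxycorticosterone",
    "pregnenediol",
    "pregnanetriol",
    "tetrahydrocorticosterone",
    "pregnanediol",
    "5a_tetrahydrocorticosterone",
)
# Aetiology separation (NAFLD vs alcohol cirrhosis): mechanism not described;
# a distinct shift on ethanol-responsive glucocorticoid/androgen metabolites.
_ALCOHOL_SHIFT = (
    ("etiocholanolone", 0.9),
    ("androsterone", 0.8),
    ("tetrahydrocortisol", 0.7),
    ("pregnanediol", 0.6),
    ("dehydroepiandrosterone", 0.5),
)
# Controls vs any NAFLD: mild disease signal on the glucocorticoid-pathway
# metabolites whose enzymes (11b-HSD1, 5a-reductase) shift in fatty liver.
_NAFLD_BASELINE_SHIFT = (
    ("5a_tetrahydrocortisol", 0.6),
    ("tetrahydrocortisol", 0.5),
    ("etiocholanolone", 0.5),
    ("androsterone", 0.4),
    ("5a_tetrahydrocorticosterone", 0.4),
)


@dataclass(frozen=True)
class ClassParams:
    """Per-class covariate and serum-chemistry distributions (mean, SD)."""

    age: tuple[float, float]
    bmi: tuple[float, float]
    t2d_prevalence: float
    male_fraction: float
    ast: tuple[float, float]
    alt: tuple[float, float]
    platelets: tuple[float, float]
    albumin: tuple[float, float]
    hba1c: tuple[float, float]
    nas: tuple[float, float] | None = None  # None → NAS not assessed


# Cohort demographics: controls, early fibrosis (F0-2) and advanced fibrosis
# (F3-4); individual stages within a group share the group's parameters.
# Controls' AST/platelets were not reported; normal-range values are used.
_CONTROL_PARAMS = ClassParams(
    age=(55.5, 11.1), bmi=(30.7, 5.8), t2d_prevalence=0.038, male_fraction=0.387,
    ast=(22.0, 6.0), alt=(13.2, 8.7), platelets=(250.0, 60.0),
    albumin=(4.4, 0.30), hba1c=(38.6, 10.4), nas=None,
)
_F02_PARAMS = ClassParams(
    age=(45.6, 12.0), bmi=(38.5, 7.0), t2d_prevalence=0.308, male_fraction=0.513,
    ast=(34.4, 22.0), alt=(63.4, 51.4), platelets=(242.5, 64.2),
    albumin=(4.3, 0.35), hba1c=(40.8, 8.2), nas=(4.0, 1.7),
)
_F34_PARAMS = ClassParams(
    age=(61.8, 10.8), bmi=(33.7, 5.8), t2d_prevalence=0.634, male_fraction=0.476,
    ast=(49.1, 31.8), alt=(49.9, 36.9), platelets=(183.9, 67.0),
    albumin=(3.9, 0.45), hba1c=(50.0, 13.5), nas=(4.7, 1.3),
)
_ALCOHOL_PARAMS = ClassParams(
    age=(58.0, 11.0), bmi=(28.0, 5.0), t2d_prevalence=0.25, male_fraction=0.65,
    ast=(55.0, 30.0), alt=(40.0, 25.0), platelets=(150.0, 60.0),
    albumin=(3.6, 0.50), hba1c=(40.0, 9.0), nas=None,
)

DEFAULT_COVARIATE_PARAMS: Mapping[str, ClassParams] = {
    "control": _CONTROL_PARAMS,
    "F0": _F02_PARAMS,
    "F1": _F02_PARAMS,
    "F2": _F02_PARAMS,
    "F3": _F34_PARAMS,
    "F4": _F34_PARAMS,
    "alcohol_cirrhosis": _ALCOHOL_PARAMS,
}

# Published cohort: 106 controls, 121 NAFLD (39 F0-2, 82 F3-4), 48 alcohol.
DEFAULT_N_PER_CLASS: Mapping[str, int] = {
    "control": 106,
    "F0": 13,
    "F1": 13,
    "F2": 13,
    "F3": 41,
    "F4": 41,
    "alcohol_cirrhosis": 48,
}


class ConfigurationError(ValueError):
    """Invalid cohort specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``informative_features`` maps a contrast key ``"neg1,neg2:pos1,pos2"`` to
    ``((metabolite, effect_size), ...)`` where the effect size is expressed in
    units of ``noise_sd`` on the log10 scale and is applied, additively over
    contrasts, to every class in the positive arm.
    """

    n_per_class: Mapping[str, int]
    panel: tuple[str, ...] = DEFAULT_PANEL
    informative_features: Mapping[str, tuple[tuple[str, float], ...]] = field(
        default_factory=dict
    )
    covariate_params: Mapping[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    baseline_log10: Mapping[str, float] = field(default_factory=dict)
    creatinine_log10_params: tuple[float, float] = (2.0, 0.25)  # median 100 mg/dL
    noise_sd: float = 0.35
    detection_floor_ug_l: float = 1.0
    seed: int = 0

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self.n_per_class)

    def validate(self) -> None:
        if not self.n_per_class:
            raise ConfigurationError("at least one class is required")
        for label, n in self.n_per_class.items():
            if label not in CLASS_LABELS:
                raise ConfigurationError(f"unrecognised class label {label!r}")
            if n < 2:
                raise ConfigurationError(
                    f"n_per_class must be >= 2 for every class; got {n} for {label!r}"
                )
            if label not in self.covariate_params:
                raise ConfigurationError(f"no covariate parameters for class {label!r}")
        if len(set(self.panel)) != len(self.panel):
            raise ConfigurationError("panel metabolite names must be unique")
        panel = set(self.panel)
        for key, features in self.informative_features.items():
            parse_contrast(key)
            for name, _effect in features:
                if name not in panel:
                    raise ConfigurationError(
                        f"informative feature {name!r} (contrast {key!r}) "
                        "is not in the panel"
                    )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.creatinine_log10_params[1] <= 0:
            raise ConfigurationError("creatinine SD must be > 0")
        for label, p in self.covariate_params.items():
            for fname in ("age", "bmi", "ast", "alt", "platelets", "albumin", "hba1c"):
                if getattr(p, fname)[1] <= 0:
                    raise ConfigurationError(
                        f"SD for {fname} must be > 0 (class {label!r})"
                    )


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated participant."""

    subject_id: str
    stage: str
    steroids_raw: Mapping[str, float]  # ug/L, 0.0 = below detection
    creatinine_mg_dl: float
    age_years: float
    bmi_kg_m2: float
    sex: str  # "M" | "F"
    t2d: bool
    ast_iu_l: float
    alt_iu_l: float
    platelets_1e9_l: float
    albumin_g_dl: float
    hba1c_mmol_mol: float
    nas_score: int | None = None


def parse_contrast(contrast: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split ``"neg1,neg2:pos1,pos2"`` into (negative, positive) class tuples."""
    try:
        neg_s, pos_s = contrast.split(":")
    except ValueError:
        raise ConfigurationError(
            f"contrast must be 'NEG:POS' with comma-separated classes; got {contrast!r}"
        ) from None
    neg = tuple(s.strip() for s in neg_s.split(",") if s.strip())
    pos = tuple(s.strip() for s in pos_s.split(",") if s.strip())
    if not neg or not pos:
        raise ConfigurationError(f"both contrast arms must be non-empty: {contrast!r}")
    if set(neg) & set(pos):
        raise ConfigurationError(f"contrast arms must be disjoint: {contrast!r}")
    for label in neg + pos:
        if label not in CLASS_LABELS:
            raise ConfigurationError(f"unrecognised class label {label!r} in contrast")
    return neg, pos


def contrast_key(negative: Sequence[str], positive: Sequence[str]) -> str:
    return ",".join(negative) + ":" + ",".join(positive)


def default_spec(seed: int = 0) -> CohortSpec:
    """The default study conditions: class sizes, demographics and per-contrast
    informative metabolites parameterised from the published cohort."""
    # Effect magnitudes are chosen so that, at the cohort's sample sizes,
    # every contrast's informative metabolites are identifiable above the
    # finite-sample noise floor of the relevance ranking, while preserving
    # the clinical ordering of contrast difficulty (aetiology hardest, then
    # any-NAFLD screening, then stage separation).
    informative = {
        CONTRAST_F02_VS_F34: _rank_effects(_TOP10_F02_VS_F34, top=1.0),
        CONTRAST_F03_VS_F4: _rank_effects(_TOP10_F03_VS_F4, top=0.8),
        CONTRAST_CONTROL_VS_F34: _rank_effects(_TOP10_CONTROL_VS_F34, top=0.6),
        CONTRAST_CONTROL_VS_F4: _rank_effects(_TOP10_CONTROL_VS_F4, top=0.6),
        CONTRAST_CONTROL_VS_F04: _NAFLD_BASELINE_SHIFT,
        CONTRAST_F4_VS_ALCOHOL: _ALCOHOL_SHIFT,
    }
    return CohortSpec(
        n_per_class=dict(DEFAULT_N_PER_CLASS),
        informative_features=informative,
        seed=seed,
    )


def _class_shifts(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Absolute log10 mean shift per class, summed over contrasts whose
    positive arm contains the class."""
    index = {m: i for i, m in enumerate(spec.panel)}
    shifts = {label: np.zeros(len(spec.panel)) for label in CLASS_LABELS}
    for key, features in spec.informative_features.items():
        _neg, pos = parse_contrast(key)
        for label in pos:
            for name, effect in features:
                shifts[label][index[name]] += effect * spec.noise_sd
    # Alcohol-related cirrhosis reuses the NAFLD-cirrhosis (F4) steroid
    # profile plus its own aetiology shift, so the F4-vs-alcohol difference
    # is exactly the declared aetiology signal.
    shifts["alcohol_cirrhosis"] += shifts["F4"]
    return {label: shifts[label] for label in spec.class_labels}


def ground_truth(spec: CohortSpec, contrast: str) -> list[str]:
    """The informative metabolites the generator used for a contrast.

    A spec with no informative features at all has no signal anywhere, so
    any contrast truthfully maps to the empty list; otherwise an unknown
    contrast is an error.
    """
    if not spec.informative_features:
        parse_contrast(contrast)
        return []
    if contrast not in spec.informative_features:
        raise ConfigurationError(f"contrast {contrast!r} not present in the spec")
    return [name for name, _ in spec.informative_features[contrast]]


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    # Plausibility clipping, not statistical truncation: clinical covariates
    # are reported as mean +/- SD and only need to stay in physiological range.
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort; deterministic given ``spec.seed``.

    Steroids: log10-normal around a per-metabolite baseline plus the class
    shift, truncated at the detection floor (below-floor values are reported
    as 0, i.e. not detected).  Covariates: per-class normal, clipped to
    plausible physiological ranges (age 18-90 y, BMI 15-60 kg/m2).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shifts = _class_shifts(spec)
    baseline = np.array(
        [
            spec.baseline_log10.get(m, _BASELINE_LOG10.get(m, _BASELINE_DEFAULT))
            for m in spec.panel
        ]
    )
    records: list[SubjectRecord] = []
    counter = 0
    for label in spec.class_labels:
        n = spec.n_per_class[label]
        p = spec.covariate_params[label]
        mean_log10 = baseline + shifts[label]
        log_conc = rng.normal(mean_log10, spec.noise_sd, size=(n, len(spec.panel)))
        conc = 10.0 ** log_conc
        conc[conc < spec.detection_floor_ug_l] = 0.0
        mu_c, sd_c = spec.creatinine_log10_params
        creat = 10.0 ** rng.normal(mu_c, sd_c, size=n)
        creat = np.maximum(creat, 10.0)
        age = _truncated_normal(rng, *p.age, 18.0, 90.0, size=n)
        bmi = _truncated_normal(rng, *p.bmi, 15.0, 60.0, size=n)
        sex = np.where(rng.random(n) < p.male_fraction, "M", "F")
        t2d = rng.random(n) < p.t2d_prevalence
        ast = _truncated_normal(rng, *p.ast, 5.0, 500.0, size=n)
        alt = _truncated_normal(rng, *p.alt, 5.0, 500.0, size=n)
        plate = _truncated_normal(rng, *p.platelets, 30.0, 600.0, size=n)
        alb = _truncated_normal(rng, *p.albumin, 2.0, 5.5, size=n)
        hba1c = _truncated_normal(rng, *p.hba1c, 20.0, 130.0, size=n)
        if p.nas is not None:
            # NAS is drawn independently of the steroid signal.
            nas = np.clip(np.rint(rng.normal(*p.nas, size=n)), 0, 8).astype(int)
        else:
            nas = None
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"S{counter:04d}",
                    stage=label,
                    steroids_raw={
                        m: float(conc[i, j]) for j, m in enumerate(spec.panel)
                    },
                    creatinine_mg_dl=float(creat[i]),
                    age_years=float(age[i]),
                    bmi_kg_m2=float(bmi[i]),
                    sex=str(sex[i]),
                    t2d=bool(t2d[i]),
                    ast_iu_l=float(ast[i]),
                    alt_iu_l=float(alt[i]),
                    platelets_1e9_l=float(plate[i]),
                    albumin_g_dl=float(alb[i]),
                    hba1c_mmol_mol=float(hba1c[i]),
                    nas_score=None if nas is None else int(nas[i]),
                )
            )
            counter += 1
    return records


# ---------------------------------------------------------------------------
# Tabular I/O

_FIXED_COLUMNS = (
    "subject_id",
    "stage",
    "age_years",
    "bmi_kg_m2",
    "sex",
    "t2d",
    "ast_iu_l",
    "alt_iu_l",
    "platelets_1e9_l",
    "albumin_g_dl",
    "hba1c_mmol_mol",
    "nas_score",
    "creatinine_mg_dl",
)


def cohort_to_dataframe(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("empty cohort")
    panel = list(records[0].steroids_raw)
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _FIXED_COLUMNS}
        row.update(r.steroids_raw)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_FIXED_COLUMNS) + panel)
    return df


def dataframe_to_cohort(df: pd.DataFrame) -> list[SubjectRecord]:
    panel = [c for c in df.columns if c not in _FIXED_COLUMNS]
    records = []
    for _, row in df.iterrows():
        nas = row["nas_score"]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                stage=str(row["stage"]),
                steroids_raw={m: float(row[m]) for m in panel},
                creatinine_mg_dl=float(row["creatinine_mg_dl"]),
                age_years=float(row["age_years"]),
                bmi_kg_m2=float(row["bmi_kg_m2"]),
                sex=str(row["sex"]),
                t2d=bool(row["t2d"]),
                ast_iu_l=float(row["ast_iu_l"]),
                alt_iu_l=float(row["alt_iu_l"]),
                platelets_1e9_l=float(row["platelets_1e9_l"]),
                albumin_g_dl=float(row["albumin_g_dl"]),
                hba1c_mmol_mol=float(row["hba1c_mmol_mol"]),
                nas_score=None if pd.isna(nas) else int(nas),
            )
        )
    return records


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectRecord]:
    return dataframe_to_cohort(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Spec (de)serialisation

def spec_to_yaml(spec: CohortSpec, path=None) -> str:
    doc = {
        "n_per_class": dict(spec.n_per_class),
        "panel": list(spec.panel),
        "informative_features": {
            k: [[m, float(e)] for m, e in v]
            for k, v in spec.informative_features.items()
        },
        "covariate_params": {k: asdict(p) for k, p in spec.covariate_params.items()},
        "baseline_log10": dict(spec.baseline_log10),
        "creatinine_log10_params": list(spec.creatinine_log10_params),
        "noise_sd": spec.noise_sd,
        "detection_floor_ug_l": spec.detection_floor_ug_l,
        "seed": spec.seed,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def _params_from_dict(d: Mapping) -> ClassParams:
    kw = dict(d)
    for f in ("age", "bmi", "ast", "alt", "platelets", "albumin", "hba1c"):
        kw[f] = tuple(kw[f])
    if kw.get("nas") is not None:
        kw["nas"] = tuple(kw["nas"])
    return ClassParams(**kw)


def spec_from_yaml(source) -> CohortSpec:
    """Load a CohortSpec from a YAML string, path, or file object."""
    if isinstance(source, str) and "\n" not in source and not source.strip().startswith("{"):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, io.IOBase):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(source)
    return CohortSpec(
        n_per_class=dict(doc["n_per_class"]),
        panel=tuple(doc.get("panel", DEFAULT_PANEL)),
        informative_features={
            k: tuple((m, float(e)) for m, e in v)
            for k, v in doc.get("informative_features", {}).items()
        },
        covariate_params={
            k: _params_from_dict(p) for k, p in doc["covariate_params"].items()
        }
        if "covariate_params" in doc
        else dict(DEFAULT_COVARIATE_PARAMS),
        baseline_log10=dict(doc.get("baseline_log10", {})),
        creatinine_log10_params=tuple(doc.get("creatinine_log10_params", (2.0, 0.25))),
        noise_sd=float(doc.get("noise_sd", 0.35)),
        detection_floor_ug_l=float(doc.get("detection_floor_ug_l", 1.0)),
        seed=int(doc.get("seed", 0)),
    )


def load_packaged_spec() -> CohortSpec:
    """The default cohort spec shipped with the package."""
    text = resources.files("steroidstage").joinpath("data/default_cohort.yaml").read_text()
    return spec_from_yaml(text)
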