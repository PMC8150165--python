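"""Serum-based non-invasive fibrosis scores used as ROC comparators.

All five are deterministic closed-form functions of routine chemistry:

* APRI   = (AST / ULN) / platelets × 100, AST upper limit of normal 40 IU/L
  by default.
* FIB-4  = age × AST / (platelets × √ALT).
* AST/ALT ratio.
* NFS    = −1.675 + 0.037·age + 0.094·BMI + 1.13·[IFG or T2D]
           + 0.99·(AST/ALT) − 0.013·platelets − 0.66·albumin.
* BARD   = (BMI > 28 → 1) + (AST/ALT > 0.8 → 2) + (T2D → 1); thresholds are
  strict inequalities.

Units: AST/ALT in IU/L, platelets ×10⁹/L, albumin g/dL, age years,
BMI kg/m².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import DomainError

__all__ = [
    "ScorePanel",
    "apri",
    "fib4",
    "ast_alt_ratio",
    "nfs",
    "bard",
    "score_record",
    "score_cohort",
    "SCORE_FUNCTIONS",
]

log = logging.getLogger(__name__)

DEFAULT_AST_ULN_IU_L = 40.0

_PHYSIOLOGICAL_RANGES = {
    "age_years": (18, 100),
    "bmi": (12, 70),
    "ast": (1, 2000),
    "alt": (1, 2000),
    "platelets": (10, 1000),
    "albumin": (1, 6),
}


@dataclass(frozen=True)
class ScorePanel:
    """The five comparator scores for one subject."""

    apri: float
    fib4: float
    ast_alt_ratio: float
    nfs: float
    bard: int

    def __post_init__(self):
        if self.bard not in (0, 1, 2, 3, 4):
            raise ValueError(f"BARD must be an integer 0-4, got {self.bard}")


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")


def _warn_outside_range(**kwargs):
    for name, value in kwargs.items():
        lo, hi = _PHYSIOLOGICAL_RANGES[name.split("__")[0]]
        if not (lo <= value <= hi):
            log.warning("%s=%.3g outside physiological range [%g, %g]", name, value, lo, hi)


def apri(ast_iu_l: float, ast_uln_iu_l: float = DEFAULT_AST_ULN_IU_L, platelets_1e9_l: float = None) -> float:
    """AST-to-platelet ratio index."""
    if platelets_1e9_l is None:
        raise DomainError("platelet count is required")
    _require_positive(ast=ast_iu_l, ast_uln=ast_uln_iu_l, platelets=platelets_1e9_l)
    return (ast_iu_l / ast_uln_iu_l) / platelets_1e9_l * 100.0


def fib4(age_years: float, ast_iu_l: float, alt_iu_l: float, platelets_1e9_l: float) -> float:
    """Fibrosis-4 index: age × AST / (platelets × √ALT)."""
    _require_positive(age=age_years, ast=ast_iu_l, alt=alt_iu_l, platelets=platelets_1e9_l)
    return age_years * ast_iu_l / (platelets_1e9_l * np.sqrt(alt_iu_l))


def ast_alt_ratio(ast_iu_l: float, alt_iu_l: float) -> float:
    if not alt_iu_l > 0:
        raise DomainError(f"ALT must be > 0, got {alt_iu_l}")
    if ast_iu_l < 0:
        raise DomainError(f"AST must be >= 0, got {ast_iu_l}")
    return ast_iu_l / alt_iu_l


def nfs(
    age_years: float,
    bmi_kg_m2: float,
    ifg_or_t2d: bool,
    ast_iu_l: float,
    alt_iu_l: float,
    platelets_1e9_l: float,
    albumin_g_dl: float,
) -> float:
    """NAFLD fibrosis score (affine in every argument)."""
    ratio = ast_alt_ratio(ast_iu_l, alt_iu_l)
    _warn_outside_range(
        age_years=age_years,
        bmi=bmi_kg_m2,
        ast=ast_iu_l,
        alt=alt_iu_l,
        platelets=platelets_1e9_l,
        albumin=albumin_g_dl,
    )
    return (
        -1.675
        + 0.037 * age_years
        + 0.094 * bmi_kg_m2
        + 1.13 * (1.0 if ifg_or_t2d else 0.0)
        + 0.99 * ratio
        - 0.013 * platelets_1e9_l
        - 0.66 * albumin_g_dl
    )


def bard(bmi_kg_m2: float, ast_alt: float, t2d: bool) -> int:
    """BMI-AST/ALT-diabetes score; all thresholds strict (>)."""
    if not (np.isfinite(bmi_kg_m2) and np.isfinite(ast_alt)):
        raise DomainError("BARD inputs must be finite")
    return int(bmi_kg_m2 > 28.0) + 2 * int(ast_alt > 0.8) + int(t2d)


def score_record(record, ast_uln_iu_l: float = DEFAULT_AST_ULN_IU_L) -> ScorePanel:
    """All five scores for one subject record."""
    ratio = ast_alt_ratio(record.ast_iu_l, record.alt_iu_l)
    return ScorePanel(
        apri=apri(record.ast_iu_l, ast_uln_iu_l, record.platelets_1e9_l),
        fib4=fib4(record.age_years, record.ast_iu_l, record.alt_iu_l, record.platelets_1e9_l),
        ast_alt_ratio=ratio,
        nfs=nfs(
            record.age_years,
            record.bmi_kg_m2,
            record.t2d,
            record.ast_iu_l,
            record.alt_iu_l,
            record.platelets_1e9_l,
            record.albumin_g_dl,
        ),
        bard=bard(record.bmi_kg_m2, ratio, record.t2d),
    )


def score_cohort(records, ast_uln_iu_l: float = DEFAULT_AST_ULN_IU_L):
    """Batch scoring.

    Returns ``(scores_df, exclusions_df)``: subjects whose chemistry is
    missing or out of domain are reported in the exclusion table with the
    reason, never silently dropped.
    """
    rows, excluded = [], []
    for r in records:
        try:
            panel = score_record(r, ast_uln_iu_l)
        except (DomainError, ValueError) as exc:
            excluded.append({"subject_id": r.subject_id, "reason": str(exc)})
            continue
        rows.append(
            {
                "subject_id": r.subject_id,
                "stage": r.stage,
                "apri": panel.apri,
                "fib4": panel.fib4,
                "ast_alt_ratio": panel.ast_alt_ratio,
                "nfs": panel.nfs,
                "bard": panel.bard,
            }
        )
    cols = ["subject_id", "stage", "apri", "fib4", "ast_alt_ratio", "nfs", "bard"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(excluded, columns=["subject_id", "reason"]),
    )


def _record_fib4(r):
    return fib4(r.age_years, r.ast_iu_l, r.alt_iu_l, r.platelets_1e9_l)


def _record_nfs(r):
    return nfs(r.age_years, r.bmi_kg_m2, r.t2d, r.ast_iu_l, r.alt_iu_l, r.platelets_1e9_l, r.albumin_g_dl)


SCORE_FUNCTIONS = {
    "apri": lambda r: apri(r.ast_iu_l, DEFAULT_AST_ULN_IU_L, r.platelets_1e9_l),
    "fib4": _record_fib4,
    "ast_alt_ratio": lambda r: ast_alt_ratio(r.ast_iu_l, r.alt_iu_l),
    "nfs": _record_nfs,
    "bard": lambda r: float(bard(r.bmi_kg_m2, ast_alt_ratio(r.ast_iu_l, r.alt_iu_l), r.t2d)),
}
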