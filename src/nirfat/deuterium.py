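"""Deuterium-dilution total-body-water computation and acceptability QC.

An oral D2O dose equilibrates with body water; the plateau enrichment of
saliva above the pre-dose (basal) sample gives the dilution space, and TBW
is the dilution space corrected for non-aqueous hydrogen exchange. Records
are screened with the study-style acceptability rules: TBW within 45-70% of
body weight (inclusive), deuterium-derived BF% >= 10, basal enrichment not
elevated, and the two post-dose samples in agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import DEFAULT_HYDRATION_TABLE, HydrationTable, fat_mass_from_ffm, ffm_dd
from .errors import ModelDomainError

__all__ = [
    "QCThresholds",
    "DDRecord",
    "tbw_from_dilution",
    "plateau_enrichment",
    "qc_filter",
    "apply_qc",
    "REASON_CODES",
]

REASON_CODES = ("BASAL_HIGH", "POST_DISAGREE", "TBW_OUT_OF_RANGE", "BF_NONPHYSIOLOGICAL")

#: dilution-space to TBW correction for non-aqueous hydrogen exchange
DEFAULT_EXCHANGE_CORRECTION = 1.041


@dataclass(frozen=True)
class QCThresholds:
    """Acceptability thresholds. The TBW window and the BF% floor are the
    study's stated rules; the basal ceiling and post-dose equivalence
    tolerance are configurable defaults (the checks are stated, their
    tolerances are not)."""

    tbw_fraction_low: float = 0.45
    tbw_fraction_high: float = 0.70
    bf_pct_min: float = 10.0
    basal_max_mg_kg: float = 10.0
    post_rel_tol: float = 0.05
    exchange_correction: float = DEFAULT_EXCHANGE_CORRECTION


@dataclass
class DDRecord:
    """One subject's deuterium-dilution measurement."""

    dose_g: float
    basal_enrichment: float  # mg/kg
    post_enrichment_1: float  # mg/kg
    post_enrichment_2: float  # mg/kg
    tbw_kg: float | None = None
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.dose_g <= 0:
            raise ModelDomainError(f"dose_g must be > 0, got {self.dose_g}")
        for name in ("basal_enrichment", "post_enrichment_1", "post_enrichment_2"):
            if getattr(self, name) < 0:
                raise ModelDomainError(f"{name} must be >= 0")


def tbw_from_dilution(dose_g, plateau_enrichment_mg_kg, exchange_correction=DEFAULT_EXCHANGE_CORRECTION):
    """TBW (kg) from dose and plateau enrichment above basal.

    dilution space (kg) = dose (mg) / enrichment (mg/kg); TBW = space divided
    by the non-aqueous exchange correction (default 1.041, configurable).
    """
    enr = np.asarray(plateau_enrichment_mg_kg, dtype=float)
    if np.any(enr <= 0):
        raise ModelDomainError("plateau enrichment must be > 0 (rejected: no usable signal)")
    dilution_space_kg = np.asarray(dose_g, dtype=float) * 1000.0 / enr
    out = dilution_space_kg / exchange_correction
    return float(out) if np.isscalar(plateau_enrichment_mg_kg) else out


def plateau_enrichment(record: DDRecord) -> float:
    """Mean of the two post-dose enrichments minus the basal enrichment."""
    return 0.5 * (record.post_enrichment_1 + record.post_enrichment_2) - record.basal_enrichment


def qc_filter(record: DDRecord, weight_g: float, bf_pct: float,
              thresholds: QCThresholds = QCThresholds()) -> tuple[bool, set]:
    """Apply the acceptability rules; returns (accepted, reason codes).

    Rejection is a result, not an error; every violated rule is reported.
    """
    if record.tbw_kg is None:
        raise ModelDomainError("record.tbw_kg must be computed before QC")
    reasons: set[str] = set()
    frac = record.tbw_kg * 1000.0 / weight_g
    if not (thresholds.tbw_fraction_low <= frac <= thresholds.tbw_fraction_high):
        reasons.add("TBW_OUT_OF_RANGE")
    if bf_pct < thresholds.bf_pct_min:
        reasons.add("BF_NONPHYSIOLOGICAL")
    if record.basal_enrichment > thresholds.basal_max_mg_kg:
        reasons.add("BASAL_HIGH")
    posts = (record.post_enrichment_1, record.post_enrichment_2)
    mean_post = 0.5 * sum(posts)
    if mean_post <= 0 or abs(posts[0] - posts[1]) / mean_post > thresholds.post_rel_tol:
        reasons.add("POST_DISAGREE")
    record.qc_flags = reasons
    return (len(reasons) == 0, reasons)


def apply_qc(
    cohort: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    hydration_table: HydrationTable = DEFAULT_HYDRATION_TABLE,
) -> pd.DataFrame:
    """Compute TBW and run the acceptability filter over a cohort table.

    Expects columns: subject_id, age_months, sex, weight_g, dose_g,
    basal_mg_kg, post1_mg_kg, post2_mg_kg. Returns one row per subject with
    tbw_kg, tbw_fraction, bf_pct_dd, accepted and '|'-joined reasons. The
    filter is per-record, hence idempotent and order-independent.
    """
    rows = []
    for rec in cohort.itertuples(index=False):
        record = DDRecord(
            dose_g=rec.dose_g,
            basal_enrichment=rec.basal_mg_kg,
            post_enrichment_1=rec.post1_mg_kg,
            post_enrichment_2=rec.post2_mg_kg,
        )
        plateau = plateau_enrichment(record)
        if plateau <= 0:
            record.tbw_kg = np.nan
            accepted, reasons = False, {"POST_DISAGREE", "TBW_OUT_OF_RANGE"}
            bf = np.nan
        else:
            record.tbw_kg = tbw_from_dilution(rec.dose_g, plateau, thresholds.exchange_correction)
            ffm = ffm_dd(record.tbw_kg, rec.age_months, rec.sex, hydration_table)
            fm = float(fat_mass_from_ffm(rec.weight_g, ffm))
            bf = 100.0 * fm / rec.weight_g
            accepted, reasons = qc_filter(record, rec.weight_g, bf, thresholds)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "tbw_kg": record.tbw_kg,
                "tbw_fraction": record.tbw_kg * 1000.0 / rec.weight_g if np.isfinite(record.tbw_kg) else np.nan,
                "bf_pct_dd": bf,
                "accepted": accepted,
                "reasons": "|".join(sorted(reasons)),
            }
        )
    return pd.DataFrame(rows)
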