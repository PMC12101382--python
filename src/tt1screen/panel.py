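"""Newborn records and the derived TT1 biomarker panel.

The screening programme measures three analytes per dried blood spot that are
informative for tyrosinemia type 1 (TT1): succinylacetone (SA), tyrosine (tyr)
and phenylalanine (phe), all in µmol/L whole blood.  From these, the panel
derives the ratio biomarkers of the tyrosine catabolic pathway
(tyr/SA, SA/tyr, SA/phe, tyr/phe, phe/tyr) and the numeric product tyr x SA,
a composite analogous to the IRT x PAP product used in cystic-fibrosis
screening.

Convention that matters: for NeoBase-era records the *converted* SA (on the
NeoBase 2 scale, reported at two decimals) is the effective SA, and every
ratio/product is computed from that two-decimal value — this is the only
convention consistent with the published patient table (e.g. 833 x 3.85 =
3207.05 -> 3207, whereas the unrounded conversion 3.8514 would give 3208).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .harmonization import NEOBASE_TO_NEOBASE2, ConversionModel, convert_sa, round_half_up

__all__ = [
    "Assay",
    "Diagnosis",
    "ScreenResult",
    "NewbornRecord",
    "DerivedPanel",
    "PANEL_BIOMARKERS",
    "DISPLAY_DECIMALS",
    "effective_sa",
    "compute_panel",
    "compute_panel_frame",
    "display_panel",
    "records_to_frame",
    "frame_to_records",
    "COHORT_COLUMNS",
]


class Assay(str, Enum):
    NEOBASE = "NeoBase"
    NEOBASE2 = "NeoBase2"


class Diagnosis(str, Enum):
    TT1 = "TT1"
    NOT_TT1 = "not_TT1"
    UNKNOWN = "unknown"


class ScreenResult(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_APPLICABLE = "not_applicable"


#: Required columns of a cohort table (CSV or DataFrame).
COHORT_COLUMNS = ("record_id", "assay", "sa", "tyr", "phe", "diagnosis", "original_result")


@dataclass
class NewbornRecord:
    """One screened newborn: raw biomarkers plus screening metadata.

    Biomarkers are µmol/L whole blood.  ``sa_raw`` is on the scale of the
    assay named in ``assay``; :func:`effective_sa` places it on the NeoBase 2
    scale.  Covariates (birth weight in g, gestational age in days, age at
    sampling in h) are carried but unused by the screening protocols.
    """

    record_id: str
    assay: Assay
    sa_raw: float
    tyr: float
    phe: float
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    original_result: ScreenResult = ScreenResult.NOT_APPLICABLE
    sa_cov_original: float | None = None
    birth_weight: float | None = None
    gestational_age: float | None = None
    sex: str | None = None
    age_at_sampling: float | None = None
    transfused: bool | None = None

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay)
        self.diagnosis = Diagnosis(self.diagnosis)
        self.original_result = ScreenResult(self.original_result)
        for name in ("sa_raw", "tyr", "phe"):
            v = getattr(self, name)
            if v is None or not math.isfinite(float(v)):
                raise ValueError(f"{self.record_id}: missing or non-finite {name}")
            if float(v) < 0:
                raise ValueError(f"{self.record_id}: negative {name} ({v})")


#: Panel fields a screening criterion may threshold on.
PANEL_BIOMARKERS = (
    "sa_raw",
    "sa_eff",
    "tyr",
    "phe",
    "tyr_times_sa",
    "tyr_over_sa",
    "sa_over_tyr",
    "sa_over_phe",
    "tyr_over_phe",
    "phe_over_tyr",
)

#: Reporting resolution per derived biomarker (decimals, half-up), mirroring
#: the published patient table.
DISPLAY_DECIMALS = {
    "sa_eff": 2,
    "tyr": 0,
    "phe": 0,
    "tyr_times_sa": 0,
    "tyr_over_sa": 0,
    "sa_over_tyr": 3,
    "sa_over_phe": 3,
    "tyr_over_phe": 2,
    "phe_over_tyr": 2,
}


@dataclass(frozen=True)
class DerivedPanel:
    """Effective SA plus every derived biomarker for one record.

    ``sa_eff`` is two-decimal (NeoBase 2 scale); ratios and the product are
    stored at full float precision and rounded only for display.  A ratio
    whose denominator is zero is NaN (undefined), never silently dropped.
    """

    record_id: str
    sa_raw: float
    sa_eff: float
    tyr: float
    phe: float
    tyr_times_sa: float
    tyr_over_sa: float
    sa_over_tyr: float
    sa_over_phe: float
    tyr_over_phe: float
    phe_over_tyr: float


def effective_sa(record: NewbornRecord, model: ConversionModel = NEOBASE_TO_NEOBASE2) -> float:
    """SA on the NeoBase 2 scale: converted for NeoBase records, untouched
    (bit-for-bit) for NeoBase 2 records."""
    if record.assay is Assay.NEOBASE:
        return convert_sa(record.sa_raw, model)
    if record.assay is Assay.NEOBASE2:
        return record.sa_raw
    raise ValueError(f"unknown assay label: {record.assay!r}")


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_panel(
    record: NewbornRecord, model: ConversionModel = NEOBASE_TO_NEOBASE2
) -> DerivedPanel:
    """Compute the full derived panel for one record.

    All ratios and the tyr x SA product are computed from the two-decimal
    effective SA.  Zero denominators yield NaN for the affected ratio only.
    """
    sa_eff = effective_sa(record, model)
    tyr, phe = float(record.tyr), float(record.phe)
    return DerivedPanel(
        record_id=record.record_id,
        sa_raw=float(record.sa_raw),
        sa_eff=sa_eff,
        tyr=tyr,
        phe=phe,
        tyr_times_sa=tyr * sa_eff,
        tyr_over_sa=_safe_div(tyr, sa_eff),
        sa_over_tyr=_safe_div(sa_eff, tyr),
        sa_over_phe=_safe_div(sa_eff, phe),
        tyr_over_phe=_safe_div(tyr, phe),
        phe_over_tyr=_safe_div(phe, tyr),
    )


def compute_panel_frame(
    cohort: pd.DataFrame, model: ConversionModel = NEOBASE_TO_NEOBASE2
) -> pd.DataFrame:
    """Vectorised :func:`compute_panel` over a cohort table.

    ``cohort`` needs columns ``record_id, assay, sa, tyr, phe``; the result
    has one row per record with all :data:`PANEL_BIOMARKERS` columns (same
    index order).  Scales to full national-cohort size (~650k rows) in
    seconds.
    """
    missing = {"record_id", "assay", "sa", "tyr", "phe"} - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    assay = cohort["assay"].astype(str)
    bad = ~assay.isin([a.value for a in Assay])
    if bad.any():
        raise ValueError(
            f"unknown assay label(s): {sorted(assay[bad].unique())}"
        )
    sa_raw = cohort["sa"].to_numpy(dtype=float)
    tyr = cohort["tyr"].to_numpy(dtype=float)
    phe = cohort["phe"].to_numpy(dtype=float)
    for name, arr in (("sa", sa_raw), ("tyr", tyr), ("phe", phe)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"missing or non-finite {name} value in cohort")
        if np.any(arr < 0):
            raise ValueError(f"negative {name} value in cohort")

    is_old = (assay == Assay.NEOBASE.value).to_numpy()
    sa_eff = sa_raw.copy()
    if is_old.any():
        sa_eff[is_old] = convert_sa(sa_raw[is_old], model)

    with np.errstate(divide="ignore", invalid="ignore"):
        panel = pd.DataFrame(
            {
                "record_id": cohort["record_id"].to_numpy(),
                "sa_raw": sa_raw,
                "sa_eff": sa_eff,
                "tyr": tyr,
                "phe": phe,
                "tyr_times_sa": tyr * sa_eff,
                "tyr_over_sa": np.where(sa_eff > 0, tyr / np.where(sa_eff > 0, sa_eff, 1), np.nan),
                "sa_over_tyr": np.where(tyr > 0, sa_eff / np.where(tyr > 0, tyr, 1), np.nan),
                "sa_over_phe": np.where(phe > 0, sa_eff / np.where(phe > 0, phe, 1), np.nan),
                "tyr_over_phe": np.where(phe > 0, tyr / np.where(phe > 0, phe, 1), np.nan),
                "phe_over_tyr": np.where(tyr > 0, phe / np.where(tyr > 0, tyr, 1), np.nan),
            },
            index=cohort.index,
        )
    return panel


def display_panel(panel: DerivedPanel) -> dict:
    """Panel values at reporting resolution (half-up), as in the published
    patient table: products and tyr/SA to integers, SA/tyr and SA/phe to three
    decimals, tyr/phe and phe/tyr to two."""
    out = {"record_id": panel.record_id, "sa_raw": panel.sa_raw}
    for name, nd in DISPLAY_DECIMALS.items():
        v = getattr(panel, name)
        if math.isnan(v):
            out[name] = math.nan
        else:
            r = round_half_up(v, nd)
            out[name] = int(r) if nd == 0 else r
    return out


def records_to_frame(records) -> pd.DataFrame:
    """Cohort DataFrame from an iterable of :class:`NewbornRecord`."""
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "assay": r.assay.value,
                "sa": r.sa_raw,
                "tyr": r.tyr,
                "phe": r.phe,
                "diagnosis": r.diagnosis.value,
                "original_result": r.original_result.value,
                "sa_cov_original": r.sa_cov_original,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(cohort: pd.DataFrame) -> list[NewbornRecord]:
    """Row-level :class:`NewbornRecord` objects from a cohort DataFrame."""
    records = []
    has_cov = "sa_cov_original" in cohort.columns
    for row in cohort.itertuples(index=False):
        records.append(
            NewbornRecord(
                record_id=str(row.record_id),
                assay=row.assay,
                sa_raw=float(row.sa),
                tyr=float(row.tyr),
                phe=float(row.phe),
                diagnosis=getattr(row, "diagnosis", Diagnosis.UNKNOWN),
                original_result=getattr(row, "original_result", ScreenResult.NOT_APPLICABLE),
                sa_cov_original=(
                    float(row.sa_cov_original)
                    if has_cov and row.sa_cov_original is not None
                    and not pd.isna(row.sa_cov_original)
                    else None
                ),
            )
        )
    return records
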