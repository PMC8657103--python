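"""Deterministic lesion-level response rules.

Implements the rule engine for three-timepoint volumetry:

* eligibility — a lesion is evaluable only if a volume exists at the
  pre-baseline, baseline and first follow-up scans;
* tumor growth kinetics (TGK) — pre- and post-treatment volumetric growth
  rates in mm^3/day and their ratio;
* the volumetric hyperprogression call (HPDv) — three conjunctive criteria:
  time to treatment failure under 2 months, TGK ratio >= 2, and volume
  increase >= 50% versus baseline;
* the Nelson volumetric category per lesion (+/-25% thresholds); and
* the patient-level dissociated-response (DR) call — progression in one
  organ together with partial response in a different organ.

All thresholds are inclusive (>= / <=) and configurable via
:class:`HPDvCriteria` and the ``threshold_pct`` arguments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORGANS",
    "TIMEPOINTS",
    "DAYS_PER_MONTH",
    "HPDvStatus",
    "NelsonResponse",
    "DRStatus",
    "HPDvCriteria",
    "LesionRecord",
    "PatientRecord",
    "TGKResult",
    "CohortSummary",
    "eligible_for_hpdv",
    "compute_tgk",
    "classify_hpdv",
    "classify_nelson",
    "classify_dissociated",
    "classify_cohort",
    "summarize_cohort",
    "lesions_from_frame",
    "patients_from_frame",
]

ORGANS = ("lung", "bone", "lymph_node", "liver", "other")
TIMEPOINTS = ("pre_baseline", "baseline", "follow_up")

#: Mean Gregorian month length, used to convert the "2 months" TTF cutoff.
DAYS_PER_MONTH = 30.44


class HPDvStatus(str, enum.Enum):
    HPDV = "HPDV"
    NON_HPDV = "NON_HPDV"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class NelsonResponse(str, enum.Enum):
    PROGRESSION = "PROGRESSION"
    PARTIAL_RESPONSE = "PARTIAL_RESPONSE"
    STABLE = "STABLE"


class DRStatus(str, enum.Enum):
    DR = "DR"
    NON_DR = "NON_DR"


@dataclass(frozen=True)
class HPDvCriteria:
    """Thresholds for the three-criterion HPDv call.

    Defaults follow the published rule: TTF < 2 months (strict), TGK ratio
    >= 2 and volume increase >= 50% versus baseline (both inclusive).
    """

    ttf_max_months: float = 2.0
    ratio_min: float = 2.0
    increase_min_pct: float = 50.0
    days_per_month: float = DAYS_PER_MONTH

    @property
    def ttf_max_days(self) -> float:
        return self.ttf_max_months * self.days_per_month


@dataclass
class LesionRecord:
    """One lesion's identity plus its per-timepoint dates and volumes.

    ``volumes`` maps timepoint -> volume in mm^3 or ``None`` when the lesion
    is absent at that scan; ``dates`` maps timepoint -> day integer. A
    timepoint missing from both maps is treated as absent.
    """

    lesion_id: str
    patient_id: str
    organ: str
    dates: dict = field(default_factory=dict)
    volumes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(
                f"unknown organ {self.organ!r} for lesion {self.lesion_id}; "
                f"expected one of {ORGANS}"
            )
        present = [tp for tp in TIMEPOINTS if tp in self.dates]
        dts = [self.dates[tp] for tp in present]
        if any(b <= a for a, b in zip(dts, dts[1:])):
            raise ValueError(
                f"scan dates must be strictly increasing for lesion "
                f"{self.lesion_id}: {dts}"
            )

    def volume(self, timepoint: str) -> Optional[float]:
        v = self.volumes.get(timepoint)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    def date(self, timepoint: str) -> Optional[int]:
        d = self.dates.get(timepoint)
        return None if d is None else int(d)


@dataclass
class PatientRecord:
    """Patient-level outcomes: TTF and overall survival."""

    patient_id: str
    ttf_days: float
    os_days: float
    os_event: int  # 1 = death, 0 = censored

    def __post_init__(self) -> None:
        if self.ttf_days <= 0:
            raise ValueError(f"ttf_days must be > 0 for {self.patient_id}")
        if self.os_days <= 0:
            raise ValueError(f"os_days must be > 0 for {self.patient_id}")
        if int(self.os_event) not in (0, 1):
            raise ValueError(f"os_event must be 0/1 for {self.patient_id}")


@dataclass
class TGKResult:
    """Pre/post growth rates in mm^3/day and their ratio.

    ``ratio`` is ``None`` (and ``evaluable`` False) when the pre-treatment
    rate is not strictly positive — a lesion that was shrinking or static
    before treatment cannot have its growth "more than doubled".
    """

    tgk_pre: float
    tgk_post: float
    ratio: Optional[float]
    evaluable: bool


def eligible_for_hpdv(lesion: LesionRecord) -> bool:
    """True iff the lesion has a volume at all three required timepoints."""
    return all(lesion.volume(tp) is not None for tp in TIMEPOINTS)


def compute_tgk(lesion: LesionRecord) -> TGKResult:
    """Volumetric growth rates from consecutive scans.

    Requires an eligible lesion.  Raises on a zero day-gap between
    consecutive scans.
    """
    if not eligible_for_hpdv(lesion):
        raise ValueError(
            f"lesion {lesion.lesion_id} lacks a volume at one of {TIMEPOINTS}"
        )
    d_pre, d_base, d_fu = (lesion.date(tp) for tp in TIMEPOINTS)
    v_pre, v_base, v_fu = (lesion.volume(tp) for tp in TIMEPOINTS)
    if d_base == d_pre or d_fu == d_base:
        raise ValueError(
            f"zero day-gap between consecutive scans for lesion {lesion.lesion_id}"
        )
    tgk_pre = (v_base - v_pre) / (d_base - d_pre)
    tgk_post = (v_fu - v_base) / (d_fu - d_base)
    if tgk_pre > 0:
        return TGKResult(tgk_pre, tgk_post, tgk_post / tgk_pre, True)
    return TGKResult(tgk_pre, tgk_post, None, False)


def classify_hpdv(
    tgk: Optional[TGKResult],
    lesion: LesionRecord,
    patient: PatientRecord,
    criteria: HPDvCriteria = HPDvCriteria(),
) -> HPDvStatus:
    """Three-criterion HPDv call for a single lesion.

    NOT_EVALUABLE comes only from eligibility; an eligible lesion whose TGK
    ratio is undefined is NON_HPDV.
    """
    if not eligible_for_hpdv(lesion):
        return HPDvStatus.NOT_EVALUABLE
    if tgk is None:
        tgk = compute_tgk(lesion)
    v_base = lesion.volume("baseline")
    if v_base == 0:
        raise ValueError(
            f"baseline volume is 0 for lesion {lesion.lesion_id}: "
            "percent change undefined"
        )
    increase_pct = (lesion.volume("follow_up") - v_base) / v_base * 100.0
    if (
        patient.ttf_days < criteria.ttf_max_days
        and tgk.ratio is not None
        and tgk.ratio >= criteria.ratio_min
        and increase_pct >= criteria.increase_min_pct
    ):
        return HPDvStatus.HPDV
    return HPDvStatus.NON_HPDV


def classify_nelson(
    v_baseline: float, v_follow_up: float, threshold_pct: float = 25.0
) -> NelsonResponse:
    """Volumetric lesion response category at first follow-up.

    PROGRESSION for growth >= threshold, PARTIAL_RESPONSE for shrinkage
    >= threshold (see module docs for the interpretation of the shrinkage
    clause), STABLE otherwise; both boundaries inclusive.
    """
    if v_baseline <= 0:
        raise ValueError("baseline volume must be strictly positive")
    change_pct = (v_follow_up - v_baseline) / v_baseline * 100.0
    if change_pct >= threshold_pct:
        return NelsonResponse.PROGRESSION
    if change_pct <= -threshold_pct:
        return NelsonResponse.PARTIAL_RESPONSE
    return NelsonResponse.STABLE


def classify_dissociated(
    patient_lesions: Sequence[tuple],
    require_different_organs: bool = True,
) -> DRStatus:
    """Patient-level dissociated-response call.

    ``patient_lesions`` is a sequence of ``(LesionRecord, NelsonResponse or
    None)`` pairs covering every lesion of one patient; ``None`` marks a
    lesion that could not be categorized (missing baseline or follow-up).
    Patients with exactly one lesion are NON_DR by definition.  With
    ``require_different_organs`` (the default, matching the published rule)
    DR needs a progressing lesion in one organ and a partial response in a
    *different* organ.
    """
    if len(patient_lesions) == 0:
        raise ValueError("patient has no lesions")
    if len(patient_lesions) == 1:
        return DRStatus.NON_DR
    prog_organs = {
        les.organ
        for les, resp in patient_lesions
        if resp is NelsonResponse.PROGRESSION
    }
    pr_organs = {
        les.organ
        for les, resp in patient_lesions
        if resp is NelsonResponse.PARTIAL_RESPONSE
    }
    if not prog_organs or not pr_organs:
        return DRStatus.NON_DR
    if not require_different_organs:
        return DRStatus.DR
    if prog_organs - pr_organs or pr_organs - prog_organs or len(prog_organs | pr_organs) > 1:
        # some progressing organ differs from some responding organ
        return DRStatus.DR
    return DRStatus.NON_DR


def _nelson_or_none(
    lesion: LesionRecord, threshold_pct: float
) -> Optional[NelsonResponse]:
    v_base = lesion.volume("baseline")
    v_fu = lesion.volume("follow_up")
    if v_base is None or v_fu is None:
        return None
    return classify_nelson(v_base, v_fu, threshold_pct)


def classify_cohort(
    lesions: Sequence[LesionRecord],
    patients: Sequence[PatientRecord],
    criteria: HPDvCriteria = HPDvCriteria(),
    nelson_threshold_pct: float = 25.0,
    require_different_organs: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every lesion-level rule and the patient-level DR rule.

    Returns ``(classifications, patients_out)``: one row per lesion with
    TGK rates/ratio, HPDv status and Nelson category; one row per patient
    with the DR status.
    """
    patients_by_id = {p.patient_id: p for p in patients}
    rows = []
    per_patient: dict[str, list] = {}
    for les in lesions:
        if les.patient_id not in patients_by_id:
            raise KeyError(
                f"lesion {les.lesion_id} references unknown patient "
                f"{les.patient_id}"
            )
        pat = patients_by_id[les.patient_id]
        if eligible_for_hpdv(les):
            tgk = compute_tgk(les)
            status = classify_hpdv(tgk, les, pat, criteria)
            tgk_pre, tgk_post, ratio = tgk.tgk_pre, tgk.tgk_post, tgk.ratio
        else:
            status = HPDvStatus.NOT_EVALUABLE
            tgk_pre = tgk_post = ratio = None
        nelson = _nelson_or_none(les, nelson_threshold_pct)
        rows.append(
            {
                "lesion_id": les.lesion_id,
                "patient_id": les.patient_id,
                "organ": les.organ,
                "tgk_pre": tgk_pre,
                "tgk_post": tgk_post,
                "tgk_ratio": ratio,
                "hpdv_status": status.value,
                "nelson_response": None if nelson is None else nelson.value,
            }
        )
        per_patient.setdefault(les.patient_id, []).append((les, nelson))
    classifications = pd.DataFrame(rows)
    pat_rows = []
    for pid in sorted(patients_by_id):
        if pid in per_patient:
            dr = classify_dissociated(
                per_patient[pid], require_different_organs=require_different_organs
            )
            pat_rows.append({"patient_id": pid, "dr_status": dr.value})
    patients_out = pd.DataFrame(pat_rows)
    return classifications, patients_out


def _pct(count: int, denom: int) -> float:
    return round(count / denom * 100.0, 1) if denom else float("nan")


@dataclass
class CohortSummary:
    """Counts and one-decimal percentages of the lesion/patient accounting."""

    n_lesions: int
    n_hpdv: int
    n_non_hpdv: int
    n_excluded: int
    pct_hpdv: float
    pct_non_hpdv: float
    pct_excluded: float
    hpdv_by_organ: dict
    non_hpdv_by_organ: dict
    hpdv_organ_pct: dict
    non_hpdv_organ_pct: dict
    n_patients: int
    n_dr: int
    n_non_dr: int
    pct_dr: float
    pct_non_dr: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_cohort(
    lesions: Sequence[LesionRecord],
    patients: Sequence[PatientRecord],
    criteria: HPDvCriteria = HPDvCriteria(),
    nelson_threshold_pct: float = 25.0,
    require_different_organs: bool = True,
) -> CohortSummary:
    """Cohort-level accounting: HPDv/non-HPDv/excluded and DR/non-DR splits.

    HPDv and non-HPDv percentages use the all-lesion denominator; per-organ
    shares use the category total as denominator.
    """
    cls, pats = classify_cohort(
        lesions,
        patients,
        criteria=criteria,
        nelson_threshold_pct=nelson_threshold_pct,
        require_different_organs=require_different_organs,
    )
    n = len(cls)
    n_hpdv = int((cls.hpdv_status == HPDvStatus.HPDV.value).sum())
    n_non = int((cls.hpdv_status == HPDvStatus.NON_HPDV.value).sum())
    n_exc = int((cls.hpdv_status == HPDvStatus.NOT_EVALUABLE.value).sum())

    def organ_counts(status: str) -> dict:
        sub = cls[cls.hpdv_status == status]
        return {org: int((sub.organ == org).sum()) for org in ORGANS}

    hpdv_org = organ_counts(HPDvStatus.HPDV.value)
    non_org = organ_counts(HPDvStatus.NON_HPDV.value)
    n_dr = int((pats.dr_status == DRStatus.DR.value).sum()) if len(pats) else 0
    n_pat = len(pats)
    return CohortSummary(
        n_lesions=n,
        n_hpdv=n_hpdv,
        n_non_hpdv=n_non,
        n_excluded=n_exc,
        pct_hpdv=_pct(n_hpdv, n),
        pct_non_hpdv=_pct(n_non, n),
        pct_excluded=_pct(n_exc, n),
        hpdv_by_organ=hpdv_org,
        non_hpdv_by_organ=non_org,
        hpdv_organ_pct={o: _pct(c, n_hpdv) for o, c in hpdv_org.items()},
        non_hpdv_organ_pct={o: _pct(c, n_non) for o, c in non_org.items()},
        n_patients=n_pat,
        n_dr=n_dr,
        n_non_dr=n_pat - n_dr,
        pct_dr=_pct(n_dr, n_pat),
        pct_non_dr=_pct(n_pat - n_dr, n_pat),
    )


def lesions_from_frame(df: pd.DataFrame) -> list[LesionRecord]:
    """Build :class:`LesionRecord` objects from the long lesion table.

    Expects columns patient_id, lesion_id, organ, timepoint, scan_date,
    volume_mm3 (empty volume = lesion absent at that scan).
    """
    required = {"patient_id", "lesion_id", "organ", "timepoint", "scan_date", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    out = []
    for (pid, lid), grp in df.groupby(["patient_id", "lesion_id"], sort=True):
        organs = grp.organ.unique()
        if len(organs) != 1:
            raise ValueError(f"lesion {lid} has inconsistent organ labels {organs}")
        dates, volumes = {}, {}
        for _, row in grp.iterrows():
            tp = row.timepoint
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r} for lesion {lid}")
            if tp in dates:
                raise ValueError(f"duplicate timepoint {tp!r} for lesion {lid}")
            dates[tp] = int(row.scan_date)
            v = row.volume_mm3
            volumes[tp] = None if pd.isna(v) else float(v)
        out.append(LesionRecord(str(lid), str(pid), str(organs[0]), dates, volumes))
    return out


def patients_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    required = {"patient_id", "ttf_days", "os_days", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    return [
        PatientRecord(str(r.patient_id), float(r.ttf_days), float(r.os_days), int(r.os_event))
        for r in df.itertuples()
    ]
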