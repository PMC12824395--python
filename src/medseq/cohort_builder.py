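"""Eligibility filters for the incident cohort.

Incidence and sample purity are enforced by excluding persons with a
prior bipolar code, adequate-medication use in a pre-diagnosis washout
window, psychosis-spectrum or dementia codes, incomplete residency over
lookback and follow-up, or age outside 16–65 at diagnosis. Each person
receives an auditable report listing every triggered reason in a fixed
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exposure_model import _ensure_day
from .states import ANTICONVULSANT_MS, ANTIPSYCHOTIC, FOLLOWUP_DAYS, LITHIUM_CLASS

LOOKBACK_DAYS = 1092  # "three years", commensurate with the 91-day grid
#: Washout window for antipsychotics / mood-stabilizers: 15 until 3
#: months before diagnosis, rendered in 91-day-commensurate days.
WASHOUT_START, WASHOUT_END = -455, -91
AGE_MIN, AGE_MAX = 16, 65

WASHOUT_CLASSES = {ANTIPSYCHOTIC, ANTICONVULSANT_MS, LITHIUM_CLASS}

REASONS = ("prior_bd", "washout_medication", "psychosis_dementia", "residency", "age")

_BD_PREFIXES = ("F30", "F31")
_PSYCHOSIS_DEMENTIA_PREFIXES = ("F2", "F00", "F01", "F02", "F03", "G30")


@dataclass(frozen=True)
class EligibilityReport:
    person_id: str
    included: bool
    exclusion_reasons: tuple[str, ...]


def _age_at(dx_day: int, birth_day: int) -> int:
    return int((dx_day - birth_day) / 365.25)


def apply_eligibility(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    use_periods: pd.DataFrame,
) -> pd.DataFrame:
    """Evaluate every exclusion rule for every person.

    Parameters
    ----------
    persons
        ``person_id, birth_date, diagnosis_date`` plus optional
        ``death_date`` and ``residency_start``/``residency_end``.
    diagnoses
        ``person_id, icd10_code, date`` history rows (the index
        diagnosis on the diagnosis day itself does not count as prior).
    use_periods
        Exposure-model output; only adequate classes (antipsychotics,
        anticonvulsant mood-stabilizers, lithium) matter for washout.

    Returns
    -------
    pandas.DataFrame
        ``person_id, included, reasons`` where ``reasons`` is a tuple in
        the fixed evaluation order. All triggered reasons are recorded,
        not only the first.
    """
    persons = _ensure_day(persons, "diagnosis_day", "diagnosis_date")
    persons = _ensure_day(persons, "birth_day", "birth_date")
    persons = _ensure_day(persons, "death_day", "death_date")
    persons = _ensure_day(persons, "residency_start_day", "residency_start")
    persons = _ensure_day(persons, "residency_end_day", "residency_end")
    if persons["diagnosis_day"].isna().any():
        bad = persons.loc[persons["diagnosis_day"].isna(), "person_id"].tolist()
        raise ValueError(f"missing diagnosis_date for persons {bad}")

    diagnoses = _ensure_day(diagnoses, "day", "date")
    diag_by_person: dict[str, list[tuple[str, int]]] = {}
    for rec in diagnoses.itertuples(index=False):
        diag_by_person.setdefault(rec.person_id, []).append(
            (str(rec.icd10_code), int(rec.day))
        )
    washout_by_person: dict[str, list[tuple[int, int]]] = {}
    if len(use_periods):
        mask = use_periods["drug_class"].isin(WASHOUT_CLASSES)
        for rec in use_periods[mask].itertuples(index=False):
            washout_by_person.setdefault(rec.person_id, []).append(
                (int(rec.start_day), int(rec.end_day))
            )

    rows = []
    for rec in persons.itertuples(index=False):
        pid = rec.person_id
        dx = int(rec.diagnosis_day)
        death = getattr(rec, "death_day", None)
        death = None if death is None or pd.isna(death) else int(death)
        reasons: list[str] = []

        codes = diag_by_person.get(pid, [])
        if any(
            c.startswith(_BD_PREFIXES) and dx - LOOKBACK_DAYS <= d < dx
            for c, d in codes
        ):
            reasons.append("prior_bd")

        if any(
            s <= dx + WASHOUT_END and e >= dx + WASHOUT_START
            for s, e in washout_by_person.get(pid, [])
        ):
            reasons.append("washout_medication")

        fu_end = dx + FOLLOWUP_DAYS
        if any(
            c.startswith(_PSYCHOSIS_DEMENTIA_PREFIXES)
            and dx - LOOKBACK_DAYS <= d <= fu_end
            for c, d in codes
        ):
            reasons.append("psychosis_dementia")

        res_start = getattr(rec, "residency_start_day", None)
        res_end = getattr(rec, "residency_end_day", None)
        required_end = min(death, fu_end) if death is not None else fu_end
        if res_start is not None and res_end is not None and not (
            pd.isna(res_start) or pd.isna(res_end)
        ):
            if int(res_start) > dx - LOOKBACK_DAYS or int(res_end) < required_end:
                reasons.append("residency")

        birth = getattr(rec, "birth_day", None)
        if birth is not None and not pd.isna(birth):
            age = _age_at(dx, int(birth))
            if not AGE_MIN <= age <= AGE_MAX:
                reasons.append("age")

        rows.append((pid, not reasons, tuple(reasons)))

    return pd.DataFrame(rows, columns=["person_id", "included", "reasons"])


def eligible_persons(persons: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Subset of ``persons`` whose report row is included."""
    keep = set(report.loc[report["included"], "person_id"])
    return persons[persons["person_id"].isin(keep)].reset_index(drop=True)


def exclusion_log(report: pd.DataFrame) -> pd.DataFrame:
    """Long-format log: one row per (person, triggered reason)."""
    rows = [
        (r.person_id, reason)
        for r in report.itertuples(index=False)
        for reason in r.reasons
    ]
    return pd.DataFrame(rows, columns=["person_id", "exclusion_reason"])
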