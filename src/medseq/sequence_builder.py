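"""Per-person 12-period treatment-state sequences.

Follow-up starts at the incident diagnosis (day 0) and is divided into
twelve consecutive 91-day periods (1092 days). Each period is reduced to
four binary medication-use indicators (use on >= 50% of evaluable days,
inpatient days subtracted) and mapped to a treatment state; death
censors the period of occurrence and everything after it. Periods spent
mostly in hospital are substituted by the following period's state, and
sequences that cannot be evaluated are excluded with a named reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure_model import _ensure_day
from .states import (
    ALPHABET,
    CENSORED,
    DRUG_CLASSES,
    FOLLOWUP_DAYS,
    N_PERIODS,
    PERIOD_DAYS,
    assign_state,
)

#: Inpatient-day count at which a period can no longer be assessed
#: (>= 50% of 91 days).
INVALID_INPATIENT_DAYS = 46

EXCL_CENSORED_FIRST = "censored_first_period"
EXCL_CONSECUTIVE_INPATIENT = "consecutive_inpatient"

SEQUENCE_COLUMNS = ["person_id"] + [f"s{k}" for k in range(1, N_PERIODS + 1)]


def build_period_grid(diagnosis_day: int) -> list[tuple[int, int]]:
    """Half-open day intervals [dx + 91(k-1), dx + 91k) for k = 1..12."""
    return [
        (diagnosis_day + PERIOD_DAYS * k, diagnosis_day + PERIOD_DAYS * (k + 1))
        for k in range(N_PERIODS)
    ]


def _interval_mask(start: int, stop: int, intervals) -> np.ndarray:
    """Boolean day mask over [start, stop) covered by inclusive intervals."""
    mask = np.zeros(stop - start, dtype=bool)
    for a, b in intervals:
        lo = max(int(a), start)
        hi = min(int(b) + 1, stop)
        if hi > lo:
            mask[lo - start : hi - start] = True
    return mask


def binarize_period(
    use_periods: dict[str, list[tuple[int, int]]],
    period: tuple[int, int],
    hospital_stays: list[tuple[int, int]],
) -> tuple[dict[str, bool], bool]:
    """Four class-use indicators for one 91-day period.

    Parameters
    ----------
    use_periods
        Per medication class, inclusive (start_day, end_day) use
        intervals for the person.
    period
        Half-open (start, stop) day interval of the period.
    hospital_stays
        Inclusive (admit_day, discharge_day) intervals.

    Returns
    -------
    (indicators, valid)
        ``indicators[cls]`` is True when class use covers >= 50% of the
        period's non-hospital days. ``valid`` is False when >= 46 of the
        91 days were spent in hospital, in which case the indicators are
        meaningless and the period must be substituted.
    """
    start, stop = period
    hosp = _interval_mask(start, stop, hospital_stays)
    n_hosp = int(hosp.sum())
    if n_hosp >= INVALID_INPATIENT_DAYS:
        return {c: False for c in DRUG_CLASSES}, False
    denom = (stop - start) - n_hosp
    indicators = {}
    for cls in DRUG_CLASSES:
        used = _interval_mask(start, stop, use_periods.get(cls, ()))
        covered = int((used & ~hosp).sum())
        indicators[cls] = covered >= 0.5 * denom
    return indicators, True


@dataclass(frozen=True)
class SequenceResult:
    person_id: str
    states: tuple[str, ...] | None
    exclusion: str | None = None


def build_sequence(
    person_id: str,
    diagnosis_day: int,
    use_periods: dict[str, list[tuple[int, int]]],
    hospital_stays: list[tuple[int, int]],
    death_day: int | None = None,
) -> SequenceResult:
    """Assemble one person's 12-period state sequence.

    Death censors the period containing ``death_day`` and all later
    periods. A period with >= 46 inpatient days takes the state of the
    following period (resolved right to left); an invalid final period
    takes the state of period 11. Persons censored from period 1 or with
    two consecutive invalid periods are excluded.
    """
    grid = build_period_grid(diagnosis_day)

    censor_from = N_PERIODS  # first censored period index (0-based), 12 = none
    if death_day is not None and death_day < diagnosis_day + FOLLOWUP_DAYS:
        censor_from = max(0, (int(death_day) - diagnosis_day) // PERIOD_DAYS)
        if censor_from == 0:
            return SequenceResult(person_id, None, EXCL_CENSORED_FIRST)

    states: list[str | None] = [None] * N_PERIODS
    invalid = [False] * N_PERIODS
    for k in range(censor_from):
        ind, ok = binarize_period(use_periods, grid[k], hospital_stays)
        if ok:
            states[k] = assign_state(
                ind["antidepressant"],
                ind["anticonvulsant_ms"],
                ind["lithium"],
                ind["antipsychotic"],
            )
        else:
            invalid[k] = True
    for k in range(censor_from, N_PERIODS):
        states[k] = CENSORED

    for k in range(censor_from - 1):
        if invalid[k] and invalid[k + 1]:
            return SequenceResult(person_id, None, EXCL_CONSECUTIVE_INPATIENT)

    # Substitute invalid periods right to left so chains are well-defined;
    # an invalid period 12 has no successor and takes period 11's state.
    for k in range(censor_from - 1, -1, -1):
        if invalid[k]:
            if k + 1 < N_PERIODS:
                states[k] = states[k + 1]
            else:
                states[k] = states[k - 1]

    if states[0] == CENSORED:
        # substitution pulled censoring back into period 1
        return SequenceResult(person_id, None, EXCL_CENSORED_FIRST)
    assert all(s is not None for s in states)
    return SequenceResult(person_id, tuple(states))  # type: ignore[arg-type]


def build_sequences(
    persons: pd.DataFrame,
    use_periods: pd.DataFrame,
    hospital_stays: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vector wrapper over :func:`build_sequence` for register tables.

    Parameters
    ----------
    persons
        Must carry ``person_id`` and ``diagnosis_day`` (or
        ``diagnosis_date``); ``death_day``/``death_date`` optional.
    use_periods
        Output of :func:`medseq.exposure_model.build_use_periods`.
    hospital_stays
        ``person_id`` with ``admit_day``/``discharge_day`` (or dates).

    Returns
    -------
    (sequences, exclusions)
        ``sequences`` has columns ``person_id, s1..s12``; ``exclusions``
        has ``person_id, exclusion_reason``.
    """
    persons = _ensure_day(persons, "diagnosis_day", "diagnosis_date")
    persons = _ensure_day(persons, "death_day", "death_date")
    hospital_stays = _ensure_day(hospital_stays, "admit_day", "admit_date")
    hospital_stays = _ensure_day(hospital_stays, "discharge_day", "discharge_date")

    up_by_person: dict[str, dict[str, list[tuple[int, int]]]] = {}
    if len(use_periods):
        for (pid, cls), grp in use_periods.groupby(["person_id", "drug_class"]):
            up_by_person.setdefault(pid, {})[cls] = list(
                zip(grp["start_day"].astype(int), grp["end_day"].astype(int))
            )
    stays_by_person: dict[str, list[tuple[int, int]]] = {}
    if len(hospital_stays):
        for pid, grp in hospital_stays.groupby("person_id"):
            stays_by_person[pid] = list(
                zip(grp["admit_day"].astype(int), grp["discharge_day"].astype(int))
            )

    rows, excl = [], []
    for rec in persons.itertuples(index=False):
        pid = rec.person_id
        death = getattr(rec, "death_day", None)
        if death is not None and pd.isna(death):
            death = None
        res = build_sequence(
            pid,
            int(rec.diagnosis_day),
            up_by_person.get(pid, {}),
            stays_by_person.get(pid, []),
            int(death) if death is not None else None,
        )
        if res.exclusion is not None:
            excl.append((pid, res.exclusion))
        else:
            rows.append((pid, *res.states))

    seq_df = pd.DataFrame(rows, columns=SEQUENCE_COLUMNS)
    excl_df = pd.DataFrame(excl, columns=["person_id", "exclusion_reason"])
    return seq_df, excl_df


def sequences_to_array(sequences: pd.DataFrame) -> np.ndarray:
    """Encode an s1..s12 sequence table as an (n, 12) integer array."""
    idx = {s: i for i, s in enumerate(ALPHABET)}
    cols = [f"s{k}" for k in range(1, N_PERIODS + 1)]
    arr = np.empty((len(sequences), N_PERIODS), dtype=np.int64)
    for j, c in enumerate(cols):
        col = sequences[c].map(idx)
        if col.isna().any():
            bad = sorted(set(sequences[c]) - set(ALPHABET))
            raise ValueError(f"unknown state symbols: {bad}")
        arr[:, j] = col.to_numpy()
    return arr
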