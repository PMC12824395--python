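"""Dispensing records → continuous drug-use periods per medication class.

A deliberately simple drug-exposure model: each dispensation covers a run
of days starting at the dispense date, the run length being a sliding
mean of the person's recent days-of-supply within the class (smoothing
over stockpiling), and runs separated by at most ``grace_days`` are
merged into one continuous use period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import ANTICONVULSANT_MS, ANTIDEPRESSANT, ANTIPSYCHOTIC, LITHIUM_CLASS

log = logging.getLogger(__name__)

#: Default ATC prefix → class rules. Longest matching prefix wins, so the
#: lithium rule (N05AN) shadows the general antipsychotic rule (N05A).
#: These defaults are configurable and not authoritative: real analyses
#: should supply the code list used by their register.
DEFAULT_ATC_RULES: tuple[tuple[str, str], ...] = (
    ("N06A", ANTIDEPRESSANT),
    ("N03A", ANTICONVULSANT_MS),
    ("N05AN", LITHIUM_CLASS),
    ("N05A", ANTIPSYCHOTIC),
)


@dataclass(frozen=True)
class AtcClassMap:
    """Ordered ATC-prefix → medication-class rules (longest prefix wins)."""

    rules: tuple[tuple[str, str], ...] = DEFAULT_ATC_RULES

    def classify(self, atc_code: str) -> str | None:
        return classify_atc(atc_code, self)

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "AtcClassMap":
        return cls(tuple(mapping.items()))


def classify_atc(atc_code: str, class_map: AtcClassMap | None = None) -> str | None:
    """Resolve an ATC code to a medication class by longest-prefix match.

    Returns ``None`` when no rule matches (the drug is outside the four
    tracked classes).
    """
    if not atc_code:
        raise ValueError("empty ATC code")
    if class_map is None:
        class_map = AtcClassMap()
    best: tuple[int, str] | None = None
    for prefix, cls in class_map.rules:
        if atc_code.startswith(prefix):
            if best is None or len(prefix) > best[0]:
                best = (len(prefix), cls)
    return best[1] if best else None


@dataclass(frozen=True)
class ExposureParams:
    """Tunables of the exposure model.

    ``window`` dispensations enter the sliding mean of days-of-supply;
    ``grace_days`` is the largest gap (in days) bridged when merging
    consecutive covered runs into one use period.
    """

    grace_days: int = 30
    window: int = 3
    strict: bool = False

    def __post_init__(self) -> None:
        if self.grace_days < 0 or self.window < 1:
            raise ValueError("grace_days must be >= 0 and window >= 1")


USE_PERIOD_COLUMNS = ["person_id", "drug_class", "start_day", "end_day"]


def to_day(dates) -> pd.Series:
    """Convert a date-like column to proleptic-Gregorian ordinal days
    (missing dates stay missing)."""
    return pd.to_datetime(dates).map(pd.Timestamp.toordinal, na_action="ignore")


def _ensure_day(df: pd.DataFrame, day_col: str, date_col: str) -> pd.DataFrame:
    if day_col in df.columns or date_col not in df.columns:
        return df
    out = df.copy()
    out[day_col] = to_day(out[date_col])
    return out


def build_use_periods(
    dispensings: pd.DataFrame,
    class_map: AtcClassMap | None = None,
    params: ExposureParams | None = None,
) -> pd.DataFrame:
    """Convert dispensing records into maximal non-overlapping use periods.

    Parameters
    ----------
    dispensings
        Columns ``person_id``, ``atc_code``, ``dispense_day`` (integer
        day, any common origin) and ``days_supply``.
    class_map
        ATC prefix rules; defaults to :data:`DEFAULT_ATC_RULES`.
    params
        Grace period and sliding-window width.

    Returns
    -------
    pandas.DataFrame
        Columns ``person_id, drug_class, start_day, end_day`` with
        inclusive day bounds, sorted, one row per maximal period.

    Notes
    -----
    Per person and class, dispensations are processed in date order; the
    k-th covers ``[date, date + round(mean supply of last w dispensations)
    - 1]``. Runs whose gap is at most ``grace_days`` are merged. Unknown
    ATC codes raise in strict mode and are otherwise skipped with a log
    entry.
    """
    if class_map is None:
        class_map = AtcClassMap()
    if params is None:
        params = ExposureParams()

    if len(dispensings) == 0:
        return pd.DataFrame(columns=USE_PERIOD_COLUMNS)

    df = _ensure_day(dispensings, "dispense_day", "dispense_date").copy()
    classes = df["atc_code"].map(lambda c: classify_atc(c, class_map))
    unknown = classes.isna()
    if unknown.any():
        if params.strict:
            bad = sorted(df.loc[unknown, "atc_code"].unique())
            raise ValueError(f"unmapped ATC codes in strict mode: {bad}")
        log.info("skipping %d dispensings with unmapped ATC codes", int(unknown.sum()))
        df = df.loc[~unknown]
        classes = classes.loc[~unknown]
    df = df.assign(drug_class=classes)
    if len(df) == 0:
        return pd.DataFrame(columns=USE_PERIOD_COLUMNS)

    df = df.sort_values(
        ["person_id", "drug_class", "dispense_day", "days_supply"], kind="mergesort"
    )

    out: list[tuple] = []
    for (pid, cls), grp in df.groupby(["person_id", "drug_class"], sort=True):
        days = grp["dispense_day"].to_numpy()
        supply = grp["days_supply"].to_numpy(dtype=float)
        if (supply < 1).any():
            raise ValueError(f"days_supply < 1 for person {pid!r}")
        cur_start: int | None = None
        cur_end = 0
        for i in range(len(days)):
            lo = max(0, i - params.window + 1)
            est = int(round(supply[lo : i + 1].mean()))
            est = max(est, 1)
            start, end = int(days[i]), int(days[i]) + est - 1
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start - cur_end - 1 <= params.grace_days:
                cur_end = max(cur_end, end)
            else:
                out.append((pid, cls, cur_start, cur_end))
                cur_start, cur_end = start, end
        out.append((pid, cls, cur_start, cur_end))

    return pd.DataFrame(out, columns=USE_PERIOD_COLUMNS)
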