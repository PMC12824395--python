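"""Initiation, discontinuation and trajectory taxonomy.

The seven treatment states are dichotomised to lack-of-treatment vs any
treatment; initiation is the first entry into treatment, discontinuation
the first fall back into lack. Periods are 3 months, so period 1 maps to
months 0–3 ("early" initiation), periods 2–4 to months 4–12, periods
5–12 to beyond a year; discontinuation gaps of <= 2, 3–4, 5–8 and >= 9
periods map to within 6 months, 1 year, 2 years and after 2 years.
Censored periods end the evaluable window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .states import CENSORED, LACK
from .util import percent

INITIATION_CLASSES = ("early_0_3m", "delayed_4_12m", "delayed_ge12m", "never")
DISCONTINUATION_CLASSES = ("none", "within_6m", "within_1y", "within_2y", "after_2y")
TRAJECTORIES = (
    "early_no_disc",
    "early_disc",
    "delayed_no_disc",
    "delayed_disc",
    "continuous_lack",
)


@dataclass(frozen=True)
class TrajectoryRecord:
    person_id: str
    initiated: bool
    initiation_class: str
    initiation_period: int | None  # 1-based, None if never
    discontinued: bool
    discontinuation_class: str
    trajectory: str


def dichotomize(states) -> list[int]:
    """Treatment (1) / lack (0) indicators over the evaluable window.

    The returned list stops at the first censored period; any state
    other than lack-of-treatment counts as treatment.
    """
    out = []
    for s in states:
        if s == CENSORED:
            break
        out.append(0 if s == LACK else 1)
    return out


def classify_initiation(
    binary_seq, pre_dx_ad_monotherapy: bool = False
) -> tuple[str, int | None]:
    """Initiation class and 1-based initiation period.

    A first treatment period at period 1 (or antidepressant monotherapy
    carried over the diagnosis into period 1) is early; periods 2–4 are
    delayed by 4–12 months; 5–12 delayed by a year or more.
    """
    first = next((i + 1 for i, b in enumerate(binary_seq) if b), None)
    if first is None:
        return "never", None
    if first == 1 or (pre_dx_ad_monotherapy and binary_seq[0] == 1):
        return "early_0_3m", first
    if first <= 4:
        return "delayed_4_12m", first
    return "delayed_ge12m", first


def classify_discontinuation(binary_seq, initiation_period: int | None) -> str:
    """Bin the first treatment → lack transition by time since initiation.

    Only the first such transition counts; later re-initiations are
    ignored. Returns "none" when no transition occurs in the evaluable
    window (including never-initiators).
    """
    if initiation_period is None:
        return "none"
    u = None
    for t in range(initiation_period, len(binary_seq)):
        if binary_seq[t] == 0 and binary_seq[t - 1] == 1:
            u = t + 1
            break
    if u is None:
        return "none"
    gap = u - initiation_period
    if gap <= 2:
        return "within_6m"
    if gap <= 4:
        return "within_1y"
    if gap <= 8:
        return "within_2y"
    return "after_2y"


def classify_trajectory(initiation_class: str, discontinued: bool) -> str:
    """Cross early/delayed initiation with any-vs-no discontinuation."""
    if initiation_class == "never":
        return "continuous_lack"
    stem = "early" if initiation_class == "early_0_3m" else "delayed"
    return f"{stem}_disc" if discontinued else f"{stem}_no_disc"


def classify_person(
    person_id: str, states, pre_dx_ad_monotherapy: bool = False
) -> TrajectoryRecord:
    binary = dichotomize(states)
    init_class, init_period = classify_initiation(binary, pre_dx_ad_monotherapy)
    disc_class = classify_discontinuation(binary, init_period)
    discontinued = disc_class != "none"
    return TrajectoryRecord(
        person_id=person_id,
        initiated=init_period is not None,
        initiation_class=init_class,
        initiation_period=init_period,
        discontinued=discontinued,
        discontinuation_class=disc_class,
        trajectory=classify_trajectory(init_class, discontinued),
    )


def classify_trajectories(
    sequences: pd.DataFrame, pre_dx_ad_flags: pd.Series | None = None
) -> pd.DataFrame:
    """Per-person trajectory table from an s1..s12 sequence frame."""
    cols = [c for c in sequences.columns if c.startswith("s") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    flags = {} if pre_dx_ad_flags is None else dict(pre_dx_ad_flags)
    recs = []
    for row in sequences.itertuples(index=False):
        pid = row.person_id
        states = [getattr(row, c) for c in cols]
        recs.append(classify_person(pid, states, bool(flags.get(pid, False))))
    return pd.DataFrame([r.__dict__ for r in recs])


def summarize_trajectories(
    records: pd.DataFrame, group_labels: pd.Series
) -> pd.DataFrame:
    """Counts and percentages per population group, printed-table style.

    Sections: initiation yes/no (all persons); time to initiation (among
    initiators); discontinuation yes/no and time to discontinuation
    (among persons initiating within a year of diagnosis, i.e. periods
    1–4); and the five initiation × discontinuation trajectories (all
    persons). Percentages are rounded half-up to one decimal of their
    section denominator.
    """
    df = records.merge(
        group_labels.rename("group"), left_on="person_id", right_index=True
    ) if "group" not in records.columns else records
    if "group" not in df.columns:
        raise ValueError("records need a 'group' column or a group_labels index")
    rows = []

    def emit(section: str, row_name: str, sub: pd.DataFrame, mask) -> None:
        for g, grp in sub.groupby("group", sort=False):
            n = len(grp)
            c = int(mask(grp).sum())
            rows.append((section, row_name, g, c, n, percent(c, n)))

    emit("initiation", "yes", df, lambda d: d["initiated"])
    emit("initiation", "no", df, lambda d: ~d["initiated"])
    initiators = df[df["initiated"]]
    for cls in ("early_0_3m", "delayed_4_12m", "delayed_ge12m"):
        emit(
            "time_to_initiation", cls, initiators,
            lambda d, cls=cls: d["initiation_class"] == cls,
        )
    within_year = df[df["initiation_period"].notna() & (df["initiation_period"] <= 4)]
    emit("discontinuation", "no", within_year, lambda d: ~d["discontinued"])
    emit("discontinuation", "yes", within_year, lambda d: d["discontinued"])
    disc = within_year[within_year["discontinued"]]
    for cls in ("within_6m", "within_1y", "within_2y", "after_2y"):
        emit(
            "time_to_discontinuation", cls, disc,
            lambda d, cls=cls: d["discontinuation_class"] == cls,
        )
    for traj in TRAJECTORIES:
        emit("trajectory", traj, df, lambda d, t=traj: d["trajectory"] == t)
    return pd.DataFrame(
        rows, columns=["section", "row", "group", "count", "denominator", "percent"]
    )
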