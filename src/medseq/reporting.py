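"""Printed-table style summaries (counts with percentages per group)."""

from __future__ import annotations

import pandas as pd

from .synthetic_registry import POPULATION_GROUPS
from .trajectory_stats import summarize_trajectories
from .util import percent


def typology_table(
    typology_labels: pd.DataFrame, group_labels: pd.Series
) -> pd.DataFrame:
    """Typology membership counts and percentages per population group.

    ``typology_labels`` carries ``person_id`` and ``typology_name``;
    ``group_labels`` is indexed by person_id. Percentages use the group
    size as denominator.
    """
    df = typology_labels.merge(
        group_labels.rename("group"), left_on="person_id", right_index=True
    )
    rows = []
    order = [g for g in POPULATION_GROUPS if g in set(df["group"])] + sorted(
        set(df["group"]) - set(POPULATION_GROUPS)
    )
    names = list(pd.unique(df["typology_name"]))
    for g in order:
        sub = df[df["group"] == g]
        n = len(sub)
        for name in names:
            c = int((sub["typology_name"] == name).sum())
            rows.append(("typology", name, g, c, n, percent(c, n)))
    return pd.DataFrame(
        rows, columns=["section", "row", "group", "count", "denominator", "percent"]
    )


def table_one(
    persons: pd.DataFrame,
    trajectories: pd.DataFrame,
    typology_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the three-section cohort summary.

    Section A/B: initiation, discontinuation and trajectory rows from
    the trajectory records; section C: typology membership (when
    cluster labels are supplied). Percentages are rounded half-up to
    one decimal; :func:`validate_table` re-derives each from its count
    and denominator.
    """
    groups = persons.set_index("person_id")["population_group"]
    recs = trajectories.merge(
        groups.rename("group"), left_on="person_id", right_index=True
    )
    order = [g for g in POPULATION_GROUPS if g in set(recs["group"])]
    recs["group"] = pd.Categorical(recs["group"], categories=order, ordered=True)
    recs = recs.sort_values("group", kind="mergesort")
    recs["group"] = recs["group"].astype(str)
    out = summarize_trajectories(recs, groups)
    if typology_labels is not None:
        out = pd.concat([out, typology_table(typology_labels, groups)], ignore_index=True)
    validate_table(out)
    return out.reset_index(drop=True)


def validate_table(table: pd.DataFrame) -> None:
    """Check every printed percentage against its count and denominator."""
    for r in table.itertuples(index=False):
        expect = percent(r.count, r.denominator)
        if not (pd.isna(expect) and pd.isna(r.percent)) and expect != r.percent:
            raise AssertionError(
                f"inconsistent percentage in row {r}: expected {expect}"
            )
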