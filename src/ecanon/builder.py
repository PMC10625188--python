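"""Cohort selection and index-date assignment.

The real-world arm enters the study at an index date: NOAC-naïve subjects at
their first NOAC prescription, and a randomly chosen fraction of subjects as
"artificial current users" whose entry is shifted forward by a treatment
duration drawn from the trial arm's observed on-treatment times.  This
mirrors how a trial enrolls a mix of new and prevalent users, and prevents
the external arm from being all new users.  Overall survival is then
recomputed from the index date, censored at the study-end date; subjects
whose death precedes their (artificial) index date are dropped — keeping
them would credit immortal person-time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "SelectionCriteria",
    "apply_selection",
    "assign_index_dates",
    "derive_analysis_table",
]

log = logging.getLogger("ecanon.builder")


@dataclass(frozen=True)
class SelectionCriteria:
    min_age: float = 45.0
    noac_window: tuple[str, str] = ("2014-01-01", "2019-09-30")
    require_af_before_noac: bool = True

    def __post_init__(self):
        if not pd.Timestamp(self.noac_window[0]) < pd.Timestamp(self.noac_window[1]):
            raise ValueError("noac_window start must precede end")


def apply_selection(table: CohortTable, criteria: SelectionCriteria) -> CohortTable:
    """Filter to eligible subjects (age, NOAC window, AF before NOAC); order preserved.

    The synthetic generator produces the time-since-AF category directly, so
    an AF diagnosis before NOAC initiation holds by construction and that
    criterion removes nobody unless an explicit ``af_before_noac`` flag
    column is present.
    """
    for col in ("age", "first_noac_date"):
        if col not in table.data.columns:
            raise ValueError(f"selection requires column {col!r}")
    df = table.data
    keep = pd.Series(True, index=df.index)

    age_ok = df["age"] >= criteria.min_age
    log.info("selection: %d removed by age >= %g", int((~age_ok).sum()), criteria.min_age)
    keep &= age_ok

    start, end = (pd.Timestamp(d) for d in criteria.noac_window)
    win_ok = (df["first_noac_date"] >= start) & (df["first_noac_date"] <= end)
    log.info("selection: %d removed by NOAC window", int((keep & ~win_ok).sum()))
    keep &= win_ok

    if criteria.require_af_before_noac and "af_before_noac" in df.columns:
        af_ok = df["af_before_noac"].astype(bool)
        log.info("selection: %d removed by AF-before-NOAC", int((keep & ~af_ok).sum()))
        keep &= af_ok

    return CohortTable(df.loc[keep].reset_index(drop=True), table.arm)


def assign_index_dates(
    table: CohortTable,
    rct_durations,
    target_current_fraction: float,
    censor_date,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag round(f·n) subjects as artificial current users and give each a
    treatment offset sampled with replacement from ``rct_durations``,
    truncated so the index date stays at least one day before the censor
    date.  Returns one assignment row per subject."""
    if not 0.0 <= target_current_fraction <= 1.0:
        raise ValueError("target_current_fraction outside [0, 1]")
    durations = np.asarray(rct_durations, dtype=float)
    if target_current_fraction > 0 and durations.size == 0:
        raise ValueError("rct_durations must be non-empty when fraction > 0")

    rng = np.random.default_rng(seed)
    n = table.n
    n_current = int(round(target_current_fraction * n))
    current_idx = rng.choice(n, size=n_current, replace=False) if n_current else np.array([], int)
    is_current = np.zeros(n, dtype=bool)
    is_current[current_idx] = True

    offsets = np.zeros(n, dtype=np.int64)
    if n_current:
        offsets[is_current] = rng.choice(durations, size=n_current, replace=True).astype(np.int64)

    censor = pd.Timestamp(censor_date)
    first = pd.to_datetime(table.data["first_noac_date"]).reset_index(drop=True)
    max_offset = (censor - first).dt.days - 1
    offsets = np.minimum(offsets, np.maximum(max_offset.to_numpy(), 0))

    return pd.DataFrame(
        {
            "subject_id": table.data["subject_id"].to_numpy(),
            "index_date": first + pd.to_timedelta(offsets, unit="D"),
            "is_artificial_current_user": is_current,
            "treatment_offset_days": offsets,
        }
    )


def derive_analysis_table(
    table: CohortTable, assignments: pd.DataFrame, censor_date
) -> CohortTable:
    """Recompute overall survival from the assigned index date.

    ``os_time`` = days from index date to death or censoring, whichever is
    first; ``os_event`` = 1 iff the death is observed by the censor date.
    Subjects dead before their artificial index date are dropped (logged).
    """
    missing = set(table.data["subject_id"]) - set(assignments["subject_id"])
    if missing:
        raise ValueError(f"{len(missing)} subjects lack an index assignment")
    censor = pd.Timestamp(censor_date)
    df = table.data.merge(
        assignments[["subject_id", "index_date", "is_artificial_current_user"]].rename(
            columns={"index_date": "_idx"}
        ),
        on="subject_id",
        how="left",
    )
    df["index_date"] = df["_idx"]
    df = df.drop(columns="_idx")

    death = pd.to_datetime(df["death_date"])
    dead_before_index = death.notna() & (death < df["index_date"])
    n_drop = int(dead_before_index.sum())
    if n_drop:
        log.info("analysis table: dropped %d subjects dead before artificial index", n_drop)
    df = df.loc[~dead_before_index].reset_index(drop=True)

    death = pd.to_datetime(df["death_date"])
    event = death.notna() & (death <= censor)
    end = death.where(event, censor)
    os_time = (end - df["index_date"]).dt.days.astype(float)
    assert (os_time >= 0).all(), "negative follow-up after immortal-time drop"
    df["os_time"] = os_time
    df["os_event"] = event.astype(int)
    return CohortTable(df, table.arm)
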