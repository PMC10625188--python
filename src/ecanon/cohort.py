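"""Subject-level cohort container and CSV round-tripping.

A :class:`CohortTable` is the currency every stage of the pipeline consumes
and produces: one row per subject, carrying baseline covariates, the
exposure/entry dates and (for the real-world arm) the overall-survival
outcome.  Internally it is a plain :class:`pandas.DataFrame` with a fixed set
of bookkeeping columns; dates are stored as ``datetime64`` and serialized as
ISO-8601.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import CovariateSpec

__all__ = ["CohortTable", "ID_COL", "DATE_COLS", "OUTCOME_COLS"]

ID_COL = "subject_id"
DATE_COLS = ("first_noac_date", "index_date", "death_date")
OUTCOME_COLS = ("os_time", "os_event")
ARM_COL = "arm_label"


@dataclass
class CohortTable:
    """One row per subject; covariates plus dates, outcome and arm label."""

    data: pd.DataFrame
    arm: str = "RWD"

    def __post_init__(self):
        if ID_COL not in self.data.columns:
            raise ValueError(f"cohort table must carry a {ID_COL!r} column")
        if self.data[ID_COL].duplicated().any():
            raise ValueError("subject_id values must be unique within a table")
        self.data = self.data.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    def covariate_frame(self, specs: Sequence[CovariateSpec]) -> pd.DataFrame:
        return self.data[[s.name for s in specs]]

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.arm)

    def validate(self, specs: Sequence[CovariateSpec]) -> None:
        """Check covariate values against their schema domains; raise on violation."""
        for s in specs:
            col = self.data[s.name]
            if s.kind == "binary":
                bad = ~col.isin([0, 1])
            elif s.kind == "categorical":
                bad = ~col.isin(list(s.levels))
            elif s.kind == "continuous":
                lo, hi = s.bounds
                bad = (col < lo) | (col > hi)
            else:
                continue
            if bad.any():
                raise ValueError(f"{int(bad.sum())} out-of-domain values in {s.name!r}")
        if "os_time" in self.data and self.data["os_time"].notna().any():
            t = self.data["os_time"].dropna()
            if (t < 0).any():
                raise ValueError("negative os_time")
            ev = self.data.loc[t.index, "os_event"]
            if not ev.isin([0, 1]).all():
                raise ValueError("os_event must be 0/1")

    # ------------------------------------------------------------------ IO
    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        for c in DATE_COLS:
            if c in out.columns:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, arm: str | None = None) -> "CohortTable":
        df = pd.read_csv(path)
        for c in DATE_COLS:
            if c in df.columns:
                df[c] = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        if arm is None:
            arm = str(df[ARM_COL].iloc[0]) if ARM_COL in df.columns and len(df) else "RWD"
        return cls(df, arm)
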