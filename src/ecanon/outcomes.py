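"""Overall-survival estimation and the pseudonymized-vs-anonymized contrast.

Kaplan–Meier curves (optionally weighted) with Greenwood standard errors
and log(−log) confidence bands, and Cox proportional-hazards fits with
Efron tie handling, both through lifelines.  The headline comparison of the
pipeline stacks the pseudonymized and anonymized versions of the same
cohort with a dataset indicator and reports the indicator's hazard ratio —
anonymization distortion expressed on the hazard scale.  The two versions
of each subject are treated as independent samples (plain Wald CI), with a
robust-variance option for readers who prefer a clustered analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .cohort import CohortTable

__all__ = ["SurvivalCurve", "CoxResult", "kaplan_meier", "cox_fit", "anonymization_contrast"]


@dataclass
class SurvivalCurve:
    times: np.ndarray  # distinct event times, sorted
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S(t) = 1 before the first event."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per term: coef, hr, ci_lower, ci_upper, p
    log_likelihood: float
    converged: bool
    ties_method: str = "efron"

    def hr(self, term: str | None = None) -> float:
        t = term or self.summary.index[0]
        return float(self.summary.loc[t, "hr"])

    def ci(self, term: str | None = None) -> tuple[float, float]:
        t = term or self.summary.index[0]
        return (
            float(self.summary.loc[t, "ci_lower"]),
            float(self.summary.loc[t, "ci_upper"]),
        )

    def p_value(self, term: str | None = None) -> float:
        t = term or self.summary.index[0]
        return float(self.summary.loc[t, "p"])


def kaplan_meier(times, events, weights=None, alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance and log(−log) CI.

    With weights, the weighted at-risk and event counts enter both the
    product-limit steps and the Greenwood sum.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    e = np.asarray(events)
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be >= 0")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e, weights=w)
    table = kmf.event_table
    mask = table["observed"] > 0
    et = table.index.to_numpy(float)[mask.to_numpy()]
    d = table.loc[mask, "observed"].to_numpy(float)
    n = table.loc[mask, "at_risk"].to_numpy(float)

    s = np.cumprod(1.0 - d / n)
    # Greenwood: Var(S) = S^2 * cumsum d / (n (n - d)); guard terminal d == n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    se = s * np.sqrt(np.cumsum(terms))
    se = np.where(np.isfinite(se), se, 0.0)

    ci = kmf.confidence_interval_
    lo = np.interp(et, ci.index.to_numpy(float), ci.iloc[:, 0].to_numpy())
    hi = np.interp(et, ci.index.to_numpy(float), ci.iloc[:, 1].to_numpy())
    return SurvivalCurve(et, n, d, s, se, lo, hi)


def cox_fit(
    times,
    events,
    design: pd.DataFrame,
    weights=None,
    robust: bool = False,
    alpha: float = 0.05,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald CI and p per term).

    Monotone-likelihood cases (e.g. a no-event group indicator) are flagged
    as non-converged with an effectively infinite hazard ratio rather than
    raised.
    """
    x = pd.DataFrame(design).reset_index(drop=True)
    df = x.copy()
    df["T"] = np.asarray(times, dtype=float)
    df["E"] = np.asarray(events, dtype=int)
    if df["E"].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    kwargs = {}
    if weights is not None:
        df["_w"] = np.asarray(weights, dtype=float)
        kwargs["weights_col"] = "_w"
    cph = CoxPHFitter(alpha=alpha)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="T", event_col="E", robust=robust, **kwargs)
        except ConvergenceError:
            # monotone likelihood (e.g. one group without events): report a
            # diverging-HR diagnostic instead of raising
            terms = list(x.columns)
            out = pd.DataFrame(
                {
                    "coef": np.inf,
                    "hr": np.inf,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "p": np.nan,
                },
                index=pd.Index(terms),
            )
            return CoxResult(summary=out, log_likelihood=np.nan, converged=False)
    summ = cph.summary
    with np.errstate(over="ignore"):
        out = pd.DataFrame(
            {
                "coef": summ["coef"],
                "hr": summ["exp(coef)"],
                "ci_lower": np.exp(summ["coef lower 95%"]),
                "ci_upper": np.exp(summ["coef upper 95%"]),
                "p": summ["p"],
            }
        )
    if np.abs(out["coef"]).max() > 10:
        converged = False  # monotone-likelihood diagnostic: HR diverging
    return CoxResult(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
    )


def _outcome_frame(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    df = table.data if isinstance(table, CohortTable) else table
    if "os_time" not in df.columns or df["os_time"].isna().all():
        raise ValueError("table carries no overall-survival outcome")
    out = df[["os_time", "os_event"]].dropna()
    return out


def anonymization_contrast(
    pseudo: CohortTable,
    anon: CohortTable,
    subset: str = "all",
    pseudo_ids=None,
    anon_ids=None,
    robust: bool = False,
) -> tuple[CoxResult, SurvivalCurve, SurvivalCurve]:
    """Hazard ratio of anonymized vs pseudonymized overall survival.

    ``subset`` selects ``all`` rows, the ``matched`` control subjects of each
    data version (ids supplied per version, since matching is re-run on each),
    or the ``unmatched`` complement.  Returns the indicator-only Cox result
    plus the two Kaplan–Meier curves (pseudonymized first).
    """
    frames = []
    for tbl, ids, flag in ((pseudo, pseudo_ids, 0), (anon, anon_ids, 1)):
        df = tbl.data if isinstance(tbl, CohortTable) else tbl
        if subset != "all":
            if ids is None:
                raise ValueError(f"subset={subset!r} requires matched ids per version")
            sel = df["subject_id"].isin(set(ids))
            df = df.loc[sel] if subset == "matched" else df.loc[~sel]
        out = _outcome_frame(df)
        out = out.assign(anonymized=flag)
        frames.append(out)
    stacked = pd.concat(frames, ignore_index=True)
    cox = cox_fit(stacked["os_time"], stacked["os_event"], stacked[["anonymized"]], robust=robust)
    km_pseudo = kaplan_meier(frames[0]["os_time"], frames[0]["os_event"])
    km_anon = kaplan_meier(frames[1]["os_time"], frames[1]["os_event"])
    return cox, km_pseudo, km_anon
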