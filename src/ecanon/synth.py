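"""Synthetic cohort generator.

Emulates the two study populations — a registry-derived real-world arm
(default n = 3,327) with an overall-survival outcome, and a trial control arm
(default n = 250) with baseline data only — so that the whole anonymization /
external-control-arm pipeline can be exercised without access-restricted
data.

Mechanics
---------
Baseline covariates are drawn through a Gaussian copula: a latent
multivariate normal vector with a configurable correlation matrix is mapped
through the standard-normal CDF and thresholded (binary), bucketed
(categorical) or quantile-transformed to a truncated normal (continuous).
Thresholding a copula leaves each marginal at its target in expectation
regardless of the latent correlation.

Survival in the real-world arm follows a Weibull proportional-hazards model:
with baseline cumulative hazard ``H0(t) = (t / scale)^shape`` and linear
predictor ``lp = Σ β_j (x_j − ref_j)``, the event time is
``T = scale · (E / exp(lp))^(1/shape)`` for a unit exponential ``E``.
Continuous covariates are centred at their target mean in the linear
predictor; binaries are left on the 0/1 scale.  Follow-up is administratively
censored at a fixed study-end date; death dates beyond that date are not
recorded (as a registry would not know them at data-lock).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .schema import CovariateSpec, default_covariates

__all__ = [
    "CohortConfig",
    "default_latent_correlation",
    "generate_cohort",
    "summarize_marginals",
    "render_marginals",
]

_SMALL_CELL = 5  # rendered counts below this are masked "< 5"


def default_latent_correlation(
    specs: Sequence[CovariateSpec],
    flag_rho: float = 0.15,
    age_rho: float = 0.25,
) -> np.ndarray:
    """Exchangeable latent correlation among comorbidity flags, plus an
    age → flag correlation; sex and the categorical variables stay
    independent.  The source populations publish no correlation structure,
    so this is a deliberately simple, configurable stand-in."""
    names = [s.name for s in specs]
    p = len(names)
    r = np.eye(p)
    flags = [
        i
        for i, s in enumerate(specs)
        if s.kind == "binary" and s.name != "sex_male"
    ]
    for a in flags:
        for b in flags:
            if a != b:
                r[a, b] = flag_rho
    if "age" in names:
        ia = names.index("age")
        for b in flags:
            r[ia, b] = r[b, ia] = age_rho
    return r


@dataclass
class CohortConfig:
    """Everything the generator (and downstream index-date logic) needs.

    ``covariates`` maps arm label → list of :class:`CovariateSpec`; the two
    arms share names/kinds but target different marginal columns.
    ``log_hazard_ratios`` maps covariate name → β on the log-hazard scale
    (categorical variables may map to a per-level dict).
    """

    n_rwd: int = 3327
    n_rct: int = 250
    covariates: Mapping[str, list[CovariateSpec]] = field(
        default_factory=lambda: {
            "RWD": default_covariates("RWD"),
            "RCT": default_covariates("RCT"),
        }
    )
    latent_correlation: np.ndarray | None = None  # None -> default builder
    log_hazard_ratios: Mapping[str, object] = field(
        default_factory=lambda: {
            "age": 0.055,
            "sex_male": 0.20,
            "anemia": 0.30,
            "chronic_heart_failure": 0.50,
            "chronic_kidney_disease": 0.40,
            "copd": 0.40,
            "diabetes_mellitus": 0.20,
            "history_of_stroke": 0.25,
            "malignancy": 0.60,
            "myocardial_infarction": 0.30,
        }
    )
    baseline_hazard: tuple[float, float] = (1.2, 5700.0)  # (shape, scale days)
    study_entry_window: tuple[str, str] = ("2014-01-01", "2019-09-30")
    censor_date: str = "2020-12-31"
    current_user_fraction: float = 0.584
    rct_duration_mean_days: float = 180.0
    seed: int = 0

    def __post_init__(self):
        start = pd.Timestamp(self.study_entry_window[0])
        end = pd.Timestamp(self.study_entry_window[1])
        censor = pd.Timestamp(self.censor_date)
        if not (start < end <= censor):
            raise ValueError("require study_entry_window start < end <= censor_date")
        if not 0.0 <= self.current_user_fraction <= 1.0:
            raise ValueError("current_user_fraction outside [0, 1]")
        shape, scale = self.baseline_hazard
        if shape <= 0 or scale <= 0:
            raise ValueError("Weibull baseline requires positive shape and scale")

    def correlation_for(self, specs: Sequence[CovariateSpec]) -> np.ndarray:
        r = (
            default_latent_correlation(specs)
            if self.latent_correlation is None
            else np.asarray(self.latent_correlation, dtype=float)
        )
        p = len(specs)
        if r.shape != (p, p):
            raise ValueError(f"latent correlation must be {p}x{p}, got {r.shape}")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("latent correlation must have unit diagonal")
        if not np.allclose(r, r.T):
            raise ValueError("latent correlation must be symmetric")
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-8:
            raise ValueError(
                f"latent correlation not positive semidefinite (min eigenvalue {w.min():.3g})"
            )
        return r


def _latent_to_values(u: np.ndarray, spec: CovariateSpec, rng: np.random.Generator):
    """Map a uniform column (copula margin) to values of one covariate."""
    if spec.kind == "binary":
        return (u < float(spec.target_marginal)).astype(np.int64)
    if spec.kind == "categorical":
        probs = dict(spec.target_marginal)
        levels = list(probs)
        cuts = np.cumsum([probs[l] for l in levels])
        idx = np.searchsorted(cuts, u, side="right").clip(max=len(levels) - 1)
        return np.asarray(levels, dtype=object)[idx]
    if spec.kind == "continuous":
        mean, sd, lo, hi = spec.target_marginal
        a, b = (lo - mean) / sd, (hi - mean) / sd
        x = stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mean, scale=sd)
        if spec.integer_valued:
            x = np.rint(x)
        return x
    raise ValueError(f"cannot generate kind {spec.kind!r}")


def _linear_predictor(df: pd.DataFrame, specs, betas: Mapping[str, object]) -> np.ndarray:
    lp = np.zeros(len(df))
    by_name = {s.name: s for s in specs}
    for name, beta in betas.items():
        if name not in by_name:
            raise KeyError(f"log-hazard ratio for unknown covariate {name!r}")
        spec = by_name[name]
        if spec.kind == "continuous":
            mean = spec.target_marginal[0]
            lp += float(beta) * (df[name].to_numpy(float) - mean)
        elif spec.kind == "binary":
            lp += float(beta) * df[name].to_numpy(float)
        else:  # categorical: per-level dict, reference levels at 0
            for level, b in dict(beta).items():
                lp += float(b) * (df[name] == level).to_numpy(float)
    return lp


def generate_cohort(config: CohortConfig, arm: str = "RWD") -> CohortTable:
    """Draw one synthetic arm.

    Real-world arm rows carry ``first_noac_date``, a (possibly missing)
    ``death_date`` and overall survival measured from first NOAC use,
    censored at ``config.censor_date``.  Trial-arm rows carry baseline data
    only.  Identical config + seed yields an identical table.
    """
    if arm not in config.covariates:
        raise ValueError(f"no covariate column for arm {arm!r}")
    specs = config.covariates[arm]
    n = config.n_rwd if arm == "RWD" else config.n_rct
    corr = config.correlation_for(specs)
    rng = np.random.default_rng([config.seed, 0 if arm == "RWD" else 1])

    # latent Gaussian draw; tiny jitter keeps Cholesky happy at eigenvalue ~0
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(specs)))
    z = rng.standard_normal((n, len(specs))) @ chol.T
    u = stats.norm.cdf(z)

    data = {s.name: _latent_to_values(u[:, j], s, rng) for j, s in enumerate(specs)}
    df = pd.DataFrame(data)
    df.insert(0, "subject_id", [f"{arm}-{i:06d}" for i in range(n)])
    df["arm_label"] = arm

    start = pd.Timestamp(config.study_entry_window[0])
    end = pd.Timestamp(config.study_entry_window[1])
    window_days = (end - start).days
    offsets = rng.integers(0, window_days + 1, size=n)
    df["first_noac_date"] = start + pd.to_timedelta(offsets, unit="D")
    df["index_date"] = pd.NaT

    if arm == "RWD":
        shape, scale = config.baseline_hazard
        lp = _linear_predictor(df, specs, config.log_hazard_ratios)
        e = rng.exponential(size=n)
        t_days = np.ceil(scale * (e / np.exp(lp)) ** (1.0 / shape)).astype(np.int64)
        t_days = np.maximum(t_days, 1)
        censor = pd.Timestamp(config.censor_date)
        death = df["first_noac_date"] + pd.to_timedelta(t_days, unit="D")
        observed = death <= censor
        df["death_date"] = death.where(observed, pd.NaT)
        follow = (censor - df["first_noac_date"]).dt.days
        df["os_time"] = np.where(observed, t_days, follow).astype(float)
        df["os_event"] = observed.astype(int)
    else:
        df["death_date"] = pd.NaT
        df["os_time"] = np.nan
        df["os_event"] = np.nan

    table = CohortTable(df, arm)
    table.validate(specs)
    return table


def summarize_marginals(table: CohortTable, specs: Sequence[CovariateSpec]) -> pd.DataFrame:
    """Per-covariate baseline summary (the descriptive-table analog).

    Continuous variables report mean/SD/median/quartiles; binary and
    categorical variables report count and proportion of the full n.  Counts
    below 5 get ``mask_lt5 = True`` so renderers can print ``"< 5"`` —
    masking applies to rendered output only, never to this frame.
    """
    if table.n == 0:
        raise ValueError("cannot summarize an empty table")
    rows = []
    n = table.n
    for s in specs:
        col = table.data[s.name]
        if s.kind == "continuous":
            rows.append(
                {
                    "covariate": s.name,
                    "level": "",
                    "kind": s.kind,
                    "mean": col.mean(),
                    "sd": col.std(ddof=1) if n > 1 else 0.0,
                    "median": col.median(),
                    "q25": col.quantile(0.25),
                    "q75": col.quantile(0.75),
                    "count": np.nan,
                    "proportion": np.nan,
                    "mask_lt5": False,
                }
            )
        else:
            levels = (1,) if s.kind == "binary" else s.levels
            for lev in levels:
                c = int((col == lev).sum())
                rows.append(
                    {
                        "covariate": s.name,
                        "level": str(lev),
                        "kind": s.kind,
                        "mean": np.nan,
                        "sd": np.nan,
                        "median": np.nan,
                        "q25": np.nan,
                        "q75": np.nan,
                        "count": c,
                        "proportion": c / n,
                        "mask_lt5": c < _SMALL_CELL,
                    }
                )
    return pd.DataFrame(rows)


def render_marginals(summary: pd.DataFrame, n: int) -> str:
    """Plain-text rendering with small-cell masking applied."""
    lines = [f"N = {n}"]
    for _, r in summary.iterrows():
        if r["kind"] == "continuous":
            lines.append(f"{r['covariate']}: mean {r['mean']:.2f} (SD {r['sd']:.2f})")
        else:
            label = r["covariate"] if r["kind"] == "binary" else f"{r['covariate']}={r['level']}"
            if r["mask_lt5"]:
                lines.append(f"{label}: < 5 (< {_SMALL_CELL / n:.1%})")
            else:
                lines.append(f"{label}: {int(r['count'])} ({r['proportion']:.1%})")
    return "\n".join(lines)
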