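"""Propensity-score balancing of the external control arm against the trial arm.

The propensity score e_i = P(trial arm | covariates) is fit by
maximum-likelihood logistic regression on all baseline confounders
(statsmodels, Newton iterations).  Three balancing strategies are offered:

* **caliper matching** — greedy 1:1 nearest-neighbor matching without
  replacement on the logit of the PS, accepting only pairs within a caliper
  of 0.2 × the pooled SD of the logit PS (the conventional width);
* **matching weights (MW)** — ``w = min(e, 1−e) / P(assigned arm)``, a
  weighted analog of 1:1 matching;
* **overlap weights (OW)** — ``w = 1−e`` for trial subjects and ``e`` for
  controls, which after an ML logistic fit balances every model covariate's
  weighted mean *exactly* (the score equations force it).

Balance is reported as absolute standardized mean differences; when weights
are in play the denominator keeps the *unweighted* arm variances so a
weighting scheme cannot flatter its own diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .schema import CovariateSpec

__all__ = [
    "PropensityFit",
    "MatchSet",
    "WeightSet",
    "SeparationError",
    "design_matrix",
    "fit_propensity",
    "caliper_match",
    "matching_weights",
    "overlap_weights",
    "smd",
    "effective_sample_size",
]

TREATED_ARM = "RCT"


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation in the propensity model."""


@dataclass
class PropensityFit:
    coefficients: pd.Series  # includes "const"
    scores: pd.Series  # e_i, aligned to the stacked table index
    arm: pd.Series  # arm label per subject
    converged: bool
    n_iterations: int
    subject_ids: pd.Series | None = None

    @property
    def logits(self) -> pd.Series:
        return np.log(self.scores / (1.0 - self.scores))


@dataclass
class MatchSet:
    pairs: pd.DataFrame  # columns: rct_id, rwd_id, logit_rct, logit_rwd
    caliper_width_logit: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class WeightSet:
    kind: str  # "MW" | "OW"
    weights: pd.Series
    arm: pd.Series

    def ess(self) -> dict[str, float]:
        return effective_sample_size(self.weights, self.arm)


def design_matrix(df: pd.DataFrame, specs: Sequence[CovariateSpec]) -> pd.DataFrame:
    """Numeric design: continuous and binary as-is, categorical expanded to
    one indicator per non-reference level (reference = first domain level)."""
    cols = {}
    for s in specs:
        if s.kind in ("continuous", "binary"):
            cols[s.name] = df[s.name].astype(float)
        elif s.kind == "categorical":
            for lev in s.levels[1:]:
                cols[f"{s.name}[{lev}]"] = (df[s.name] == lev).astype(float)
        else:
            raise ValueError(f"cannot put kind {s.kind!r} in a design matrix")
    return pd.DataFrame(cols, index=df.index)


def _perfectly_separating_columns(x: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Columns that alone predict the arm exactly (unbounded likelihood)."""
    out = []
    for c in x.columns:
        v = x[c].to_numpy()
        levels = np.unique(v)
        if len(levels) <= 10:
            if all(len(set(y[v == lev])) == 1 for lev in levels) and len(np.unique(y)) == 2:
                out.append(c)
        else:
            if v[y == 1].min() > v[y == 0].max() or v[y == 0].min() > v[y == 1].max():
                out.append(c)
    return out


def _quasi_separating_columns(x: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Discrete columns with an arm-pure level (empty cell): MLE diverges."""
    out = []
    for c in x.columns:
        v = x[c].to_numpy()
        levels = np.unique(v)
        if len(levels) <= 10:
            if any(
                len(y[v == lev]) and len(set(y[v == lev])) == 1 for lev in levels
            ):
                out.append(c)
    return out


def fit_propensity(
    stacked: CohortTable, specs: Sequence[CovariateSpec], treated_arm: str = TREATED_ARM
) -> PropensityFit:
    """ML logistic regression of arm membership on all covariates.

    Raises :class:`SeparationError` (naming the offending covariates) when a
    covariate predicts the arm perfectly.  Quasi-separation — an empty
    arm × level cell of a rare flag, routine with a 250-subject trial arm —
    is tolerated: the fit falls back to a gradient method, a warning names
    the columns and ``converged`` is set False, since the scores remain
    usable for matching and weighting.
    """
    df = stacked.data
    arms = df["arm_label"]
    if arms.nunique() != 2:
        raise ValueError("stacked table must contain exactly two arms")
    y = (arms == treated_arm).to_numpy(int)
    x = design_matrix(df, specs)
    perfect = _perfectly_separating_columns(x, y)
    if perfect:
        raise SeparationError(
            f"perfect separation in propensity model; offending covariates: {perfect}"
        )
    exog = sm.add_constant(x, has_constant="add")

    model = sm.Logit(y, exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-12, disp=0)
            start = res.params.to_numpy()
        except Exception:
            try:
                res = model.fit(method="bfgs", maxiter=2000, gtol=1e-8, disp=0)
                start = res.params.to_numpy()
            except Exception:
                start = np.zeros(exog.shape[1])
    beta, n_iter, score_max = _polish_logit(exog.to_numpy(float), y.astype(float), start)
    converged = bool(np.isfinite(beta).all() and score_max < 1e-8)
    params = pd.Series(beta, index=exog.columns)
    if not converged:
        quasi = _quasi_separating_columns(x, y)
        warnings.warn(
            f"propensity model quasi-separated (max score {score_max:.2g}); "
            f"suspect covariates: {quasi}",
            RuntimeWarning,
            stacklevel=2,
        )
    eta = exog.to_numpy(float) @ beta
    scores = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=df.index, name="propensity")
    scores = scores.clip(1e-12, 1 - 1e-12)
    return PropensityFit(
        coefficients=params,
        scores=scores,
        arm=arms,
        converged=converged,
        n_iterations=n_iter,
        subject_ids=df["subject_id"] if "subject_id" in df.columns else None,
    )


def _polish_logit(X: np.ndarray, y: np.ndarray, beta: np.ndarray, max_iter: int = 300):
    """Damped Newton refinement of a logistic MLE until max |score| < 1e-10.

    Under quasi-separation the likelihood has no finite maximizer, but the
    score still tends to zero as the separated coefficients drift; capped
    pseudo-inverse steps follow that path far enough for downstream
    exact-balance identities to hold numerically.
    """
    beta = np.asarray(beta, dtype=float).copy()
    if not np.isfinite(beta).all():
        beta = np.zeros(X.shape[1])

    def loglike(b):
        eta = X @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglike(beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (y - p)
        if np.abs(g).max() < 1e-10:
            break
        w = np.clip(p * (1.0 - p), 1e-300, None)
        h = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, g, rcond=None)[0]
        norm = np.abs(step).max()
        if norm > 5.0:  # cap drift along separated directions
            step *= 5.0 / norm
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = loglike(cand)
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            t /= 2.0
        else:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    score_max = float(np.abs(X.T @ (y - p)).max())
    return beta, it, score_max


def caliper_match(
    fit: PropensityFit,
    caliper_multiplier: float = 0.2,
    seed: int = 0,
    raw_width: float | None = None,
    treated_arm: str = TREATED_ARM,
) -> MatchSet:
    """Greedy 1:1 nearest-neighbor caliper matching on the logit PS.

    Trial subjects are processed in a seeded random order; each takes the
    nearest still-unmatched control within the caliper (ties broken by
    lowest control row position).  The caliper is
    ``caliper_multiplier × SD(pooled logits)`` unless ``raw_width`` is given.
    """
    logits = fit.logits
    width = float(raw_width) if raw_width is not None else caliper_multiplier * float(
        logits.std(ddof=1)
    )
    t_idx = np.flatnonzero((fit.arm == treated_arm).to_numpy())
    c_idx = np.flatnonzero((fit.arm != treated_arm).to_numpy())
    lv = logits.to_numpy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t_idx))

    available = np.ones(len(c_idx), dtype=bool)
    c_log = lv[c_idx]
    rows = []
    for k in order:
        ti = t_idx[k]
        d = np.abs(c_log - lv[ti])
        d[~available] = np.inf
        j = int(np.argmin(d))  # first occurrence = lowest row position
        if d[j] <= width:
            available[j] = False
            rows.append((ti, c_idx[j], lv[ti], c_log[j]))
    pairs = pd.DataFrame(rows, columns=["rct_pos", "rwd_pos", "logit_rct", "logit_rwd"])
    pairs = pairs.sort_values("rct_pos", kind="mergesort").reset_index(drop=True)
    if fit.subject_ids is not None:
        sid = fit.subject_ids.to_numpy()
        pairs.insert(0, "rct_id", sid[pairs["rct_pos"].to_numpy(int)])
        pairs.insert(1, "rwd_id", sid[pairs["rwd_pos"].to_numpy(int)])
    return MatchSet(pairs=pairs, caliper_width_logit=width)


def matching_weights(fit: PropensityFit, treated_arm: str = TREATED_ARM) -> WeightSet:
    """MW: min(e, 1−e) divided by the probability of the subject's own arm."""
    e = fit.scores
    smaller = np.minimum(e, 1.0 - e)
    treated = fit.arm == treated_arm
    w = np.where(treated, smaller / e, smaller / (1.0 - e))
    return WeightSet("MW", pd.Series(w, index=e.index, name="mw"), fit.arm)


def overlap_weights(fit: PropensityFit, treated_arm: str = TREATED_ARM) -> WeightSet:
    """OW: 1−e for the trial arm, e for the control arm."""
    e = fit.scores
    treated = fit.arm == treated_arm
    w = np.where(treated, 1.0 - e, e)
    return WeightSet("OW", pd.Series(w, index=e.index, name="ow"), fit.arm)


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def smd(
    stacked: CohortTable | pd.DataFrame,
    specs: Sequence[CovariateSpec],
    weights: WeightSet | pd.Series | None = None,
    treated_arm: str = TREATED_ARM,
    cutoffs: tuple[float, float] = (0.1, 0.25),
) -> pd.DataFrame:
    """Absolute standardized mean differences per covariate (indicator per
    non-reference categorical level).

    Continuous: |m₁−m₂| / sqrt((s₁²+s₂²)/2); binary indicators:
    |p₁−p₂| / sqrt((p₁(1−p₁)+p₂(1−p₂))/2).  Means use the supplied weights;
    the denominator always uses unweighted arm variances.  Labels follow the
    conventional success (< 0.1) / moderate (0.1–0.25) / fail cut-offs.
    """
    df = stacked.data if isinstance(stacked, CohortTable) else stacked
    arms = df["arm_label"]
    if arms.nunique() != 2:
        raise ValueError("SMD requires exactly two arms")
    x = design_matrix(df, specs)
    treated = (arms == treated_arm).to_numpy()
    if weights is None:
        w = np.ones(len(df))
    elif isinstance(weights, WeightSet):
        w = weights.weights.to_numpy(float)
    else:
        w = np.asarray(weights, dtype=float)

    lo_cut, hi_cut = cutoffs
    binary_like = {
        s.name for s in specs if s.kind == "binary"
    } | {f"{s.name}[{lev}]" for s in specs if s.kind == "categorical" for lev in s.levels[1:]}
    rows = []
    for c in x.columns:
        v = x[c].to_numpy(float)
        m1 = _wmean(v[treated], w[treated])
        m2 = _wmean(v[~treated], w[~treated])
        if c in binary_like:
            var1, var2 = m1 * (1 - m1), m2 * (1 - m2)
            u1 = v[treated].mean()
            u2 = v[~treated].mean()
            uvar1, uvar2 = u1 * (1 - u1), u2 * (1 - u2)
        else:
            uvar1 = v[treated].var(ddof=1)
            uvar2 = v[~treated].var(ddof=1)
            var1, var2 = uvar1, uvar2
        denom = np.sqrt((uvar1 + uvar2) / 2.0)
        diff = abs(m1 - m2)
        degenerate = denom == 0.0
        val = 0.0 if degenerate and diff < 1e-12 else (np.inf if degenerate else diff / denom)
        label = "success" if val < lo_cut else ("moderate" if val <= hi_cut else "fail")
        rows.append(
            {
                "covariate": c,
                "smd": val,
                "label": label,
                "mean_treated": m1,
                "mean_control": m2,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def effective_sample_size(weights: pd.Series, arm: pd.Series) -> dict[str, float]:
    """Kish ESS = (Σw)² / Σw² within each arm."""
    out = {}
    w = np.asarray(weights, dtype=float)
    a = np.asarray(arm)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    for lab in pd.unique(a):
        wa = w[a == lab]
        s2 = float(np.sum(wa**2))
        if s2 == 0.0:
            raise ValueError(f"all-zero weights in arm {lab!r}")
        out[str(lab)] = float(np.sum(wa) ** 2 / s2)
    return out
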