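"""Propensity model, caliper matching, MW/OW weights and SMD diagnostics."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import toy_table
from ecanon.balance import (
    MatchSet,
    PropensityFit,
    SeparationError,
    caliper_match,
    effective_sample_size,
    fit_propensity,
    matching_weights,
    overlap_weights,
    smd,
)
from ecanon.cohort import CohortTable
from ecanon.schema import CovariateSpec


def _stack_2x2():
    # RCT: 20 with x=1, 10 with x=0; RWD: 10 with x=1, 20 with x=0
    rows = (
        [("RCT", 1)] * 20 + [("RCT", 0)] * 10 + [("RWD", 1)] * 10 + [("RWD", 0)] * 20
    )
    df = pd.DataFrame(rows, columns=["arm_label", "x"])
    df.insert(0, "subject_id", [str(i) for i in range(len(df))])
    return CohortTable(df, "stacked"), [CovariateSpec("x", "binary", 0.5)]


def test_logistic_closed_form_single_binary():
    stacked, specs = _stack_2x2()
    fit = fit_propensity(stacked, specs)
    assert fit.coefficients["x"] == pytest.approx(np.log(4.0), abs=1e-6)
    assert np.allclose(np.log(fit.scores / (1 - fit.scores)), fit.logits, atol=1e-10)


def test_null_model_scores_are_arm_share():
    rng = np.random.default_rng(0)
    n = 4000
    df = pd.DataFrame(
        {
            "subject_id": [str(i) for i in range(n)],
            "arm_label": ["RCT"] * (n // 4) + ["RWD"] * (3 * n // 4),
            "x": rng.normal(size=n),
        }
    )
    fit = fit_propensity(CohortTable(df, "stacked"), [CovariateSpec("x", "continuous", (0, 1, -6, 6))])
    assert abs(fit.coefficients["x"]) < 0.1
    assert np.allclose(fit.scores.mean(), 0.25, atol=0.01)


def test_perfect_separation_raises_named_error():
    df = pd.DataFrame(
        {
            "subject_id": [str(i) for i in range(40)],
            "arm_label": ["RCT"] * 20 + ["RWD"] * 20,
            "x": [1] * 20 + [0] * 20,
        }
    )
    with pytest.raises(SeparationError, match="x"):
        fit_propensity(CohortTable(df, "stacked"), [CovariateSpec("x", "binary", 0.5)])


def _fit_from_logits(rct_logits, rwd_logits):
    logits = np.concatenate([rct_logits, rwd_logits])
    e = 1 / (1 + np.exp(-logits))
    arm = pd.Series(["RCT"] * len(rct_logits) + ["RWD"] * len(rwd_logits))
    return PropensityFit(
        coefficients=pd.Series(dtype=float),
        scores=pd.Series(e),
        arm=arm,
        converged=True,
        n_iterations=1,
    )


def test_caliper_match_prefers_nearest_within_width():
    fit = _fit_from_logits([0.0], [0.05, 1.0])
    m = caliper_match(fit, raw_width=0.1, seed=0)
    assert m.n_matched == 1
    assert m.pairs["logit_rwd"].iloc[0] == pytest.approx(0.05)


def test_caliper_zero_width_no_pairs():
    fit = _fit_from_logits([0.0, 0.5], [0.1, 0.6])
    m = caliper_match(fit, raw_width=0.0, seed=0)
    assert m.n_matched == 0


def test_identical_logits_all_matched():
    fit = _fit_from_logits([0.3] * 4, [0.3] * 10)
    m = caliper_match(fit, raw_width=0.0, seed=1)
    assert m.n_matched == 4


def degenerate_instance(rct_logits, rwd_logits, width, tol=1e-9):
    """True when a distance tie or caliper-boundary case could make the
    outcome depend on floating-point representation."""
    d = np.abs(np.asarray(rct_logits)[:, None] - np.asarray(rwd_logits)[None, :])
    if np.any(np.abs(d - width) < tol):
        return True
    ds = np.sort(d.ravel())
    return bool(np.any(np.diff(ds) < tol))


def greedy_all_orders(rct_logits, rwd_logits, width):
    """Brute-force oracle: the greedy rule under every processing order."""
    outcomes = set()
    for order in itertools.permutations(range(len(rct_logits))):
        available = np.ones(len(rwd_logits), dtype=bool)
        pairs = []
        for ti in order:
            d = np.abs(np.asarray(rwd_logits) - rct_logits[ti]).astype(float)
            d[~available] = np.inf
            j = int(np.argmin(d))
            if d[j] <= width:
                available[j] = False
                pairs.append((ti, j))
        outcomes.add(frozenset(pairs))
    return outcomes


@pytest.mark.parametrize("n_instances", [500])
def test_matcher_agrees_with_brute_force_on_order_invariant_instances(n_instances):
    """Wherever the greedy rule is order-invariant (unique outcome over all
    n! processing orders), the seeded implementation must reproduce it."""
    rng = np.random.default_rng(2024)
    checked = 0
    attempts = 0
    while checked < n_instances and attempts < 20 * n_instances:
        attempts += 1
        n_t = int(rng.integers(1, 7))
        n_c = int(rng.integers(1, 7))
        t = np.round(rng.normal(size=n_t), 3)
        c = np.round(rng.normal(size=n_c), 3)
        width = float(rng.uniform(0.1, 1.5))
        if degenerate_instance(t, c, width):
            continue
        outcomes = greedy_all_orders(t, c, width)
        if len(outcomes) != 1:
            continue
        expected = next(iter(outcomes))
        fit = _fit_from_logits(t, c)
        m = caliper_match(fit, raw_width=width, seed=int(rng.integers(1_000_000)))
        got = frozenset(
            (int(r.rct_pos), int(r.rwd_pos) - n_t) for r in m.pairs.itertuples()
        )
        assert got == expected
        checked += 1
    assert checked == n_instances


def test_matching_weight_formulas():
    fit = _fit_from_logits([np.log(4)], [np.log(4), 0.0])  # e = 0.8, 0.8, 0.5
    mw = matching_weights(fit)
    assert mw.weights.to_numpy() == pytest.approx([0.25, 1.0, 1.0])
    assert ((mw.weights >= 0) & (mw.weights <= 1)).all()
    ow = overlap_weights(fit)
    assert ow.weights.to_numpy() == pytest.approx([0.2, 0.8, 0.5])


def test_overlap_exact_balance_on_full_stack(full_stack, full_fit, full_config):
    """Score equations of the ML logistic fit force exact OW mean balance."""
    from ecanon.balance import design_matrix

    specs = full_config.covariates["RWD"]
    ow = overlap_weights(full_fit)
    x = design_matrix(full_stack.data, specs)
    treated = (full_stack.data["arm_label"] == "RCT").to_numpy()
    w = ow.weights.to_numpy()
    for c in x.columns:
        v = x[c].to_numpy()
        m1 = np.sum(w[treated] * v[treated]) / np.sum(w[treated])
        m0 = np.sum(w[~treated] * v[~treated]) / np.sum(w[~treated])
        assert abs(m1 - m0) < 1e-8, c


def test_ess_constant_weights_and_formula():
    arm = pd.Series(["RWD"] * 10)
    assert effective_sample_size(pd.Series(np.ones(10)), arm)["RWD"] == pytest.approx(10.0)
    ess = effective_sample_size(pd.Series([1.0, 1.0, 0.5]), pd.Series(["RWD"] * 3))
    assert ess["RWD"] == pytest.approx(6.25 / 2.25)
    one = effective_sample_size(pd.Series([0.0, 0.7]), pd.Series(["RWD"] * 2))
    assert one["RWD"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        effective_sample_size(pd.Series([0.0, 0.0]), pd.Series(["RWD"] * 2))


def test_smd_copd_printed_value():
    """152/3,327 vs 181/3,327 positives gives SMD 0.04."""
    n = 3327
    rows = [("RCT", 1)] * 152 + [("RCT", 0)] * (n - 152) + [("RWD", 1)] * 181 + [
        ("RWD", 0)
    ] * (n - 181)
    df = pd.DataFrame(rows, columns=["arm_label", "copd"])
    df.insert(0, "subject_id", [str(i) for i in range(len(df))])
    out = smd(CohortTable(df, "stacked"), [CovariateSpec("copd", "binary", 0.05)])
    assert out["smd"].iloc[0] == pytest.approx(0.040, abs=5e-4)
    assert out["label"].iloc[0] == "success"


def test_smd_age_row_closed_form():
    """Means 75.92 vs 75.84 with SDs 9.19 / 10.22 give SMD ≈ 0.0082."""
    m1, m2, s1, s2 = 75.92, 75.84, 9.19, 10.22
    val = abs(m1 - m2) / np.sqrt((s1**2 + s2**2) / 2)
    assert val == pytest.approx(0.0082, abs=2e-4)
    rng = np.random.default_rng(0)
    n = 200_000
    df = pd.DataFrame(
        {
            "subject_id": [str(i) for i in range(2 * n)],
            "arm_label": ["RCT"] * n + ["RWD"] * n,
            "age": np.concatenate([rng.normal(m1, s1, n), rng.normal(m2, s2, n)]),
        }
    )
    out = smd(CohortTable(df, "stacked"), [CovariateSpec("age", "continuous", (75, 10, 0, 150))])
    assert out["smd"].iloc[0] == pytest.approx(val, abs=0.005)


def test_identical_arms_zero_smd():
    base = pd.DataFrame({"x": [0, 1, 1, 0, 1], "age": [50.0, 60, 70, 55, 65]})
    df = pd.concat(
        [base.assign(arm_label="RCT"), base.assign(arm_label="RWD")], ignore_index=True
    )
    df.insert(0, "subject_id", [str(i) for i in range(len(df))])
    specs = [
        CovariateSpec("x", "binary", 0.5),
        CovariateSpec("age", "continuous", (60, 8, 40, 90)),
    ]
    out = smd(CohortTable(df, "stacked"), specs)
    assert (out["smd"] == 0).all()


def test_degenerate_zero_variance_flagged():
    df = pd.DataFrame(
        {
            "subject_id": [str(i) for i in range(4)],
            "arm_label": ["RCT", "RCT", "RWD", "RWD"],
            "x": [1, 1, 1, 1],
        }
    )
    out = smd(CohortTable(df, "stacked"), [CovariateSpec("x", "binary", 1.0)])
    assert out["smd"].iloc[0] == 0.0 and out["degenerate"].iloc[0]


def test_pre_matching_imbalance_matches_discrepant_covariates(full_stack, full_config):
    """The covariates most discrepant between arms (BMI ≥ 30, chronic heart
    failure) show large pre-balancing SMDs; weighting repairs them."""
    specs = full_config.covariates["RWD"]
    pre = smd(full_stack, specs).set_index("covariate")["smd"]
    assert pre["bmi_ge30"] > 0.25
    assert pre["chronic_heart_failure"] > 0.25


def test_mw_and_ow_balance_full_stack(full_stack, full_fit, full_config):
    specs = full_config.covariates["RWD"]
    for ws in (matching_weights(full_fit), overlap_weights(full_fit)):
        table = smd(full_stack, specs, weights=ws)
        assert (table["smd"] < 0.1).all(), ws.kind
        ess = ws.ess()
        assert ess["RCT"] <= 250 and ess["RWD"] <= 3327
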