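"""(k, ε)-anonymizer: mechanisms, k-repair, composition, risk bound."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import toy_table
from ecanon.anonymize import (
    PrivacyConfig,
    anonymize,
    categorical_kernel,
    clean_out_of_range,
    exponential_mechanism_categorical,
    laplace_mechanism,
    partition_classes,
    privacy_risk_bound,
    repair_k_violations,
    shuffle_and_reid,
)
from ecanon.schema import CovariateSpec

LN32 = math.log(32)


def grp_specs():
    return [CovariateSpec("grp", "categorical", {"A": 0.5, "B": 0.3, "C": 0.2})]


# ---------------------------------------------------------------- partition
def test_partition_sizes():
    t = toy_table({"grp": ["A"] * 5 + ["B"]})
    idx = partition_classes(t, ("grp",), grp_specs())
    assert sorted(len(v) for v in idx.classes.values()) == [1, 5]


def test_partition_single_class_and_empty():
    t = toy_table({"grp": ["A"] * 7})
    idx = partition_classes(t, ("grp",), grp_specs())
    assert idx.sizes == {("A",): 7}
    empty = toy_table({"grp": []})
    assert partition_classes(empty, ("grp",), grp_specs()).classes == {}


def test_partition_bands_continuous_quasi():
    specs = [CovariateSpec("age", "continuous", (75, 9, 45, 105), quasi_identifier=True)]
    t = toy_table({"age": [47.0, 49.0, 52.0]})
    idx = partition_classes(t, ("age",), specs, band_width=5.0)
    assert sorted(len(v) for v in idx.classes.values()) == [1, 2]


# ---------------------------------------------------------------- laplace
def test_laplace_variance_and_mean():
    rng = np.random.default_rng(0)
    draws = laplace_mechanism(np.zeros(100_000), 1.0, LN32, rng)
    b = 1.0 / LN32
    assert abs(draws.var() - 2 * b * b) / (2 * b * b) < 0.05
    se = np.sqrt(2 * b * b / 100_000)
    assert abs(draws.mean()) < 4 * se


def test_laplace_no_noise_limit():
    rng = np.random.default_rng(0)
    out = laplace_mechanism(np.full(1000, 7.0), 1.0, 1e9, rng)
    assert np.abs(out - 7.0).max() < 1e-6


def test_laplace_ks_calibration():
    rng = np.random.default_rng(123)
    draws = laplace_mechanism(np.zeros(100_000), 2.0, LN32, rng)
    stat, p = stats.kstest(draws, stats.laplace(scale=2.0 / LN32).cdf)
    assert p > 0.01


def test_laplace_invalid_params():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        laplace_mechanism(0.0, 0.0, 1.0, rng)
    with pytest.raises(ValueError):
        laplace_mechanism(0.0, 1.0, 0.0, rng)


# ---------------------------------------------------------------- exponential
def test_keep_probability_binary():
    rng = np.random.default_rng(1)
    vals = np.zeros(100_000, dtype=int)
    out = exponential_mechanism_categorical(vals, [0, 1], LN32, rng)
    q = 32 / 33
    se = np.sqrt(q * (1 - q) / 100_000)
    assert abs((out == 0).mean() - q) < 4 * se


def test_epsilon_zero_uniform():
    rng = np.random.default_rng(2)
    out = exponential_mechanism_categorical(np.zeros(60_000, int), [0, 1, 2], 0.0, rng)
    freqs = np.bincount(out.astype(int), minlength=3) / 60_000
    assert np.abs(freqs - 1 / 3).max() < 4 * np.sqrt((1 / 3) * (2 / 3) / 60_000)


def test_transition_frequencies_match_kernel():
    rng = np.random.default_rng(3)
    domain = ["a", "b", "c", "d"]
    kern = categorical_kernel(4, 1.5)
    n = 100_000
    out = exponential_mechanism_categorical(np.array(["b"] * n, dtype=object), domain, 1.5, rng)
    for j, lev in enumerate(domain):
        p = kern[1, j]
        se = np.sqrt(p * (1 - p) / n)
        assert abs((out == lev).mean() - p) < 4 * se


@pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
@pytest.mark.parametrize("eps", [0.01, LN32, 7.0])
def test_dp_ratio_bound(m, eps):
    kern = categorical_kernel(m, eps)
    ratio = (kern[:, None, :] / kern[None, :, :]).max()
    # bound is tight (= e^ε); compare on the log scale to absorb fp roundoff
    assert math.log(ratio) <= eps + 1e-12


def test_value_outside_domain_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="domain"):
        exponential_mechanism_categorical("z", ["a", "b"], 1.0, rng)


# ---------------------------------------------------------------- repair
def cfg_grp(**kw):
    kw.setdefault("quasi_identifiers", ("grp",))
    return PrivacyConfig(**kw)


def test_repair_noop_when_compliant():
    t = toy_table({"grp": ["A"] * 5 + ["B"] * 5})
    out, rounds = repair_k_violations(t.data, grp_specs(), cfg_grp(), np.random.default_rng(0))
    assert rounds == 0
    pd.testing.assert_frame_equal(out, t.data)


@pytest.mark.parametrize("seed", range(10))
def test_repair_small_case_merges_singleton(seed):
    t = toy_table({"grp": ["A"] * 5 + ["B"]})
    out, _ = repair_k_violations(t.data, grp_specs(), cfg_grp(), np.random.default_rng(seed))
    sizes = out["grp"].value_counts()
    assert (sizes >= 5).all()
    assert sizes.sum() == 6


def test_repair_k_larger_than_n_errors():
    t = toy_table({"grp": ["A", "B"]})
    with pytest.raises(ValueError, match="cannot"):
        repair_k_violations(t.data, grp_specs(), cfg_grp(k=5), np.random.default_rng(0))


def test_repair_age_bands():
    specs = [
        CovariateSpec(
            "age", "continuous", (75, 9, 45, 105), quasi_identifier=True, integer_valued=True
        )
    ]
    ages = [71.0, 72, 73, 74, 75, 103.0]
    t = toy_table({"age": ages})
    cfg = PrivacyConfig(quasi_identifiers=("age",), age_band_width=10.0)
    out, _ = repair_k_violations(t.data, specs, cfg, np.random.default_rng(4))
    idx = partition_classes(out, ("age",), specs, 10.0)
    assert idx.min_size >= 5
    assert out["age"].between(45, 105).all()


# ---------------------------------------------------------------- clean / shuffle
def test_clean_clamps_and_rounds():
    specs = [
        CovariateSpec(
            "age", "continuous", (75, 9, 45, 105), integer_valued=True, domain=(45.0, 105.0)
        )
    ]
    df = pd.DataFrame({"age": [107.3, 63.4, 70.0]})
    out = clean_out_of_range(df, specs)
    assert list(out["age"]) == [105.0, 63.0, 70.0]


def test_shuffle_preserves_row_multiset_and_renames_ids():
    t = toy_table({"x": list(range(20))})
    out = shuffle_and_reid(t.data, np.random.default_rng(0))
    assert sorted(out["x"]) == list(range(20))
    assert not set(out["subject_id"]) & set(t.data["subject_id"])
    out1 = shuffle_and_reid(t.data.iloc[:1], np.random.default_rng(1))
    assert len(out1) == 1 and out1["subject_id"].iloc[0] != t.data["subject_id"].iloc[0]


# ---------------------------------------------------------------- composition
def _pseudo(n=800, seed=5):
    from ecanon.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(n_rwd=n, seed=seed)
    return generate_cohort(cfg, "RWD"), cfg.covariates["RWD"]


def test_anonymize_preserves_record_count_and_k():
    table, specs = _pseudo()
    cfg = PrivacyConfig(seed=9)
    out = anonymize(table, cfg, specs)
    assert out.n == table.n
    idx = partition_classes(out.table, cfg.quasi_identifiers, specs, cfg.age_band_width)
    assert idx.min_size >= cfg.k
    assert set(out.data.columns) == set(table.data.columns)


def test_anonymize_deterministic():
    table, specs = _pseudo(n=300)
    cfg = PrivacyConfig(seed=4)
    a = anonymize(table, cfg, specs)
    b = anonymize(table, cfg, specs)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_no_noise_limit_identity_up_to_order():
    """ε → ∞ on an already k-anonymous table: values survive, only order/ids change."""
    table, specs = _pseudo(n=1000, seed=6)
    cfg = PrivacyConfig(epsilon=1e9, seed=2, age_band_width=1000.0, anonymize_outcomes=False)
    out = anonymize(table, cfg, specs)
    cols = [s.name for s in specs] + ["os_time", "os_event"]
    a = table.data[cols].sort_values(cols).reset_index(drop=True)
    b = out.data[cols].sort_values(cols).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b, check_dtype=False)


def test_randomized_response_shifts_prevalence_as_expected():
    """Binary marginal after anonymization follows p·q + (1−p)(1−q), q = 32/33."""
    from ecanon.synth import CohortConfig, generate_cohort

    n = 50_000
    cfg = CohortConfig(n_rwd=n, seed=8)
    table = generate_cohort(cfg, "RWD")
    specs = cfg.covariates["RWD"]
    out = anonymize(table, PrivacyConfig(seed=1), specs)
    q = 32 / 33
    p = 0.046
    expected = p * q + (1 - p) * (1 - q)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(out.data["copd"].mean() - expected) < 4 * se


def test_outcome_anonymization_switch():
    table, specs = _pseudo(n=500, seed=7)
    off = anonymize(table, PrivacyConfig(seed=3, anonymize_outcomes=False), specs)
    merged_off = sorted(off.data["os_time"])
    assert merged_off == sorted(table.data["os_time"])
    on = anonymize(table, PrivacyConfig(seed=3, anonymize_outcomes=True), specs)
    assert sorted(on.data["os_time"]) != sorted(table.data["os_time"])


# ---------------------------------------------------------------- risk bound
def test_privacy_risk_bound_printed_values():
    assert round(100 * privacy_risk_bound(LN32, 8255), 2) == 0.39
    assert round(100 * privacy_risk_bound(0.01, 8255), 3) == 0.012


def test_privacy_risk_bound_monotonicity_and_limit():
    assert privacy_risk_bound(1.0, 8255) < privacy_risk_bound(2.0, 8255)
    assert privacy_risk_bound(1.0, 10_000) < privacy_risk_bound(1.0, 1000)
    assert privacy_risk_bound(200.0, 8255) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        privacy_risk_bound(0.0, 8255)
    with pytest.raises(ValueError):
        privacy_risk_bound(1.0, 1)
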