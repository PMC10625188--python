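"""(k, ε)-anonymization of a subject-level cohort table.

The privacy model combines two guarantees:

* **k-anonymity** on the quasi-identifiers (by default age, banded for class
  formation only, and sex): every combination of quasi-identifier values is
  shared by at least ``k`` released records (default k = 5).
* **per-variable ε-differential privacy** on the released values (default
  ε = ln 32 ≈ 3.466): the Laplace mechanism for numeric variables and a
  randomized-response form of the exponential mechanism for categorical
  ones.  The budget is applied per attribute — a deliberately weaker notion
  than whole-record ε-DP, stated loudly here because a reader may otherwise
  assume record-level composition.

The released table additionally has direct identifiers suppressed, dates
blanked, record order shuffled and fresh random record identifiers, and it
always contains exactly as many records as the input.

Mechanism details
-----------------
The categorical mechanism is the exponential mechanism with identity
utility u(x, r) = 1{r = x} and Δu = 1, which reduces to randomized
response: keep the original category with probability
``q = e^ε / (e^ε + m − 1)`` and otherwise draw uniformly from the other
``m − 1`` categories.  The worst-case output-probability ratio is then
exactly ``q (m − 1) / (1 − q) = e^ε``, the ε-DP bound.

Records in equivalence classes smaller than ``k`` have their
quasi-identifier values re-drawn through the same mechanism, for up to
``max_repair_rounds`` passes; any residual violator is deterministically
folded into the largest compliant class.  Because noising age and sex can
re-break classes, a final repair pass runs after cleaning, so the released
table always satisfies the k-criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, DATE_COLS
from .schema import CovariateSpec

__all__ = [
    "PrivacyConfig",
    "EquivalenceClassIndex",
    "AnonymizedTable",
    "partition_classes",
    "laplace_mechanism",
    "exponential_mechanism_categorical",
    "categorical_kernel",
    "repair_k_violations",
    "clean_out_of_range",
    "shuffle_and_reid",
    "anonymize",
    "privacy_risk_bound",
]


@dataclass
class PrivacyConfig:
    """Knobs of the anonymization stage.

    ``categorical_noise_scope`` selects whether the exponential mechanism
    runs on every categorical value (``"all"``, the default) or only on the
    records that failed the k-criterion (``"k_failing"``).
    ``sensitivities`` overrides the per-variable Laplace Δ; a variable
    without an entry falls back to its schema sensitivity (domain width in
    the worst case).
    """

    k: int = 5
    epsilon: float = math.log(32)
    quasi_identifiers: tuple[str, ...] = ("age", "sex_male")
    sensitivities: Mapping[str, float] = field(default_factory=dict)
    age_band_width: float = 10.0
    max_repair_rounds: int = 5
    anonymize_outcomes: bool = True
    outcome_time_sensitivity: float = 30.0
    categorical_noise_scope: str = "all"
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not self.quasi_identifiers:
            raise ValueError("quasi-identifier set must be non-empty")
        if self.categorical_noise_scope not in ("all", "k_failing"):
            raise ValueError("categorical_noise_scope must be 'all' or 'k_failing'")
        if not self.age_band_width > 0:
            raise ValueError("age_band_width must be > 0")

    def sensitivity_for(self, spec: CovariateSpec) -> float:
        if spec.name in self.sensitivities:
            return float(self.sensitivities[spec.name])
        return spec.laplace_sensitivity


@dataclass
class EquivalenceClassIndex:
    """Partition of record positions by quasi-identifier value tuple."""

    classes: dict[tuple, np.ndarray]

    @property
    def sizes(self) -> dict[tuple, int]:
        return {t: len(ix) for t, ix in self.classes.items()}

    def violators(self, k: int) -> np.ndarray:
        bad = [ix for ix in self.classes.values() if len(ix) < k]
        return np.concatenate(bad) if bad else np.array([], dtype=np.int64)

    @property
    def min_size(self) -> int:
        return min((len(ix) for ix in self.classes.values()), default=0)


@dataclass
class AnonymizedTable:
    """A released cohort table plus transformation provenance."""

    table: CohortTable
    provenance: dict
    repair_rounds_used: int

    @property
    def data(self) -> pd.DataFrame:
        return self.table.data

    @property
    def n(self) -> int:
        return self.table.n


def _band(values: np.ndarray, width: float) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=float) / width).astype(np.int64)


def _quasi_tuples(df: pd.DataFrame, specs_by_name, quasi: Sequence[str], band_width: float):
    cols = []
    for name in quasi:
        spec = specs_by_name[name]
        if spec.kind == "continuous":
            cols.append(_band(df[name].to_numpy(), band_width))
        elif spec.kind in ("binary", "categorical"):
            cols.append(df[name].to_numpy())
        else:
            raise ValueError(f"quasi-identifier {name!r} has unusable kind {spec.kind!r}")
    return list(zip(*cols)) if cols else []


def partition_classes(
    table: CohortTable | pd.DataFrame,
    quasi_identifiers: Sequence[str],
    specs: Sequence[CovariateSpec],
    band_width: float = 10.0,
) -> EquivalenceClassIndex:
    """Exact partition of records by quasi-identifier value tuple.

    Continuous quasi-identifiers are banded (``floor(value / width)``) for
    class formation only; released values are untouched here.
    """
    df = table.data if isinstance(table, CohortTable) else table
    by_name = {s.name: s for s in specs}
    for name in quasi_identifiers:
        if name not in by_name:
            raise ValueError(f"quasi-identifier {name!r} missing from schema")
    tuples = _quasi_tuples(df, by_name, quasi_identifiers, band_width)
    classes: dict[tuple, list[int]] = {}
    for pos, t in enumerate(tuples):
        classes.setdefault(t, []).append(pos)
    return EquivalenceClassIndex({t: np.asarray(ix, dtype=np.int64) for t, ix in classes.items()})


def laplace_mechanism(value, sensitivity: float, epsilon: float, rng: np.random.Generator):
    """Add Laplace(0, Δ/ε) noise; scalar or array in, same shape out."""
    if not sensitivity > 0:
        raise ValueError("sensitivity must be > 0")
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    arr = np.asarray(value, dtype=float)
    noise = rng.laplace(0.0, sensitivity / epsilon, size=arr.shape)
    out = arr + noise
    return float(out) if np.isscalar(value) or arr.shape == () else out


def exponential_mechanism_categorical(
    value, domain: Sequence, epsilon: float, rng: np.random.Generator
):
    """Randomized-response exponential mechanism over ``domain``.

    Keeps the input category with probability ``e^ε/(e^ε + m − 1)``;
    otherwise returns a uniform draw from the other categories.  ``ε = 0``
    degenerates to the uniform kernel.  Accepts a scalar or an array of
    values; every value must lie in the domain.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    domain = list(domain)
    m = len(domain)
    if m < 2:
        raise ValueError("domain must contain at least 2 categories")
    scalar = np.isscalar(value) or isinstance(value, str)
    values = np.asarray([value] if scalar else value, dtype=object)
    codes = np.array([domain.index(v) if v in domain else -1 for v in values])
    if (codes < 0).any():
        bad = values[codes < 0][0]
        raise ValueError(f"value {bad!r} outside domain {domain!r}")

    # numerically stable keep-probability: 1 / (1 + (m-1) e^{-eps})
    q = 1.0 / (1.0 + (m - 1) * math.exp(-epsilon))
    keep = rng.random(len(values)) < q
    # draw an index among the m-1 "other" categories, skipping the original
    alt = rng.integers(0, m - 1, size=len(values))
    alt = np.where(alt >= codes, alt + 1, alt)
    out_codes = np.where(keep, codes, alt)
    out = np.asarray(domain, dtype=object)[out_codes]
    return out[0] if scalar else out


def categorical_kernel(m: int, epsilon: float) -> np.ndarray:
    """Transition matrix P(output | input) of the categorical mechanism:
    keep-probability on the diagonal, uniform leakage off it.  This is the
    exact kernel the sampler in :func:`exponential_mechanism_categorical`
    realizes; its worst-case probability ratio equals e^ε."""
    if m < 2:
        raise ValueError("m must be >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    q = 1.0 / (1.0 + (m - 1) * math.exp(-epsilon))
    k = np.full((m, m), (1.0 - q) / (m - 1))
    np.fill_diagonal(k, q)
    return k


def _age_bands(spec: CovariateSpec, width: float) -> list[int]:
    lo, hi = spec.bounds
    return list(range(int(math.floor(lo / width)), int(math.floor(hi / width)) + 1))


def _draw_in_band(band: int, width: float, spec: CovariateSpec, rng) -> float:
    lo, hi = spec.bounds
    a, b = max(band * width, lo), min((band + 1) * width - 1e-9, hi)
    x = rng.uniform(a, b)
    return float(np.rint(x)) if spec.integer_valued else float(x)


def repair_k_violations(
    df: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    config: PrivacyConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """Re-draw quasi-identifier values of k-failing records until every
    equivalence class reaches size k.

    Each round re-draws every quasi value of every violator through the
    exponential mechanism (continuous quasi-identifiers are re-drawn at the
    band level, then given a uniform value inside the new band).  After
    ``max_repair_rounds`` rounds, residual violators are deterministically
    reassigned the quasi tuple of the largest compliant class.  Raises if
    the table is smaller than k.
    """
    if len(df) < config.k:
        raise ValueError(f"table of {len(df)} records cannot be {config.k}-anonymized")
    df = df.copy()
    by_name = {s.name: s for s in specs}
    quasi = config.quasi_identifiers
    rounds = 0
    for rounds in range(config.max_repair_rounds + 1):
        index = partition_classes(df, quasi, specs, config.age_band_width)
        bad = index.violators(config.k)
        if bad.size == 0:
            return df, rounds
        if rounds == config.max_repair_rounds:
            break
        for name in quasi:
            spec = by_name[name]
            if spec.kind == "continuous":
                bands = _age_bands(spec, config.age_band_width)
                cur = _band(df[name].to_numpy()[bad], config.age_band_width)
                new = exponential_mechanism_categorical(cur.tolist(), bands, config.epsilon, rng)
                vals = [_draw_in_band(int(b), config.age_band_width, spec, rng) for b in new]
                df.loc[df.index[bad], name] = vals
            else:
                new = exponential_mechanism_categorical(
                    df[name].to_numpy()[bad], list(spec.levels), config.epsilon, rng
                )
                df.loc[df.index[bad], name] = new.astype(df[name].dtype, copy=False)

    # deterministic fallback: fold residual violators into the largest
    # compliant class (or the modal tuple when no class is compliant)
    index = partition_classes(df, quasi, specs, config.age_band_width)
    bad = index.violators(config.k)
    compliant = {t: ix for t, ix in index.classes.items() if len(ix) >= config.k}
    pool = compliant if compliant else index.classes
    target = max(sorted(pool), key=lambda t: len(pool[t]))
    if not compliant:
        bad = np.arange(len(df))  # everyone joins the modal tuple
    for name, val in zip(quasi, target):
        spec = by_name[name]
        if spec.kind == "continuous":
            mid = (val + 0.5) * config.age_band_width
            lo, hi = spec.bounds
            mid = min(max(mid, lo), hi)
            df.loc[df.index[bad], name] = float(np.rint(mid)) if spec.integer_valued else mid
        else:
            df.loc[df.index[bad], name] = val
    return df, config.max_repair_rounds


def clean_out_of_range(
    df: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    outcome_time_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Clamp noised continuous values into their schema domains and round
    integer-valued variables; optionally clamp/round the survival time."""
    df = df.copy()
    for s in specs:
        if s.kind != "continuous":
            continue
        lo, hi = s.bounds
        col = df[s.name].astype(float).clip(lo, hi)
        df[s.name] = np.rint(col) if s.integer_valued else col
    if outcome_time_bounds is not None and "os_time" in df.columns:
        lo, hi = outcome_time_bounds
        df["os_time"] = np.rint(df["os_time"].astype(float).clip(lo, hi))
    return df


def shuffle_and_reid(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform random row permutation; subject ids replaced by fresh random
    record identifiers with no retained mapping."""
    perm = rng.permutation(len(df))
    out = df.iloc[perm].reset_index(drop=True)
    ids = rng.choice(10**9, size=len(df), replace=False)
    out["subject_id"] = [f"A{int(i):09d}" for i in ids]
    return out


def anonymize(
    table: CohortTable, config: PrivacyConfig, specs: Sequence[CovariateSpec]
) -> AnonymizedTable:
    """Full anonymization pipeline.

    Order of operations: suppress identifiers and dates → partition classes
    → repair k-violations → exponential mechanism on categorical variables →
    Laplace mechanism on continuous variables (and, when configured, on the
    survival outcome) → clean out-of-range values → final k-repair →
    shuffle and re-identify.  Record count is always preserved.
    """
    rng = np.random.default_rng(config.seed)
    df = table.data.copy()
    n_in = len(df)
    provenance: dict[str, object] = {"n_input": n_in, "epsilon": config.epsilon, "k": config.k}

    # direct identifiers and exact dates are suppressed outright
    for c in DATE_COLS:
        if c in df.columns:
            df[c] = pd.NaT
    provenance["suppressed"] = ["subject_id", *[c for c in DATE_COLS if c in df.columns]]

    initial = partition_classes(df, config.quasi_identifiers, specs, config.age_band_width)
    failing_mask = np.zeros(n_in, dtype=bool)
    failing_mask[initial.violators(config.k)] = True

    df, rounds = repair_k_violations(df, specs, config, rng)

    cat_specs = [s for s in specs if s.kind in ("binary", "categorical")]
    for s in cat_specs:
        if config.categorical_noise_scope == "all":
            df[s.name] = exponential_mechanism_categorical(
                df[s.name].to_numpy(), list(s.levels), config.epsilon, rng
            ).astype(df[s.name].dtype, copy=False)
        elif failing_mask.any():
            sel = np.flatnonzero(failing_mask)
            df.loc[df.index[sel], s.name] = exponential_mechanism_categorical(
                df[s.name].to_numpy()[sel], list(s.levels), config.epsilon, rng
            ).astype(df[s.name].dtype, copy=False)
    provenance["categorical_mechanism"] = {
        s.name: f"exponential(eps={config.epsilon:.4g}, scope={config.categorical_noise_scope})"
        for s in cat_specs
    }

    cont_specs = [s for s in specs if s.kind == "continuous"]
    for s in cont_specs:
        df[s.name] = laplace_mechanism(
            df[s.name].to_numpy(), config.sensitivity_for(s), config.epsilon, rng
        )
    provenance["laplace_mechanism"] = {
        s.name: f"laplace(delta={config.sensitivity_for(s):.4g}, eps={config.epsilon:.4g})"
        for s in cont_specs
    }

    outcome_bounds = None
    has_outcome = "os_time" in df.columns and df["os_time"].notna().any()
    if config.anonymize_outcomes and has_outcome:
        t_max = float(df["os_time"].max())
        df["os_time"] = laplace_mechanism(
            df["os_time"].to_numpy(), config.outcome_time_sensitivity, config.epsilon, rng
        )
        df["os_event"] = exponential_mechanism_categorical(
            df["os_event"].astype(int).to_numpy(), [0, 1], config.epsilon, rng
        ).astype(int)
        outcome_bounds = (0.0, t_max)
        provenance["outcome_mechanism"] = (
            f"laplace(delta={config.outcome_time_sensitivity:.4g}) on os_time, "
            "randomized response on os_event"
        )
    else:
        provenance["outcome_mechanism"] = "none"

    df = clean_out_of_range(df, specs, outcome_bounds)

    # noising quasi variables can re-break k; restore it before release
    df, rounds2 = repair_k_violations(df, specs, config, rng)
    provenance["final_repair_rounds"] = rounds2

    df = shuffle_and_reid(df, rng)

    released = CohortTable(df, table.arm)
    if released.n != n_in:
        raise AssertionError("anonymization must preserve the record count")
    check = partition_classes(released, config.quasi_identifiers, specs, config.age_band_width)
    if check.min_size < config.k:
        raise AssertionError("released table violates k-anonymity")
    if set(released.data["subject_id"]) & set(table.data["subject_id"]):
        raise AssertionError("original subject ids leaked into the release")
    return AnonymizedTable(released, provenance, max(rounds, rounds2))


def privacy_risk_bound(epsilon: float, n: int) -> float:
    """Maximum membership-disclosure probability ρ = 1 / (1 + (n − 1) e^(−ε)).

    A uniform-prior adversary observing an ε-DP release of a cohort of size
    ``n`` can identify a member with probability at most ρ; the bound is
    increasing in ε and decreasing in n.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    return 1.0 / (1.0 + (n - 1) * math.exp(-epsilon))
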