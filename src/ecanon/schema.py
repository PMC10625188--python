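"""Covariate schema for the atrial-fibrillation cohorts.

The analysis rests on 36 baseline confounders measured in an elderly
atrial-fibrillation population starting (or already using) a non-vitamin-K
oral anticoagulant (NOAC): age, sex, 33 binary comorbidity / co-medication
flags, and a three-category time-since-AF-diagnosis variable.  Each covariate
is described by a :class:`CovariateSpec`, which carries everything the
synthetic generator, the anonymizer and the balance diagnostics need to know
about it: its type, its target marginal in each arm, whether it acts as a
quasi-identifier, its Laplace sensitivity and its legal domain.

Two default marginal columns are provided: a real-world-data-like arm
(n = 3,327) and a trial-control-like arm (n = 250).  Cells reported only as
"< 5" in the source summary tables are encoded with small synthetic counts
(3 of 3,327 and 2 of 250); the exact values are immaterial for every test the
package runs, but a concrete number is required to generate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "CovariateSpec",
    "default_covariates",
    "BINARY_FLAGS",
    "RWD_N",
    "RCT_N",
]

RWD_N = 3327
RCT_N = 250

VALID_KINDS = ("binary", "categorical", "continuous", "date")


@dataclass(frozen=True)
class CovariateSpec:
    """Schema entry for one baseline covariate.

    Parameters
    ----------
    name
        Column label.
    kind
        One of ``binary``, ``categorical``, ``continuous``, ``date``.
    target_marginal
        Prevalence in [0, 1] for binary; a ``{category: probability}``
        mapping for categorical; ``(mean, sd, min, max)`` for continuous.
    quasi_identifier
        Whether the variable participates in k-anonymity equivalence
        classes.
    sensitivity
        Laplace sensitivity Δ (continuous only).  ``None`` falls back to
        the domain width (the worst case).
    domain
        Allowed categories, or ``(min, max)`` for continuous.
    integer_valued
        Continuous variable stored as whole numbers (e.g. age in years).
    """

    name: str
    kind: str
    target_marginal: object
    quasi_identifier: bool = False
    sensitivity: float | None = None
    domain: tuple | None = None
    integer_valued: bool = False

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name}")
        if self.kind == "binary":
            p = float(self.target_marginal)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: binary prevalence {p} outside [0, 1]")
        elif self.kind == "categorical":
            probs = dict(self.target_marginal)
            if any(not 0.0 <= q <= 1.0 for q in probs.values()):
                raise ValueError(f"{self.name}: category probability outside [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: category probabilities must sum to 1")
            if self.domain is not None and tuple(self.domain) != tuple(probs):
                raise ValueError(f"{self.name}: domain does not match marginal keys")
        elif self.kind == "continuous":
            mean, sd, lo, hi = self.target_marginal
            if not lo < hi:
                raise ValueError(f"{self.name}: requires min < max")
            if not sd > 0:
                raise ValueError(f"{self.name}: requires sd > 0")
            if self.sensitivity is not None and not self.sensitivity > 0:
                raise ValueError(f"{self.name}: sensitivity must be > 0")

    @property
    def levels(self) -> tuple:
        """Category labels (categorical), (0, 1) for binary."""
        if self.kind == "binary":
            return (0, 1)
        if self.kind == "categorical":
            return tuple(dict(self.target_marginal))
        raise TypeError(f"{self.name} has no discrete levels")

    @property
    def bounds(self) -> tuple[float, float]:
        if self.kind != "continuous":
            raise TypeError(f"{self.name} is not continuous")
        if self.domain is not None:
            return (float(self.domain[0]), float(self.domain[1]))
        _, _, lo, hi = self.target_marginal
        return (float(lo), float(hi))

    @property
    def laplace_sensitivity(self) -> float:
        lo, hi = self.bounds
        return float(self.sensitivity) if self.sensitivity is not None else hi - lo

    def with_marginal(self, marginal) -> "CovariateSpec":
        return replace(self, target_marginal=marginal)


# Binary comorbidity / medication flags: name -> (RWD count of 3,327, RCT count of 250).
# "< 5" cells encoded as 3 (RWD) and 2 (RCT); synthetic stand-ins, see module docstring.
BINARY_FLAGS: Mapping[str, tuple[int, int]] = {
    "anemia": (761, 26),
    "antidiabetic_med": (954, 76),
    "antihypertensive_med": (3228, 247),
    "aortic_arteriosclerosis": (3, 2),
    "arterial_hypertension": (2226, 220),
    "bmi_ge30": (470, 84),
    "carotid_procedure": (9, 2),
    "chronic_heart_failure": (696, 117),
    "chronic_kidney_disease": (477, 41),
    "copd": (152, 24),
    "coronary_artery_disease": (709, 50),
    "diabetes_mellitus": (832, 87),
    "isth_major_bleeding": (137, 22),
    "osteoporotic_fracture": (165, 5),
    "history_of_stroke": (305, 20),
    "hyperlipidemia": (565, 92),
    "hyperthyroidism": (70, 2),
    "hypothyroidism": (530, 28),
    "low_body_weight": (3091, 221),
    "malignancy": (441, 45),
    "myocardial_infarction": (161, 36),
    "nsaid_use": (825, 18),
    "pci": (202, 15),
    "peripheral_arterial_disease": (113, 20),
    "platelet_inhibitors": (3023, 234),
    "histamine2_use": (18, 2),
    "ssri_use": (176, 6),
    "heparin_use": (1059, 55),
    "prior_noac_use": (1936, 146),
    "creatinine_ge15": (392, 27),
    "smoking": (273, 10),
    "tia": (111, 13),
    "ppi_use": (1494, 109),
}

# Time since AF diagnosis, 3 categories: counts per arm.
AF_DURATION_LEVELS = ("le30", "d31_89", "ge90")
AF_DURATION_COUNTS = {
    "RWD": (693, 2414, 220),
    "RCT": (99, 135, 16),
}

AGE_MARGINAL = {"RWD": (75.92, 9.19, 45.0, 105.0), "RCT": (74.27, 8.32, 45.0, 105.0)}
SEX_MALE = {"RWD": 1622 / RWD_N, "RCT": 141 / RCT_N}


def default_covariates(arm: str = "RWD") -> list[CovariateSpec]:
    """The 36-covariate default schema, with the marginal column of ``arm``.

    ``arm`` is ``"RWD"`` (real-world-data-like, n = 3,327) or ``"RCT"``
    (trial-control-like, n = 250).
    """
    if arm not in ("RWD", "RCT"):
        raise ValueError(f"arm must be 'RWD' or 'RCT', got {arm!r}")
    n = RWD_N if arm == "RWD" else RCT_N
    idx = 0 if arm == "RWD" else 1

    specs: list[CovariateSpec] = [
        CovariateSpec(
            name="age",
            kind="continuous",
            target_marginal=AGE_MARGINAL[arm],
            quasi_identifier=True,
            sensitivity=10.0,  # calibrated, see docs/methods.md
            domain=(45.0, 105.0),
            integer_valued=True,
        ),
        CovariateSpec(
            name="sex_male",
            kind="binary",
            target_marginal=SEX_MALE[arm],
            quasi_identifier=True,
        ),
    ]
    for name, counts in BINARY_FLAGS.items():
        specs.append(CovariateSpec(name=name, kind="binary", target_marginal=counts[idx] / n))

    af_counts = AF_DURATION_COUNTS[arm]
    total = sum(af_counts)
    probs = {lev: c / total for lev, c in zip(AF_DURATION_LEVELS, af_counts)}
    # renormalize exactly
    s = sum(probs.values())
    probs = {k: v / s for k, v in probs.items()}
    specs.append(
        CovariateSpec(
            name="af_duration_cat",
            kind="categorical",
            target_marginal=probs,
            domain=AF_DURATION_LEVELS,
        )
    )
    return specs
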