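"""End-to-end experiment: generate → select → anonymize → balance → compare.

One :class:`ExperimentConfig` drives the whole run.  Per-stage RNG seeds are
derived by hashing (master seed, stage name), so adding a stage never shifts
another stage's random stream, and the matching stage shares one seed across
the pseudonymized and anonymized branches (in the no-noise limit the two
branches must then produce identical matched sets).

``run_experiment`` writes every report surface as CSV plus a YAML manifest
(config hash, per-stage seeds, package version) and simple figures, and
returns an :class:`ExperimentReport` with the headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anonymize import PrivacyConfig, anonymize, privacy_risk_bound
from .audit import AttackConfig, audit_report, membership_inference_attack
from .balance import (
    caliper_match,
    effective_sample_size,
    fit_propensity,
    matching_weights,
    overlap_weights,
    smd,
)
from .builder import SelectionCriteria, apply_selection, assign_index_dates, derive_analysis_table
from .cohort import CohortTable
from .outcomes import anonymization_contrast, cox_fit
from .schema import CovariateSpec
from .synth import CohortConfig, generate_cohort, summarize_marginals

__all__ = ["ExperimentConfig", "ExperimentReport", "stage_seed", "run_experiment"]

log = logging.getLogger("ecanon.pipeline")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2s(master:stage) mod 2^31."""
    digest = hashlib.blake2s(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class BalanceConfig:
    caliper_multiplier: float = 0.2
    smd_cutoffs: tuple[float, float] = (0.1, 0.25)


@dataclass
class AuditGridConfig:
    epsilons: tuple[float, ...] = (0.01, math.log(32), 7.0)
    attack: AttackConfig = field(default_factory=AttackConfig)
    enabled: bool = True


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    privacy: PrivacyConfig = field(default_factory=PrivacyConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    audit: AuditGridConfig = field(default_factory=AuditGridConfig)
    master_seed: int = 0

    def with_master_seed(self, seed: int) -> "ExperimentConfig":
        return dataclasses.replace(self, master_seed=seed)

    # ------------------------------------------------------------ config IO
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        def sub(section, klass, **extra):
            data = dict(raw.get(section) or {})
            data.update(extra)
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            for key in ("noac_window", "study_entry_window", "smd_cutoffs", "baseline_hazard",
                        "quasi_identifiers", "epsilons"):
                if key in data and isinstance(data[key], list):
                    data[key] = tuple(data[key])
            return klass(**data)

        cohort_raw = dict(raw.get("cohort") or {})
        if "covariates" in cohort_raw:
            cov = {
                arm: [CovariateSpec(**{**c, "domain": tuple(c["domain"]) if c.get("domain") else None,
                                        "target_marginal": _marginal_from_yaml(c)})
                      for c in specs]
                for arm, specs in cohort_raw["covariates"].items()
            }
            cohort_raw["covariates"] = cov
            raw = {**raw, "cohort": cohort_raw}
        audit_raw = dict(raw.get("audit") or {})
        attack = AttackConfig(**(audit_raw.pop("attack", {}) or {}))
        raw_audit = {**audit_raw}
        return cls(
            cohort=sub("cohort", CohortConfig),
            criteria=sub("criteria", SelectionCriteria),
            privacy=sub("privacy", PrivacyConfig),
            balance=sub("balance", BalanceConfig),
            audit=AuditGridConfig(
                epsilons=tuple(raw_audit.get("epsilons", (0.01, math.log(32), 7.0))),
                attack=attack,
                enabled=bool(raw_audit.get("enabled", True)),
            ),
            master_seed=int(raw.get("master_seed", 0)),
        )

    def to_dict(self) -> dict:
        def specs_out(specs):
            out = []
            for s in specs:
                d = dataclasses.asdict(s)
                if isinstance(d["target_marginal"], tuple):
                    d["target_marginal"] = list(d["target_marginal"])
                if d["domain"] is not None:
                    d["domain"] = list(d["domain"])
                out.append(d)
            return out

        cohort = dataclasses.asdict(self.cohort)
        cohort["covariates"] = {a: specs_out(s) for a, s in self.cohort.covariates.items()}
        if self.cohort.latent_correlation is not None:
            cohort["latent_correlation"] = np.asarray(self.cohort.latent_correlation).tolist()
        return {
            "cohort": _listify(cohort),
            "criteria": _listify(dataclasses.asdict(self.criteria)),
            "privacy": _listify(dataclasses.asdict(self.privacy)),
            "balance": _listify(dataclasses.asdict(self.balance)),
            "audit": {
                "epsilons": list(self.audit.epsilons),
                "attack": dataclasses.asdict(self.audit.attack),
                "enabled": self.audit.enabled,
            },
            "master_seed": self.master_seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _marginal_from_yaml(c: dict):
    m = c["target_marginal"]
    if isinstance(m, list):
        return tuple(m)
    if isinstance(m, dict) and c.get("domain"):
        # YAML serialization sorts mapping keys; restore the domain's order
        return {lev: m[lev] for lev in c["domain"]}
    return m


def _listify(d):
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


@dataclass
class ExperimentReport:
    outdir: Path
    artifacts: dict[str, Path]
    matched_counts: dict[str, int]
    ess: dict[str, dict[str, dict[str, float]]]  # version -> method -> arm -> ESS
    hazard_ratios: dict[str, dict[str, float]]  # subset -> {hr, ci_lower, ci_upper, p}
    balance_success: dict[str, dict[str, int]]  # version -> method -> n(SMD<0.1)
    stage_seeds: dict[str, int]


def _balance_for_version(
    stacked: CohortTable, specs, cfg: ExperimentConfig, match_seed: int
):
    fit = fit_propensity(stacked, specs)
    matches = caliper_match(fit, cfg.balance.caliper_multiplier, seed=match_seed)
    mw = matching_weights(fit)
    ow = overlap_weights(fit)

    tables = {"pre": smd(stacked, specs, cutoffs=cfg.balance.smd_cutoffs)}
    matched_pos = np.concatenate(
        [matches.pairs["rct_pos"].to_numpy(int), matches.pairs["rwd_pos"].to_numpy(int)]
    ) if matches.n_matched else np.array([], dtype=int)
    if matches.n_matched:
        sub = CohortTable(stacked.data.iloc[matched_pos].reset_index(drop=True), stacked.arm)
        tables["match"] = smd(sub, specs, cutoffs=cfg.balance.smd_cutoffs)
    else:
        tables["match"] = tables["pre"].assign(smd=np.nan, label="fail")
    tables["mw"] = smd(stacked, specs, weights=mw, cutoffs=cfg.balance.smd_cutoffs)
    tables["ow"] = smd(stacked, specs, weights=ow, cutoffs=cfg.balance.smd_cutoffs)
    ess = {"MW": mw.ess(), "OW": ow.ess()}
    return fit, matches, tables, ess


def run_experiment(config: ExperimentConfig, outdir) -> ExperimentReport:
    """Execute the full pipeline and write all report surfaces to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: stage_seed(config.master_seed, name)
        for name in ("generate", "durations", "index", "anonymize", "match", "audit",
                     "nonmembers")
    }
    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame | CohortTable):
        path = outdir / f"{name}.csv"
        if isinstance(df, CohortTable):
            df.write_csv(path)
        else:
            df.to_csv(path, index=False)
        artifacts[name] = path

    # ---- generate ----------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["generate"])
    rwd = generate_cohort(cohort_cfg, "RWD")
    rct = generate_cohort(cohort_cfg, "RCT")
    specs = cohort_cfg.covariates["RWD"]
    log.info("generated RWD n=%d, RCT n=%d", rwd.n, rct.n)

    # ---- select + index ----------------------------------------------------
    rwd_sel = apply_selection(rwd, config.criteria)
    durations = np.random.default_rng(seeds["durations"]).exponential(
        cohort_cfg.rct_duration_mean_days, size=cohort_cfg.n_rct
    )
    durations = np.ceil(durations).astype(int)
    assignments = assign_index_dates(
        rwd_sel,
        durations,
        cohort_cfg.current_user_fraction,
        cohort_cfg.censor_date,
        seed=seeds["index"],
    )
    pseudo = derive_analysis_table(rwd_sel, assignments, cohort_cfg.censor_date)
    save("pseudonymized_rwd", pseudo)
    save("rct_arm", rct)

    # ---- anonymize ---------------------------------------------------------
    privacy = dataclasses.replace(config.privacy, seed=seeds["anonymize"])
    anon_result = anonymize(pseudo, privacy, specs)
    anon = anon_result.table
    save("anonymized_rwd", anon)
    (outdir / "anonymization_provenance.yaml").write_text(
        yaml.safe_dump(anon_result.provenance, sort_keys=True)
    )
    artifacts["anonymization_provenance"] = outdir / "anonymization_provenance.yaml"

    # ---- baseline table (descriptive analog) -------------------------------
    baseline = []
    for label, tbl in (("pseudonymized", pseudo), ("anonymized", anon), ("rct", rct)):
        s = summarize_marginals(tbl, specs if label != "rct" else cohort_cfg.covariates["RCT"])
        s.insert(0, "dataset", label)
        baseline.append(s)
    save("baseline_table", pd.concat(baseline, ignore_index=True))

    # ---- balance per data version ------------------------------------------
    matched_counts: dict[str, int] = {}
    matched_ids: dict[str, set] = {}
    ess: dict[str, dict] = {}
    balance_success: dict[str, dict[str, int]] = {}
    for version, tbl in (("pseudo", pseudo), ("anon", anon)):
        stacked = CohortTable(
            pd.concat([tbl.data, rct.data], ignore_index=True), arm="stacked"
        )
        fit, matches, tables, version_ess = _balance_for_version(
            stacked, specs, config, seeds["match"]
        )
        matched_counts[version] = matches.n_matched
        matched_ids[version] = set(matches.pairs["rwd_id"]) if matches.n_matched else set()
        ess[version] = version_ess
        balance_success[version] = {
            m: int((t["smd"] < config.balance.smd_cutoffs[0]).sum()) for m, t in tables.items()
        }
        for method, t in tables.items():
            save(f"balance_{version}_{method}", t)
        save(f"matched_pairs_{version}", matches.pairs)
        save(
            f"propensity_{version}",
            pd.DataFrame(
                {
                    "subject_id": stacked.data["subject_id"],
                    "arm_label": stacked.data["arm_label"],
                    "score": fit.scores,
                    "logit": fit.logits,
                }
            ),
        )

    # ---- outcomes ----------------------------------------------------------
    hazard_ratios: dict[str, dict[str, float]] = {}
    for subset in ("all", "matched", "unmatched"):
        cox, km_p, km_a = anonymization_contrast(
            pseudo,
            anon,
            subset=subset,
            pseudo_ids=matched_ids["pseudo"],
            anon_ids=matched_ids["anon"],
        )
        hazard_ratios[subset] = {
            "hr": cox.hr("anonymized"),
            "ci_lower": cox.ci("anonymized")[0],
            "ci_upper": cox.ci("anonymized")[1],
            "p": cox.p_value("anonymized"),
        }
        save(f"km_{subset}_pseudo", km_p.to_frame())
        save(f"km_{subset}_anon", km_a.to_frame())
    save(
        "cox_contrast",
        pd.DataFrame(
            [{"subset": s, **v} for s, v in hazard_ratios.items()]
        ),
    )

    # covariate-outcome association forest per version
    from .balance import design_matrix

    for version, tbl in (("pseudo", pseudo), ("anon", anon)):
        x = design_matrix(tbl.data, specs)
        forest = cox_fit(tbl.data["os_time"], tbl.data["os_event"], x)
        save(f"cox_forest_{version}", forest.summary.rename_axis("term").reset_index())

    # ---- privacy audit -----------------------------------------------------
    if config.audit.enabled:
        nonmember_cfg = dataclasses.replace(config.cohort, seed=seeds["nonmembers"])
        nonmembers = generate_cohort(nonmember_cfg, "RWD")
        results = {}
        for i, eps in enumerate(config.audit.epsilons):
            p = dataclasses.replace(privacy, epsilon=float(eps), seed=seeds["audit"] + i)
            release = anonymize(pseudo, p, specs)
            attack = dataclasses.replace(config.audit.attack, seed=seeds["audit"] + 1000 + i)
            results[float(eps)] = membership_inference_attack(
                release, pseudo, nonmembers, specs, attack
            )
        audit_df = audit_report(results, n=pseudo.n)
        save("privacy_audit", audit_df)

    # ---- figures + manifest -------------------------------------------------
    try:
        _figures(outdir, artifacts)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        log.warning("figure rendering failed: %s", exc)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
        "matched_counts": matched_counts,
        "hazard_ratios": hazard_ratios,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    return ExperimentReport(
        outdir=outdir,
        artifacts=artifacts,
        matched_counts=matched_counts,
        ess=ess,
        hazard_ratios=hazard_ratios,
        balance_success=balance_success,
        stage_seeds=seeds,
    )


def _figures(outdir: Path, artifacts: dict[str, Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for key, label in (("km_all_pseudo", "pseudonymized"), ("km_all_anon", "anonymized")):
        if key in artifacts:
            km = pd.read_csv(artifacts[key])
            ax.step(km["time"], km["survival"], where="post", label=label)
    ax.set_xlabel("days from study entry")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "km_all.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 9))
    offset = {"pre": 0.0, "match": 0.15, "mw": 0.3, "ow": 0.45}
    for method, dy in offset.items():
        key = f"balance_pseudo_{method}"
        if key in artifacts:
            t = pd.read_csv(artifacts[key])
            ax.scatter(t["smd"], np.arange(len(t)) + dy, s=10, label=method)
    ax.axvline(0.1, color="grey", ls="--", lw=0.8)
    ax.axvline(0.25, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("absolute standardized mean difference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "smd.png", dpi=120)
    plt.close(fig)
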