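"""End-to-end orchestration of the synthetic study.

design -> behaviour -> AND/OR model fits -> behavioural GLMMs -> scans ->
LSS betas -> decomposition -> RSA, driven by one config whose global seed is
expanded deterministically into per-stage, per-participant substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour_stats import (
    build_accuracy_design,
    build_latency_design,
    fit_glmm,
)
from .behaviour_synth import CohortConfig, generate_cohort
from .decomposition_rsa import (
    behavioural_covariates,
    build_occurrence_design,
    build_rsa_table,
    copresentation_nuisance,
    decompose_patterns,
    delta1_sensitivity,
    fit_rsa_lmm,
    outlier_threshold,
    simulation_nuisance,
)
from .inference_models import compare_models, fit_participant, spearman_observed_expected
from .pattern_synth import (
    NoiseConfig,
    calibrate_adaptation,
    lss_estimate,
    make_ground_truth,
    simulate_scan,
)
from .task_design import (
    SESSIONS,
    generate_interleaved_schedule,
    generate_progressive_schedule,
    generate_scan_trials,
)

STAGES = ("design", "behaviour", "models", "glmm", "scans", "rsa")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic study; every seed is explicit."""

    seed: int = 0
    n_participants: int = 34
    regime: str = "OR"
    kappa: float = 0.9
    retrieval_beta: tuple = (8.0, 2.0)
    miss_rate: float = 0.0181
    model_iters: int = 1000
    n_boot: int = 10_000
    glmm_engine: str = "cluster"
    n_voxels: int = 50
    pattern_decay_lambda: float = 2.0
    pattern_amplitude: float = 1.0
    noise_sigma: float = 1.0
    noise_rho: float = 0.3
    nuisance_sim_iters: int = 0  # 0 disables the simulation nuisance predictor
    rsa_engine: str = "auto"
    out_dir: str = "pipeline_output"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        if tuple(cfg.retrieval_beta) != tuple(raw["retrieval_beta"]):
            raise ValueError("config did not round-trip")
        cfg.retrieval_beta = tuple(cfg.retrieval_beta)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage, write artifacts, and return the summary report."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "regime": config.regime,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")
    try:
        _run_stages(config, out, report)
    except Exception as exc:  # persist partial outputs before aborting
        report["failed_stage"] = report.get("current_stage", "unknown")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        raise RuntimeError(
            f"pipeline aborted in stage {report['failed_stage']}: {exc}"
        ) from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _run_stages(config: PipelineConfig, out: Path, report: dict) -> None:
    # -- design ------------------------------------------------------------
    report["current_stage"] = "design"
    seed = _stage_seed(config, "design")
    inter = generate_interleaved_schedule(seed)
    prog = generate_progressive_schedule(seed + 1)
    scan_list = generate_scan_trials(seed + 2)
    inter.trials.to_csv(out / "schedule_interleaved.tsv", sep="\t", index=False)
    prog.trials.to_csv(out / "schedule_progressive.tsv", sep="\t", index=False)
    scan_list.trials.to_csv(out / "scan_trials.tsv", sep="\t", index=False)
    report["stages"]["design"] = {
        "interleaved_trials": int(len(inter.trials)),
        "progressive_trials": int(len(prog.trials)),
        "scan_trials": int(len(scan_list.events)),
        "null_events": int((scan_list.trials["pair"] == "").sum()),
    }

    # -- behaviour ---------------------------------------------------------
    report["current_stage"] = "behaviour"
    cohort_cfg = CohortConfig(
        n_participants=config.n_participants, regime=config.regime,
        kappa=config.kappa, retrieval_beta=tuple(config.retrieval_beta),
        miss_rate=config.miss_rate,
    )
    behaviour, profiles = generate_cohort(cohort_cfg, seed=_stage_seed(config, "behaviour"))
    behaviour.to_csv(out / "behaviour.tsv", sep="\t", index=False)
    report["stages"]["behaviour"] = {
        "n_participants": config.n_participants,
        "n_trials": int(len(behaviour)),
        "missing_fraction": float(behaviour["correct"].isna().mean()),
    }

    # -- AND/OR model fits ---------------------------------------------------
    report["current_stage"] = "models"
    seed = _stage_seed(config, "models")
    rows = []
    for prof in profiles:
        for session in SESSIONS:
            fits = fit_participant(
                behaviour, prof.id, session,
                n_iter=config.model_iters, seed=seed + 7 * prof.id,
            )
            rows.append(
                {"participant": prof.id, "session": session,
                 "training_method": prof.training_method,
                 "kappa_AND": fits["AND"].kappa_hat, "H_AND": fits["AND"].H,
                 "kappa_OR": fits["OR"].kappa_hat, "H_OR": fits["OR"].H,
                 "rho_AND": spearman_observed_expected(fits["AND"]),
                 "rho_OR": spearman_observed_expected(fits["OR"])}
            )
    fits_df = pd.DataFrame(rows)
    fits_df.to_csv(out / "model_fits.tsv", sep="\t", index=False)
    comparison = compare_models(fits_df, n_boot=config.n_boot, seed=seed + 1)
    preferred = "OR" if comparison["mean_H_OR"] < comparison["mean_H_AND"] else "AND"
    report["stages"]["models"] = {
        "comparison": comparison, "preferred_model": preferred,
        "median_kappa_AND": float(fits_df["kappa_AND"].median()),
        "median_kappa_OR": float(fits_df["kappa_OR"].median()),
    }

    # -- behavioural GLMMs ---------------------------------------------------
    report["current_stage"] = "glmm"
    seed = _stage_seed(config, "glmm")
    acc = fit_glmm(build_accuracy_design(behaviour, seed=seed), engine=config.glmm_engine)
    lat = fit_glmm(build_latency_design(behaviour), engine=config.glmm_engine)
    acc.coefficients.to_csv(out / "glmm_accuracy.tsv", sep="\t")
    lat.coefficients.to_csv(out / "glmm_latency.tsv", sep="\t")
    report["stages"]["glmm"] = {
        "accuracy": {"engine": acc.engine, "downgraded": acc.downgraded,
                     "coefficients": acc.coefficients["coef"].to_dict()},
        "latency": {"engine": lat.engine, "downgraded": lat.downgraded,
                    "coefficients": lat.coefficients["coef"].to_dict()},
    }

    # -- scans + decomposition ----------------------------------------------
    report["current_stage"] = "scans"
    seed = _stage_seed(config, "scans")
    rng = np.random.SeedSequence(seed)
    design = build_occurrence_design()
    noise = NoiseConfig(sigma=config.noise_sigma, rho=config.noise_rho)
    adaptation = calibrate_adaptation()
    cohort_patterns = {}
    for prof, sub in zip(profiles, rng.spawn(len(profiles))):
        s = int(sub.generate_state(2)[0] % 2**31)
        gt = make_ground_truth(
            n_voxels=config.n_voxels, decay_lambda=config.pattern_decay_lambda,
            amplitude=config.pattern_amplitude, seed=s,
        )
        scan = simulate_scan(gt, scan_list, noise=noise, adaptation=adaptation,
                             seed=s + 1)
        betas = lss_estimate(scan)
        cohort_patterns[prof.id] = decompose_patterns(betas, design)
    pd.concat(cohort_patterns, names=["participant"]).to_csv(
        out / "texture_patterns.tsv", sep="\t"
    )
    report["stages"]["scans"] = {
        "n_voxels": config.n_voxels, "n_volumes": 537,
        "adaptation": {"a": adaptation.a, "tau": adaptation.tau},
    }

    # -- RSA -----------------------------------------------------------------
    report["current_stage"] = "rsa"
    seed = _stage_seed(config, "rsa")
    nuis1 = copresentation_nuisance()
    nuis2 = (
        simulation_nuisance(scan_list, n_iter=config.nuisance_sim_iters,
                            n_voxels=config.n_voxels, seed=seed)
        if config.nuisance_sim_iters > 0
        else None
    )
    rsa_report = {}
    for scope in ("within", "across"):
        table = build_rsa_table(cohort_patterns, behaviour, scope,
                                nuisance_copres=nuis1, nuisance_sim=nuis2)
        table.to_csv(out / f"rsa_table_{scope}.tsv", sep="\t", index=False)
        res = fit_rsa_lmm(table, scope=scope, engine=config.rsa_engine)
        entry = {
            "n_rows": res.n_rows, "n_excluded": res.n_excluded,
            "outlier_threshold": res.threshold, "engine": res.engine,
            "distance_coef": float(res.coefficients.loc["distance", "coef"]),
            "distance_t": float(res.coefficients.loc["distance", "t"]),
        }
        if scope == "within":
            sens = delta1_sensitivity(table, engine=config.rsa_engine)
            entry["delta1_excluded"] = {
                "n_rows": sens.n_rows,
                "distance_coef": float(sens.coefficients.loc["distance", "coef"]),
                "distance_t": float(sens.coefficients.loc["distance", "t"]),
            }
        res.coefficients.to_csv(out / f"rsa_coefficients_{scope}.tsv", sep="\t")
        rsa_report[scope] = entry
    report["stages"]["rsa"] = rsa_report
    report.pop("current_stage")


def validate_report(report: dict) -> dict:
    """Machine-readable checklist of the design/model constants.

    Recomputes the analytic quantities (outlier thresholds, adaptation
    anchors) and checks the schedule counts recorded in the report.
    """
    checks = {}

    def add(name, ok):
        checks[name] = bool(ok)

    thr100, thr1000 = outlier_threshold(100), outlier_threshold(1000)
    add("outlier_threshold_n100_approx_2.7", round(thr100, 1) == 2.7)
    add("outlier_threshold_n1000_approx_3.4", round(thr1000, 1) == 3.4)
    model = calibrate_adaptation()
    add("adaptation_23pct_at_100ms", abs(model.attenuation(0.1) - 0.23) < 1e-12)
    add("adaptation_10pct_at_1s", abs(model.attenuation(1.0) - 0.10) < 1e-12)
    stages = report.get("stages", {})
    design = stages.get("design")
    if design is None:
        checks["training_schedule_360_trials"] = "not run"
        checks["scan_192_trials_16_nulls"] = "not run"
    else:
        add("training_schedule_360_trials",
            design["interleaved_trials"] == 360 and design["progressive_trials"] == 360)
        add("scan_192_trials_16_nulls",
            design["scan_trials"] == 192 and design["null_events"] == 16)
    models = stages.get("models")
    if models is None or "regime" not in report:
        checks["generating_model_preferred"] = "not run"
    else:
        add("generating_model_preferred",
            models["preferred_model"] == report["regime"])
    return checks
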