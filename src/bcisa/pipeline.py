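"""Workflow orchestration: simulate -> fit -> compare -> recover.

Importable functions (no console entry points) tie the stages together and
own all serialization: participant tables as CSV, fit results and group
summaries as JSON, run configuration as YAML validated by a pydantic
schema.  Every run writes its resolved configuration next to its outputs,
so any artifact is reproducible from its sidecar config and seeds alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .cohort import (
    SyntheticCohort,
    recovery_report,
    simulate_cohort,
)
from .delay import (
    AGENCIES,
    DELAYS_MS,
    Exp2ParticipantData,
    PARAM_NAMES,
    detection_curve,
    fit_participant_exp2,
    fit_psychometric,
)
from .evidence import (
    PriorSpec,
    bernoulli_loglik,
    bias_model_loglik,
    compare_models,
    forced_fusion_loglik,
    forced_separation_loglik,
    kl_goodness_of_fit,
    laplace_evidence,
    uniform_model_loglik,
)
from .tactile import (
    MOVEMENT_TRIAL_TYPES,
    Exp1ParticipantData,
    Exp1Params,
    detection_probability,
    fit_participant_exp1,
)

__all__ = [
    "RunConfig",
    "load_config",
    "run_simulate",
    "run_fit",
    "run_compare",
    "run_recover",
    "read_exp1_csv",
    "read_exp2_csv",
    "write_cohort_csv",
]

log = logging.getLogger("bcisa")


class RunConfig(BaseModel):
    """Validated run configuration (YAML-serializable)."""

    experiment: str = Field(pattern="^exp[12]$")
    seed: int = 0
    n_participants: int = Field(default=8, ge=1)
    n_trials: int | None = Field(default=None, ge=1)
    n_restarts: int = Field(default=10, ge=1)
    tol: float | None = None
    prior_sd: float = Field(default=1.0, gt=0)
    out_dir: str = "."

    @field_validator("n_trials")
    @classmethod
    def _positive(cls, v):
        if v is not None and v < 1:
            raise ValueError("n_trials must be >= 1")
        return v


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))


def _write_sidecar(config: RunConfig, out_dir: Path, stage: str):
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{stage}_config.yaml", "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def write_cohort_csv(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort's trial tables (CSV) and provenance sidecar (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, _, data in cohort.members:
        if cohort.experiment == "exp1":
            for tt in MOVEMENT_TRIAL_TYPES:
                n, k = data.counts[tt]
                rows.append(
                    {"participant_id": pid, "trial_type": tt,
                     "n_trials": n, "n_detections": k}
                )
        else:
            for (agency, d), (n, k) in sorted(data.counts.items()):
                rows.append(
                    {"participant_id": pid, "agency": agency, "delay_ms": d,
                     "n_trials": n, "n_detections": k}
                )
    path = out_dir / f"{cohort.experiment}_cohort.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    with open(out_dir / f"{cohort.experiment}_provenance.json", "w") as fh:
        json.dump(cohort.provenance, fh, indent=2)
    return path


def read_exp1_csv(path) -> dict[str, Exp1ParticipantData]:
    """Read tactile-paradigm trial tables keyed by participant."""
    df = pd.read_csv(path)
    required = {"participant_id", "trial_type", "n_trials", "n_detections"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    out = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        counts = {}
        for i, row in grp.iterrows():
            if row["trial_type"] not in MOVEMENT_TRIAL_TYPES:
                raise ValueError(f"row {i}: unknown trial_type {row['trial_type']!r}")
            counts[row["trial_type"]] = (int(row["n_trials"]), int(row["n_detections"]))
        out[str(pid)] = Exp1ParticipantData(counts=counts)
    return out


def read_exp2_csv(path) -> dict[str, Exp2ParticipantData]:
    """Read delay-paradigm trial tables keyed by participant."""
    df = pd.read_csv(path)
    required = {"participant_id", "agency", "delay_ms", "n_trials", "n_detections"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    out = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        counts = {}
        for i, row in grp.iterrows():
            if row["agency"] not in AGENCIES:
                raise ValueError(f"row {i}: unknown agency {row['agency']!r}")
            counts[(str(row["agency"]), int(row["delay_ms"]))] = (
                int(row["n_trials"]), int(row["n_detections"]),
            )
        out[str(pid)] = Exp2ParticipantData(counts=counts)
    return out


def run_simulate(config: RunConfig) -> Path:
    """Simulate a synthetic cohort and write its CSV + provenance."""
    out_dir = Path(config.out_dir)
    _write_sidecar(config, out_dir, "simulate")
    cohort = simulate_cohort(
        config.experiment,
        n_participants=config.n_participants,
        seed=config.seed,
        n_trials=config.n_trials,
    )
    path = write_cohort_csv(cohort, out_dir)
    log.info("simulated %d participants -> %s", len(cohort), path)
    return path


def _fit_record_exp1(pid, data, config: RunConfig) -> dict:
    fit = fit_participant_exp1(
        data,
        seed=config.seed,
        n_restarts=config.n_restarts,
        tol=config.tol or 1e-12,
    )
    tm = fit.best_params.transition_matrix
    return {
        "participant_id": pid,
        "best_cost": fit.best_cost,
        "sigma": fit.best_params.sigma,
        "transition_logits": fit.best_params.transition_logits.tolist(),
        "transition_matrix": tm.tolist(),
        "n_function_evals": fit.n_function_evals,
        "restart_costs": fit.restart_costs.tolist(),
        "seed": fit.seed,
    }


def _fit_record_exp2(pid, data, agency, config: RunConfig) -> dict:
    fit = fit_participant_exp2(
        data,
        agency,
        seed=config.seed,
        n_restarts=config.n_restarts,
        tol=config.tol or 1e-8,
    )
    curve = detection_curve(fit.best_params)
    psy = fit_psychometric(curve, [d / 100.0 for d in DELAYS_MS])  # deci-seconds
    return {
        "participant_id": pid,
        "agency": agency,
        "best_cost": fit.best_cost,
        "params": {n: getattr(fit.best_params, n) for n in PARAM_NAMES},
        "detection_curve": curve.tolist(),
        "pse_ds": psy.threshold,
        "slope": psy.slope,
        "n_function_evals": fit.n_function_evals,
        "restart_costs": fit.restart_costs.tolist(),
        "seed": fit.seed,
    }


def run_fit(config: RunConfig, data_path) -> Path:
    """Fit every participant in a cohort CSV; write one JSON record each.

    Delay-paradigm participants are fitted separately per agency condition.
    Per-participant failures are logged and recorded, not fatal.
    """
    out_dir = Path(config.out_dir)
    _write_sidecar(config, out_dir, "fit")
    records, failures = [], []
    if config.experiment == "exp1":
        participants = read_exp1_csv(data_path)
        for pid, data in participants.items():
            try:
                records.append(_fit_record_exp1(pid, data, config))
            except Exception as exc:
                log.error("fit failed for %s: %r", pid, exc)
                failures.append({"participant_id": pid, "error": repr(exc)})
    else:
        participants = read_exp2_csv(data_path)
        for pid, data in participants.items():
            for agency in AGENCIES:
                if not data.has_agency(agency):
                    continue
                try:
                    records.append(_fit_record_exp2(pid, data, agency, config))
                except Exception as exc:
                    log.error("fit failed for %s/%s: %r", pid, agency, exc)
                    failures.append(
                        {"participant_id": pid, "agency": agency, "error": repr(exc)}
                    )
    path = out_dir / f"{config.experiment}_fits.json"
    with open(path, "w") as fh:
        json.dump({"fits": records, "failures": failures}, fh, indent=2)
    for rec in records:
        log.info(
            "fit %s: cost=%.4g nfev=%d restart costs=%s",
            rec["participant_id"], rec["best_cost"],
            rec["n_function_evals"], np.round(rec["restart_costs"], 4).tolist(),
        )
    return path


def _exp1_model_laps(data: Exp1ParticipantData, fit_rec: dict, prior: PriorSpec):
    """LAP per model for one tactile-paradigm participant."""
    cells = [data.counts[tt] for tt in MOVEMENT_TRIAL_TYPES]

    def causal_loglik(x):
        params = Exp1Params(transition_logits=x[:6], sigma=float(np.exp(x[6])))
        rates = [detection_probability(tt, params) for tt in MOVEMENT_TRIAL_TYPES]
        return bernoulli_loglik(rates, cells)

    x_opt = np.append(fit_rec["transition_logits"], np.log(fit_rec["sigma"]))
    causal = laplace_evidence(causal_loglik, x_opt, prior)

    bias_ll, _ = bias_model_loglik(data)
    rate = sum(k for _, k in cells) / sum(n for n, _ in cells)
    rate = min(max(rate, 1e-12), 1 - 1e-12)

    def bias_loglik(x):
        p = float(1.0 / (1.0 + np.exp(-x[0])))
        return bernoulli_loglik([p] * len(cells), cells)

    bias = laplace_evidence(bias_loglik, np.array([np.log(rate / (1 - rate))]), prior)
    unif_ll, _ = uniform_model_loglik(data)
    uniform = laplace_evidence(lambda x: unif_ll, np.array([]), prior)
    return {"causal": causal, "bias": bias, "uniform": uniform}


def run_compare(config: RunConfig, data_path, fits_path) -> Path:
    """Laplace evidence per participant per model, ΔLAP summaries, KL fit.

    Writes a per-participant CSV table and a JSON group summary with
    group-level evidence ratios exp(Σ ΔLAP).
    """
    out_dir = Path(config.out_dir)
    _write_sidecar(config, out_dir, "compare")
    prior = PriorSpec(sd=config.prior_sd)
    with open(fits_path) as fh:
        fits = {
            (rec["participant_id"], rec.get("agency")): rec
            for rec in json.load(fh)["fits"]
        }

    rows, laps, kls = [], {}, []
    if config.experiment == "exp1":
        participants = read_exp1_csv(data_path)
        for pid, data in participants.items():
            rec = fits.get((pid, None))
            if rec is None:
                raise ValueError(f"no fit record for participant {pid!r}")
            model_laps = _exp1_model_laps(data, rec, prior)
            params = Exp1Params(
                transition_logits=np.array(rec["transition_logits"]),
                sigma=rec["sigma"],
            )
            p_model = [
                detection_probability(tt, params) for tt in MOVEMENT_TRIAL_TYPES
            ]
            q = [data.rate(tt) for tt in MOVEMENT_TRIAL_TYPES]
            kls.append({"participant_id": pid, "kl": kl_goodness_of_fit(p_model, q)})
            for model, ev in model_laps.items():
                laps.setdefault(model, []).append(ev.lap)
                rows.append(
                    {"participant_id": pid, "model": model, "lap": ev.lap,
                     "log_lik": ev.log_lik_at_opt, "log_prior": ev.log_prior_at_opt,
                     "log_det_hessian": ev.log_det_hessian,
                     "pd_repair": ev.pd_repair_applied}
                )
        pairs = [("causal", "bias"), ("bias", "uniform")]
    else:
        participants = read_exp2_csv(data_path)
        for pid, data in participants.items():
            for agency in AGENCIES:
                if not data.has_agency(agency):
                    continue
                rec = fits.get((pid, agency))
                if rec is None:
                    raise ValueError(f"no fit record for {pid!r}/{agency}")
                cells = [data.counts[(agency, d)] for d in DELAYS_MS]
                curve = np.array(rec["detection_curve"])

                def causal_loglik(x, _cells=cells):
                    from .delay import Exp2Params
                    params = Exp2Params.from_logits(x)
                    return bernoulli_loglik(detection_curve(params), _cells)

                from scipy.special import logit as _logit
                x_opt = _logit(np.array([rec["params"][n] for n in PARAM_NAMES]))
                causal = laplace_evidence(causal_loglik, x_opt, prior)
                rate = sum(k for _, k in cells) / sum(n for n, _ in cells)
                rate = min(max(rate, 1e-12), 1 - 1e-12)

                def bias_loglik(x, _cells=cells):
                    p = float(1.0 / (1.0 + np.exp(-x[0])))
                    return bernoulli_loglik([p] * len(_cells), _cells)

                bias = laplace_evidence(
                    bias_loglik, np.array([np.log(rate / (1 - rate))]), prior
                )
                fus_ll, _ = forced_fusion_loglik(data, agency)
                sep_ll, _ = forced_separation_loglik(data, agency)
                fusion = laplace_evidence(lambda x: fus_ll, np.array([]), prior)
                separation = laplace_evidence(lambda x: sep_ll, np.array([]), prior)
                model_laps = {
                    "causal": causal, "bias": bias,
                    "fusion": fusion, "separation": separation,
                }
                q = [data.rate(agency, d) for d in DELAYS_MS]
                kls.append(
                    {"participant_id": pid, "agency": agency,
                     "kl": kl_goodness_of_fit(curve, q)}
                )
                for model, ev in model_laps.items():
                    laps.setdefault((model, agency), []).append(ev.lap)
                    rows.append(
                        {"participant_id": pid, "agency": agency, "model": model,
                         "lap": ev.lap, "log_lik": ev.log_lik_at_opt,
                         "log_prior": ev.log_prior_at_opt,
                         "log_det_hessian": ev.log_det_hessian,
                         "pd_repair": ev.pd_repair_applied}
                    )
        pairs = [("causal", "bias"), ("fusion", "bias"), ("separation", "bias")]

    table_path = out_dir / f"{config.experiment}_model_comparison.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)

    summary = {"kl_per_participant": kls,
               "kl_mean": float(np.mean([r["kl"] for r in kls]))}
    if config.experiment == "exp1":
        for a, b in pairs:
            cmp_res = compare_models(
                {a: np.array(laps[a]), b: np.array(laps[b])}, a, b
            )
            summary[f"{a}_vs_{b}"] = {
                "mean_delta_lap": cmp_res.mean, "sem": cmp_res.sem,
                "group_sum": cmp_res.group_sum, "group_ratio": cmp_res.group_ratio,
            }
    else:
        for agency in AGENCIES:
            for a, b in pairs:
                key_a, key_b = (a, agency), (b, agency)
                if key_a not in laps or key_b not in laps:
                    continue
                cmp_res = compare_models(
                    {a: np.array(laps[key_a]), b: np.array(laps[key_b])}, a, b
                )
                summary[f"{agency}.{a}_vs_{b}"] = {
                    "mean_delta_lap": cmp_res.mean, "sem": cmp_res.sem,
                    "group_sum": cmp_res.group_sum,
                    "group_ratio": float(cmp_res.group_sum)
                    if abs(cmp_res.group_sum) > 700
                    else cmp_res.group_ratio,
                }
    summary_path = out_dir / f"{config.experiment}_comparison_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary_path


def run_recover(config: RunConfig) -> Path:
    """End-to-end parameter recovery: simulate, fit everyone, tabulate.

    Writes the per-participant true-vs-recovered table (CSV) and the
    per-parameter summary with bias, RMSE and correlation (JSON).
    """
    out_dir = Path(config.out_dir)
    _write_sidecar(config, out_dir, "recover")
    cohort = simulate_cohort(
        config.experiment,
        n_participants=config.n_participants,
        seed=config.seed,
        n_trials=config.n_trials,
    )

    if config.experiment == "exp1":
        def fit_fn(gt, data):
            fit = fit_participant_exp1(
                data, seed=gt.seed, n_restarts=config.n_restarts,
                tol=config.tol or 1e-12,
            )
            from .cohort import _exp1_fitted_values
            return _exp1_fitted_values(fit.best_params)
    else:
        def fit_fn(gt, data):
            out = {}
            for agency in AGENCIES:
                fit = fit_participant_exp2(
                    data, agency, seed=gt.seed, n_restarts=config.n_restarts,
                    tol=config.tol or 1e-8,
                )
                for name in PARAM_NAMES:
                    out[f"{agency}.{name}"] = getattr(fit.best_params, name)
            return out

    report = recovery_report(cohort, fit_fn)
    table_path = out_dir / f"{config.experiment}_recovery.csv"
    report.to_csv(table_path, index=False)
    summary = report.attrs["summary"]
    with open(out_dir / f"{config.experiment}_recovery_summary.json", "w") as fh:
        json.dump(
            {p: {k: (None if pd.isna(v) else v) for k, v in row.items()}
             for p, row in summary.to_dict("index").items()},
            fh, indent=2,
        )
    return table_path
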