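"""Synthetic participants for both paradigms at known ground-truth parameters.

The original behavioral datasets are not deposited; these generators stand
in for them with exactly the statistical structure the analysis assumes:
for each condition cell the generative model's detection probability is
computed at known ground-truth parameters and the per-cell detection count
is a binomial draw.  Everything downstream — fitting, model comparison,
parameter- and model-recovery studies — runs on these tables.

Ground-truth parameter ranges default to neighborhoods of realistic
fitted regimes (noise sigma near 20, sticky internal transitions for the
tactile model; reliable emissions and sticky chains for the delay model).
Per-cell trial counts are configurable; the originals' exact per-cell
counts are not all published.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delay import (
    AGENCIES,
    DELAYS_MS,
    DelayConfig,
    Exp2Params,
    Exp2ParticipantData,
    PARAM_NAMES,
    detection_curve,
)
from .tactile import (
    MOVEMENT_TRIAL_TYPES,
    Exp1Params,
    Exp1ParticipantData,
    Exp1TrialConfig,
    detection_probability,
    transition_matrix_from_logits,
)

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "DEFAULT_EXP1_RANGES",
    "DEFAULT_EXP2_RANGES",
    "sample_ground_truth",
    "simulate_participant",
    "simulate_cohort",
    "recovery_report",
]

#: Default per-condition trial counts (config values, not claims about the
#: original designs, whose per-cell counts are not all printed).
DEFAULT_N_TRIALS = {"exp1": 100, "exp2": 24}

#: Exp-1 ground truth: transition logits in a +-0.75 box around the
#: sticky-internal fitted regime (P(int|int)=0.68, unlikely exits from
#: *none*), sigma around the fitted group mean of 20.
_EXP1_CENTER_LOGITS = (1.447, 0.0, 0.0, 1.099, -0.785, -1.210)
DEFAULT_EXP1_RANGES = {
    "transition_logits": tuple(
        (c - 0.75, c + 0.75) for c in _EXP1_CENTER_LOGITS
    ),
    "sigma": (10.0, 35.0),
}

#: Exp-2 ground truth on the probability scale, around the sticky-chain
#: simulation defaults (reliable emissions, persistent common chain).
DEFAULT_EXP2_RANGES = {
    "cp_0": (0.85, 0.95),
    "c_trans_00": (0.90, 0.98),
    "c_trans_10": (0.02, 0.10),
    "c_lik_00": (0.80, 0.95),
    "c_lik_10": (0.05, 0.20),
    "sp_0": (0.85, 0.95),
    "s_trans_00": (0.80, 0.90),
    "s_trans_10": (0.10, 0.20),
}


@dataclass(frozen=True)
class GroundTruth:
    """Known generating parameters for one synthetic participant."""

    experiment: str  # "exp1" or "exp2"
    params: object   # Exp1Params, or dict agency -> Exp2Params
    n_trials: int
    seed: int

    def __post_init__(self):
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated participants plus the provenance needed to regenerate them."""

    experiment: str
    members: list  # (participant_id, GroundTruth, ParticipantData)
    provenance: dict

    def __len__(self) -> int:
        return len(self.members)


def _check_range(name: str, lo: float, hi: float):
    if hi < lo:
        raise ValueError(f"empty range for {name!r}: ({lo}, {hi})")


def sample_ground_truth(
    experiment: str,
    ranges: dict | None = None,
    seed: int = 0,
    n_trials: int | None = None,
) -> GroundTruth:
    """Draw ground-truth parameters uniformly within per-parameter ranges.

    Degenerate ranges (min == max) yield deterministic parameters.  For the
    delay paradigm one parameter set is drawn per agency condition.
    """
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = DEFAULT_N_TRIALS[experiment]
    if experiment == "exp1":
        ranges = {**DEFAULT_EXP1_RANGES, **(ranges or {})}
        spec = ranges["transition_logits"]
        # accept one (lo, hi) pair for all six logits or one pair per logit
        pairs = [spec] * 6 if np.ndim(spec) == 1 else list(spec)
        logits = np.empty(6)
        for i, (lo, hi) in enumerate(pairs):
            _check_range("transition_logits", lo, hi)
            logits[i] = rng.uniform(lo, hi)
        lo, hi = ranges["sigma"]
        _check_range("sigma", lo, hi)
        sigma = float(rng.uniform(lo, hi))
        params = Exp1Params(transition_logits=logits, sigma=sigma)
    elif experiment == "exp2":
        ranges = {**DEFAULT_EXP2_RANGES, **(ranges or {})}
        params = {}
        for agency in AGENCIES:
            draw = {}
            for name in PARAM_NAMES:
                lo, hi = ranges[name]
                _check_range(name, lo, hi)
                draw[name] = float(rng.uniform(lo, hi))
            params[agency] = Exp2Params(**draw)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return GroundTruth(
        experiment=experiment, params=params, n_trials=n_trials, seed=seed
    )


def simulate_participant(
    gt: GroundTruth,
    config=None,
):
    """Binomial trial table for one participant at their ground truth.

    For every condition cell the model detection probability is computed at
    the ground-truth parameters and ``n_detections ~ Binomial(n_trials, p)``
    is drawn from a generator seeded by the ground truth's seed.
    """
    rng = np.random.default_rng(gt.seed)
    n = gt.n_trials
    if gt.experiment == "exp1":
        config = config or Exp1TrialConfig()
        counts = {}
        for tt in MOVEMENT_TRIAL_TYPES:
            p = detection_probability(tt, gt.params, config)
            counts[tt] = (n, int(rng.binomial(n, p)))
        return Exp1ParticipantData(counts=counts)
    config = config or DelayConfig()
    counts = {}
    for agency in AGENCIES:
        curve = detection_curve(gt.params[agency], config)
        for d, p in zip(DELAYS_MS, curve):
            counts[(agency, d)] = (n, int(rng.binomial(n, p)))
    return Exp2ParticipantData(counts=counts)


def simulate_cohort(
    experiment: str,
    n_participants: int,
    seed: int = 0,
    ranges: dict | None = None,
    n_trials: int | None = None,
    config=None,
) -> SyntheticCohort:
    """A cohort of independent synthetic participants.

    Per-participant seeds are spawned deterministically from ``seed``, so
    the same seed regenerates the identical cohort.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    member_seeds = rng.integers(0, 2**31 - 1, size=n_participants)
    members = []
    for i, s in enumerate(member_seeds):
        gt = sample_ground_truth(experiment, ranges, seed=int(s), n_trials=n_trials)
        data = simulate_participant(gt, config)
        members.append((f"sub-{i + 1:03d}", gt, data))
    provenance = {
        "experiment": experiment,
        "seed": seed,
        "n_participants": n_participants,
        "n_trials": n_trials or DEFAULT_N_TRIALS[experiment],
        "ranges": {k: list(v) for k, v in (ranges or {}).items()},
        "generator": "numpy.random.Generator(PCG64)",
        "numpy_version": np.__version__,
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()
    ).hexdigest()[:16]
    return SyntheticCohort(experiment=experiment, members=members, provenance=provenance)


def _exp1_true_values(gt: GroundTruth) -> dict[str, float]:
    tm = transition_matrix_from_logits(gt.params.transition_logits)
    out = {"sigma": gt.params.sigma}
    names = ("internal", "external", "none")
    for i, row in enumerate(names):
        for j, col in enumerate(names[:2]):
            out[f"p_{col}_given_{row}"] = float(tm[i, j])
    return out


def _exp1_fitted_values(params: Exp1Params) -> dict[str, float]:
    return _exp1_true_values(
        GroundTruth("exp1", params, n_trials=1, seed=0)
    )


def recovery_report(cohort: SyntheticCohort, fit_fn) -> pd.DataFrame:
    """Fit every synthetic participant and tabulate true vs. recovered values.

    ``fit_fn(ground_truth, data) -> dict[str, float]`` returns the recovered
    values keyed like the truth.  Individual fit failures are recorded per
    participant (NaN recovered values), not fatal.  The result carries a
    per-parameter summary (bias, RMSE, true-vs-recovered Pearson
    correlation) in ``df.attrs["summary"]``; correlations are NaN-flagged
    for cohorts of size 1.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = []
    for pid, gt, data in cohort.members:
        if cohort.experiment == "exp1":
            true = _exp1_true_values(gt)
        else:
            true = {
                f"{agency}.{name}": getattr(gt.params[agency], name)
                for agency in AGENCIES
                for name in PARAM_NAMES
            }
        try:
            recovered = fit_fn(gt, data)
            error = None
        except Exception as exc:  # individual failure is data, not fatal
            recovered = {k: float("nan") for k in true}
            error = repr(exc)
        for name, tv in true.items():
            rows.append(
                {
                    "participant_id": pid,
                    "parameter": name,
                    "true": tv,
                    "recovered": recovered.get(name, float("nan")),
                    "error": error,
                }
            )
    df = pd.DataFrame(rows)

    summaries = []
    for name, grp in df.groupby("parameter"):
        t = grp["true"].to_numpy()
        r = grp["recovered"].to_numpy()
        ok = np.isfinite(r)
        resid = r[ok] - t[ok]
        if ok.sum() > 1 and np.std(t[ok]) > 0 and np.std(r[ok]) > 0:
            corr = float(np.corrcoef(t[ok], r[ok])[0, 1])
        else:
            corr = float("nan")
        summaries.append(
            {
                "parameter": name,
                "n_fit": int(ok.sum()),
                "bias": float(resid.mean()) if ok.any() else float("nan"),
                "rmse": float(np.sqrt((resid**2).mean())) if ok.any() else float("nan"),
                "correlation": corr,
            }
        )
    df.attrs["summary"] = pd.DataFrame(summaries).set_index("parameter")
    return df
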