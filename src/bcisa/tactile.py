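"""Three-cause hidden Markov model of tactile probe detection during movement.

A stroking movement across a textured object elicits vibrotactile input on
the moving finger.  At each 10 ms timestep a hidden cause C in {internal,
external, none} explains the observed vibration frequency (model units
0-100): the *internal* cause predicts the frequency implied by the movement
policy (a truncated normal around the policy frequency, width sigma = motor
plus sensory noise), the *external* cause is maximally unspecific (uniform
over the frequency range), and *none* expects frequencies near zero.

A brief probe is inserted early in the trial; contact with the object
follows later.  Sensory attenuation falls out of causal inference: a probe
whose frequency is congruent with the movement prediction is absorbed by
the internal cause and missed, while an incongruent probe is credited to
the external cause and detected.  The model's detection probability is the
posterior probability of the external cause during the probe window.

Fitting minimizes, per participant, a Bernoulli KL divergence between the
empirical detection rate and the model's detection probability, summed over
the four movement trial types, plus endpoint penalties enforcing a *none*
state early in the trial and an *internal* state after object contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .chains import ChainSpec, ObservationSeries, PosteriorResult, run_forward_backward

__all__ = [
    "CAUSE_INTERNAL",
    "CAUSE_EXTERNAL",
    "CAUSE_NONE",
    "CAUSE_NAMES",
    "TRIAL_TYPES",
    "MOVEMENT_TRIAL_TYPES",
    "Exp1Params",
    "Exp1TrialConfig",
    "Exp1ParticipantData",
    "Exp1FitResult",
    "transition_matrix_from_logits",
    "emission_density",
    "build_observation_series",
    "detection_probability",
    "trial_posterior",
    "exp1_cost",
    "fit_participant_exp1",
]

# Fixed cause ordering for reproducible serialization.
CAUSE_INTERNAL, CAUSE_EXTERNAL, CAUSE_NONE = 0, 1, 2
CAUSE_NAMES = ("internal", "external", "none")

MOVEMENT_TRIAL_TYPES = (
    "congruent_low",
    "congruent_high",
    "incongruent_low",
    "incongruent_high",
)
TRIAL_TYPES = MOVEMENT_TRIAL_TYPES + ("no_probe",)

LOGIT_BOUND = 3.0  # free conditional-probability logits restricted to (-3, 3)
_CLIP = 1e-12


def transition_matrix_from_logits(logits: np.ndarray) -> np.ndarray:
    """Reconstruct the 3x3 row-stochastic transition matrix from 6 free logits.

    Each row holds two free entries (columns *internal* and *external*); the
    third (*none*) is recovered by normalization, i.e. row i is the softmax of
    ``[l_{i,int}, l_{i,ext}, 0]``.  The result is row-stochastic for every
    point in the bounded logit box.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.shape != (6,):
        raise ValueError("expected 6 transition logits")
    raw = np.column_stack([logits.reshape(3, 2), np.zeros(3)])
    raw = raw - raw.max(axis=1, keepdims=True)
    ex = np.exp(raw)
    return ex / ex.sum(axis=1, keepdims=True)


def _logits_from_transition(tm: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transition_matrix_from_logits` (none column as anchor)."""
    tm = np.asarray(tm, dtype=float)
    return np.log(tm[:, :2] / tm[:, 2:3]).reshape(-1)


@dataclass(frozen=True)
class Exp1Params:
    """Free parameters: six transition logits and the noise width sigma.

    ``transition_logits`` parameterize the cause-transition matrix (see
    :func:`transition_matrix_from_logits`); ``sigma`` is the width of the
    internal cause's frequency prediction, interpretable as the combination
    of motor and sensory noise, in observation units.
    """

    transition_logits: np.ndarray
    sigma: float

    def __post_init__(self):
        logits = np.asarray(self.transition_logits, dtype=float)
        object.__setattr__(self, "transition_logits", logits)
        if logits.shape != (6,):
            raise ValueError("expected 6 transition logits")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def transition_matrix(self) -> np.ndarray:
        return transition_matrix_from_logits(self.transition_logits)

    @classmethod
    def from_transition_matrix(cls, tm: np.ndarray, sigma: float) -> "Exp1Params":
        return cls(transition_logits=_logits_from_transition(tm), sigma=sigma)


#: Task-inspired default transitions: sticky internal cause, unlikely exits
#: from *none*; anchored to the fitted group means where reported
#: (P(int|int)=0.68, P(int|none)=0.26, P(ext|none)=0.17).
DEFAULT_TRANSITION = np.array(
    [
        [0.68, 0.16, 0.16],
        [0.20, 0.60, 0.20],
        [0.26, 0.17, 0.57],
    ]
)

#: Fitted group-mean noise width.
DEFAULT_SIGMA = 20.61


def default_exp1_params() -> Exp1Params:
    return Exp1Params.from_transition_matrix(DEFAULT_TRANSITION, DEFAULT_SIGMA)


@dataclass(frozen=True)
class Exp1TrialConfig:
    """Structural (non-fitted) constants of an Experiment-1 trial.

    Timesteps are 1-based and 10 ms each.  ``probe_window`` and
    ``endpoint_times`` are inclusive; ``freq_units`` maps the physical
    40/240 Hz probe/object frequencies onto model units in [0, 100].
    """

    chain_length: int = 50
    probe_window: tuple[int, int] = (10, 15)
    contact_onset: int = 25
    freq_low: float = 30.0
    freq_high: float = 70.0
    none_width: float = 5.0
    obs_range: tuple[float, float] = (0.0, 100.0)
    endpoint_times: tuple[int, int] = (5, 40)  # (t_none, t_internal)
    endpoint_weight: float = 1.0

    def __post_init__(self):
        lo, hi = self.probe_window
        t_none, t_int = self.endpoint_times
        if not (1 <= lo <= hi <= self.chain_length):
            raise ValueError("probe_window must lie within [1, chain_length]")
        if not (1 <= t_none <= self.chain_length and 1 <= t_int <= self.chain_length):
            raise ValueError("endpoint_times must lie within [1, chain_length]")
        if not self.contact_onset > hi:
            raise ValueError("contact must begin after the probe window ends")
        if not self.none_width > 0:
            raise ValueError("none_width must be positive")
        if self.endpoint_weight < 0:
            raise ValueError("endpoint_weight must be nonnegative")

    def freq(self, level: str) -> float:
        if level == "low":
            return self.freq_low
        if level == "high":
            return self.freq_high
        raise ValueError(f"unknown frequency level {level!r}")


def _truncnorm_pdf(x: float, mu: float, sd: float, lo: float, hi: float) -> float:
    z = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    return math.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi) * z)


def emission_density(
    cause: int,
    frequency: float,
    params: Exp1Params,
    config: Exp1TrialConfig = Exp1TrialConfig(),
    policy_freq: float = 0.0,
) -> float:
    """Likelihood P(frequency | cause) under the three-cause observation model.

    *none*: truncated normal at 0 (width ``config.none_width``); *external*:
    uniform over the observation range; *internal*: truncated normal at the
    movement-predicted ``policy_freq`` (width ``params.sigma``).  Truncations
    are renormalized over the observation range.
    """
    lo, hi = config.obs_range
    if not lo <= frequency <= hi:
        raise ValueError(f"frequency {frequency} outside observation range")
    if cause == CAUSE_EXTERNAL:
        return 1.0 / (hi - lo)
    if cause == CAUSE_NONE:
        return _truncnorm_pdf(frequency, lo, config.none_width, lo, hi)
    if cause == CAUSE_INTERNAL:
        if not params.sigma > 0:
            raise ValueError("sigma must be positive")
        return _truncnorm_pdf(frequency, policy_freq, params.sigma, lo, hi)
    raise ValueError(f"unknown cause index {cause}")


def build_observation_series(
    trial_type: str, config: Exp1TrialConfig = Exp1TrialConfig()
) -> tuple[ObservationSeries, float]:
    """Encode a trial type as a frequency time series plus the policy frequency.

    The series is zero at baseline, holds the probe frequency over the probe
    window, returns to zero, then holds the object frequency from contact
    onset to the end of the trial.  The policy frequency (the movement's
    predicted frequency) is the object frequency.  ``no_probe`` omits the
    probe and defaults the policy to the low-frequency object.
    """
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {trial_type!r}")
    T = config.chain_length
    values = np.zeros(T)
    if trial_type == "no_probe":
        probe_level = None
        object_level = "low"
    else:
        congruent = trial_type.startswith("congruent")
        probe_level = trial_type.rsplit("_", 1)[1]
        object_level = probe_level if congruent else ("high" if probe_level == "low" else "low")
    p0, p1 = config.probe_window
    if probe_level is not None:
        values[p0 - 1 : p1] = config.freq(probe_level)
    values[config.contact_onset - 1 :] = config.freq(object_level)
    return ObservationSeries(values=values), config.freq(object_level)


def _chain_spec(
    params: Exp1Params, config: Exp1TrialConfig, policy_freq: float
) -> ChainSpec:
    # Priors on the first hidden state are held uninformative (1/3 each);
    # they were found not to influence detection behavior.
    lo, hi = config.obs_range
    sigma = params.sigma
    none_w = config.none_width
    uniform = 1.0 / (hi - lo)
    cache: dict[tuple[int, float], float] = {}

    def emission(state: int, value: float) -> float:
        # trial series hold at most three distinct frequencies; memoize
        key = (state, value)
        out = cache.get(key)
        if out is None:
            if state == CAUSE_EXTERNAL:
                out = uniform
            elif state == CAUSE_NONE:
                out = _truncnorm_pdf(value, lo, none_w, lo, hi)
            else:
                out = _truncnorm_pdf(value, policy_freq, sigma, lo, hi)
            cache[key] = out
        return out

    return ChainSpec(
        n_states=3,
        length=config.chain_length,
        prior=np.full(3, 1.0 / 3.0),
        transition=params.transition_matrix,
        emission=emission,
    )


def trial_posterior(
    trial_type: str,
    params: Exp1Params,
    config: Exp1TrialConfig = Exp1TrialConfig(),
) -> PosteriorResult:
    """Smoothed cause posterior over the whole trial timeline."""
    obs, policy_freq = build_observation_series(trial_type, config)
    spec = _chain_spec(params, config, policy_freq)
    return run_forward_backward(spec, obs)


# --- fast path ------------------------------------------------------------
# Fitting evaluates the cost thousands of times; the generic engine's
# callback/validation overhead dominates at T=50 x 3 states.  This scalar
# forward-backward computes the same smoothed marginals (tested equal to
# trial_posterior to 1e-12) an order of magnitude faster.

_series_cache: dict[tuple, tuple] = {}


def _trial_values(trial_type: str, config: Exp1TrialConfig):
    key = (trial_type, config)
    hit = _series_cache.get(key)
    if hit is None:
        obs, policy_freq = build_observation_series(trial_type, config)
        hit = (tuple(float(v) for v in obs.values), policy_freq)
        _series_cache[key] = hit
    return hit


def _fb3_marginals(A: np.ndarray, rows: list) -> list:
    """Smoothed marginals for a uniform-prior 3-state chain; scalar arithmetic."""
    a00, a01, a02 = A[0]
    a10, a11, a12 = A[1]
    a20, a21, a22 = A[2]
    T = len(rows)
    e0, e1, e2 = rows[0]
    f0, f1, f2 = e0, e1, e2  # uniform prior cancels in the normalization
    z = f0 + f1 + f2
    f0 /= z
    f1 /= z
    f2 /= z
    fwd = [(f0, f1, f2)]
    for t in range(1, T):
        e0, e1, e2 = rows[t]
        g0 = (f0 * a00 + f1 * a10 + f2 * a20) * e0
        g1 = (f0 * a01 + f1 * a11 + f2 * a21) * e1
        g2 = (f0 * a02 + f1 * a12 + f2 * a22) * e2
        z = g0 + g1 + g2
        f0, f1, f2 = g0 / z, g1 / z, g2 / z
        fwd.append((f0, f1, f2))
    b0 = b1 = b2 = 1.0
    out = [None] * T
    m0, m1, m2 = fwd[T - 1]
    out[T - 1] = (m0, m1, m2)
    for t in range(T - 2, -1, -1):
        e0, e1, e2 = rows[t + 1]
        c0, c1, c2 = e0 * b0, e1 * b1, e2 * b2
        b0 = a00 * c0 + a01 * c1 + a02 * c2
        b1 = a10 * c0 + a11 * c1 + a12 * c2
        b2 = a20 * c0 + a21 * c1 + a22 * c2
        z = b0 + b1 + b2
        b0 /= z
        b1 /= z
        b2 /= z
        f0, f1, f2 = fwd[t]
        m0, m1, m2 = f0 * b0, f1 * b1, f2 * b2
        z = m0 + m1 + m2
        out[t] = (m0 / z, m1 / z, m2 / z)
    return out


def _trial_marginals(
    trial_type: str, params: Exp1Params, config: Exp1TrialConfig
) -> list:
    values, policy_freq = _trial_values(trial_type, config)
    lo, hi = config.obs_range
    uniform = 1.0 / (hi - lo)
    emis = {}
    for v in set(values):
        emis[v] = (
            _truncnorm_pdf(v, policy_freq, params.sigma, lo, hi),
            uniform,
            _truncnorm_pdf(v, lo, config.none_width, lo, hi),
        )
    rows = [emis[v] for v in values]
    return _fb3_marginals(params.transition_matrix, rows)


def detection_probability(
    trial_type: str,
    params: Exp1Params,
    config: Exp1TrialConfig = Exp1TrialConfig(),
) -> float:
    """Model probability of a probe-detection response for one trial type.

    The probe is detected when the external cause wins the inference; the
    detection probability is read out as the mean posterior P(C=external)
    over the probe window.
    """
    marg = _trial_marginals(trial_type, params, config)
    p0, p1 = config.probe_window
    window = marg[p0 - 1 : p1]
    return sum(m[CAUSE_EXTERNAL] for m in window) / len(window)


@dataclass(frozen=True)
class Exp1ParticipantData:
    """Detection counts per movement trial type.

    ``counts`` maps each of the four movement trial types to
    ``(n_trials, n_detections)``.
    """

    counts: dict[str, tuple[int, int]]

    def __post_init__(self):
        for tt in MOVEMENT_TRIAL_TYPES:
            if tt not in self.counts:
                raise ValueError(f"missing trial type {tt!r}")
            n, k = self.counts[tt]
            if n <= 0 or k < 0 or k > n:
                raise ValueError(f"invalid counts for {tt!r}: n={n}, k={k}")

    def rate(self, trial_type: str) -> float:
        n, k = self.counts[trial_type]
        return k / n


def _bernoulli_kl(q: float, p: float) -> float:
    """KL(Bern(q) || Bern(p)) with the 0 log 0 = 0 convention; p clipped."""
    p = min(max(p, _CLIP), 1.0 - _CLIP)
    out = 0.0
    if q > 0.0:
        out += q * math.log(q / p)
    if q < 1.0:
        out += (1.0 - q) * math.log((1.0 - q) / (1.0 - p))
    return out


def exp1_cost(
    params: Exp1Params,
    data: Exp1ParticipantData,
    config: Exp1TrialConfig = Exp1TrialConfig(),
) -> float:
    """Fitting cost: summed Bernoulli KL terms plus endpoint penalties.

    For each movement trial type, the KL divergence between the empirical
    detection rate q and the model's detection probability is accumulated.
    The endpoint term ``lambda * [-log P(M_{t_none}=none)
    - log P(M_{t_int}=internal)]`` is evaluated on the congruent-trial
    posterior (averaged over the two congruent types), enforcing certainty
    about *none* before stimulation and *internal* after object contact.
    """
    cost = 0.0
    congruent_penalty = 0.0
    n_congruent = 0
    t_none, t_int = config.endpoint_times
    p0, p1 = config.probe_window
    for tt in MOVEMENT_TRIAL_TYPES:
        marg = _trial_marginals(tt, params, config)
        window = marg[p0 - 1 : p1]
        p_ext = sum(m[CAUSE_EXTERNAL] for m in window) / len(window)
        cost += _bernoulli_kl(data.rate(tt), p_ext)
        if tt.startswith("congruent") and config.endpoint_weight > 0:
            p_none = max(marg[t_none - 1][CAUSE_NONE], _CLIP)
            p_internal = max(marg[t_int - 1][CAUSE_INTERNAL], _CLIP)
            congruent_penalty += -math.log(p_none) - math.log(p_internal)
            n_congruent += 1
    if n_congruent:
        cost += config.endpoint_weight * congruent_penalty / n_congruent
    return cost


@dataclass(frozen=True)
class Exp1FitResult:
    """Outcome of a multi-start Powell fit for one participant."""

    best_params: Exp1Params
    best_cost: float
    n_function_evals: int
    restart_costs: np.ndarray
    seed: int

    def __post_init__(self):
        if abs(self.best_cost - float(np.min(self.restart_costs))) > 1e-9:
            raise ValueError("best_cost must be the minimum restart cost")


# sigma is optimized through a log transform to keep it positive.
_LOG_SIGMA_BOUNDS = (math.log(1.0), math.log(100.0))
_LOG_SIGMA_START = (math.log(5.0), math.log(40.0))


def fit_participant_exp1(
    data: Exp1ParticipantData,
    config: Exp1TrialConfig = Exp1TrialConfig(),
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-12,
    maxfev: int = 4000,
) -> Exp1FitResult:
    """Fit the seven free parameters to one participant by multi-start Powell.

    Transition logits are bounded to (-3, 3); sigma is fitted on the log
    scale.  ``n_restarts`` starts are drawn uniformly within the bounds from
    the seeded generator and the restart with the lowest cost wins.
    """
    rng = np.random.default_rng(seed)
    bounds = [(-LOGIT_BOUND, LOGIT_BOUND)] * 6 + [_LOG_SIGMA_BOUNDS]

    def objective(x: np.ndarray) -> float:
        params = Exp1Params(transition_logits=x[:6], sigma=math.exp(x[6]))
        return exp1_cost(params, data, config)

    best = None
    restart_costs = []
    n_evals = 0
    failures = []
    for _ in range(n_restarts):
        x0 = np.append(
            rng.uniform(-LOGIT_BOUND, LOGIT_BOUND, size=6),
            rng.uniform(*_LOG_SIGMA_START),
        )
        res = minimize(
            objective,
            x0,
            method="Powell",
            bounds=bounds,
            tol=tol,
            options={"maxfev": maxfev},
        )
        n_evals += res.nfev
        if not np.isfinite(res.fun):
            failures.append(res.message)
            restart_costs.append(np.inf)
            continue
        restart_costs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            "all restarts failed: " + "; ".join(map(str, failures))
        )
    params = Exp1Params(
        transition_logits=best.x[:6], sigma=math.exp(best.x[6])
    )
    return Exp1FitResult(
        best_params=params,
        best_cost=float(best.fun),
        n_function_evals=int(n_evals),
        restart_costs=np.array(restart_costs),
        seed=seed,
    )
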