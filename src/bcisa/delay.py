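"""Common-cause vs. separate-cause models of visuo-proprioceptive delay detection.

A lever movement (neutral -> right -> neutral) generates a proprioceptive
binary stream; a video of the movement generates a visual binary stream,
optionally delayed by 0-417 ms.  Two competing causal structures explain
the pair: a *common-cause* model in which one hidden binary chain emits
both streams at every timestep, and a *separate-cause* model with one
independent hidden chain per stream.  Both structures share an emission
table; the chain timestep is one deci-second and chains are 80 steps long.

Per trial, the structure posterior P(W=separate | streams) is the model's
probability of reporting a delay: small delays are absorbed by the common
cause (the delay goes unnoticed, the sensory-attenuation signature), while
large delays make the separate-cause structure win.  Fitting matches this
posterior to empirical detection rates per delay level with a Bernoulli KL
cost; active- and passive-movement data are fitted separately, and the
fitted detection curves are summarized by a two-parameter logistic
psychometric function whose threshold is the point of subjective equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import expit, logit

from .chains import ChainSpec, ObservationSeries, run_forward_backward

__all__ = [
    "DELAYS_MS",
    "AGENCIES",
    "DelayConfig",
    "Exp2Params",
    "Exp2ParticipantData",
    "Exp2FitResult",
    "PsychometricFit",
    "shift_steps_for_delay",
    "build_delay_observation_pair",
    "common_cause_log_evidence",
    "separate_cause_log_evidence",
    "posterior_separate",
    "exp2_cost",
    "fit_participant_exp2",
    "fit_psychometric",
    "default_exp2_params",
    "detection_curve",
]

#: Experimental delay levels between movement and video playback.
DELAYS_MS = (0, 83, 167, 250, 333, 417)
AGENCIES = ("active", "passive")

#: ~41.7 ms of delay per chain timestep maps the six delays onto
#: shift steps {0, 2, 4, 6, 8, 10}.
MS_PER_SHIFT_STEP = 41.7

_CLIP = 1e-12

PARAM_NAMES = (
    "cp_0",        # common chain: prior on state 0 (neutral)
    "c_trans_00",  # common chain: P(state 0 -> 0)
    "c_trans_10",  # common chain: P(state 1 -> 0)
    "c_lik_00",    # shared emission: P(observe 0 | state 0)
    "c_lik_10",    # shared emission: P(observe 0 | state 1)
    "sp_0",        # separate chains: prior on state 0
    "s_trans_00",  # separate chains: P(0 -> 0)
    "s_trans_10",  # separate chains: P(1 -> 0)
)


def shift_steps_for_delay(delay_ms: float) -> int:
    """Timestep shift between the visual and proprioceptive streams."""
    if delay_ms < 0:
        raise ValueError("delay must be nonnegative")
    return int(round(delay_ms / MS_PER_SHIFT_STEP))


@dataclass(frozen=True)
class DelayConfig:
    """Structural constants of an Experiment-2 trial.

    The movement step pattern (0 before ``move_on``, 1 until ``move_off``,
    0 after) is scaffolding around the neutral -> right -> neutral movement;
    both the undelayed and maximally delayed patterns fit inside the chain.
    """

    chain_length: int = 80
    move_on: int = 20   # 0-based timestep at which the lever reaches "right"
    move_off: int = 50  # 0-based timestep at which it returns to neutral
    ms_per_step: float = MS_PER_SHIFT_STEP

    def __post_init__(self):
        if not 0 < self.move_on < self.move_off < self.chain_length:
            raise ValueError("movement pattern must lie inside the chain")


@dataclass(frozen=True)
class Exp2Params:
    """Eight free probabilities, stored on the probability scale.

    The two separate-cause chains (visual, proprioceptive) share
    ``sp_0``/``s_trans_*``; the emission table ``c_lik_*`` is shared by both
    structures and both sensory channels.  The structure prior
    P(W=common) is fixed at 0.5.
    """

    cp_0: float
    c_trans_00: float
    c_trans_10: float
    c_lik_00: float
    c_lik_10: float
    sp_0: float
    s_trans_00: float
    s_trans_10: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0, 1)")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def to_logits(self) -> np.ndarray:
        return logit(self.to_array())

    @classmethod
    def from_array(cls, values: np.ndarray) -> "Exp2Params":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "Exp2Params":
        return cls.from_array(expit(np.asarray(logits, dtype=float)))

    @property
    def emission_table(self) -> np.ndarray:
        """P(observation | state): rows states {0, 1}, columns observations {0, 1}."""
        return np.array(
            [[self.c_lik_00, 1.0 - self.c_lik_00],
             [self.c_lik_10, 1.0 - self.c_lik_10]]
        )


def default_exp2_params() -> Exp2Params:
    """Plausible sticky-chain regime for qualitative simulation.

    Reliable emissions, a sticky common chain and a less persistent pair of
    separate chains reproduce the delay-crossover pattern: the common cause
    wins for synchronous streams and loses once the streams are shifted far
    enough that its single chain cannot explain both.
    """
    return Exp2Params(
        cp_0=0.9,
        c_trans_00=0.95,
        c_trans_10=0.05,
        c_lik_00=0.9,
        c_lik_10=0.1,
        sp_0=0.9,
        s_trans_00=0.85,
        s_trans_10=0.15,
    )


def build_delay_observation_pair(
    delay_ms: float, config: DelayConfig = DelayConfig()
) -> tuple[ObservationSeries, ObservationSeries]:
    """Binary (visual, proprioceptive) streams for one experimental delay.

    The proprioceptive stream carries the movement step pattern; the visual
    stream is the identical pattern shifted later by the delay's timestep
    count.
    """
    shift = shift_steps_for_delay(delay_ms)
    T = config.chain_length
    if config.move_off + shift >= T:
        raise ValueError(
            f"delay of {shift} steps pushes the pattern past the chain end"
        )
    proprio = np.zeros(T, dtype=int)
    proprio[config.move_on : config.move_off] = 1
    visual = np.zeros(T, dtype=int)
    visual[config.move_on + shift : config.move_off + shift] = 1
    return ObservationSeries(values=visual), ObservationSeries(values=proprio)


def _chain_log_evidence(
    prior0: float,
    trans00: float,
    trans10: float,
    emission_rows,  # (T, ) sequence of per-timestep likelihood vectors over states
) -> float:
    """Scaled forward pass returning the log evidence for a 2-state chain.

    Scalar arithmetic: the chains here are tiny (2 states, T <= 80) and the
    forward recursion is latency-bound, not flop-bound.
    """
    a00, a01 = trans00, 1.0 - trans00
    a10, a11 = trans10, 1.0 - trans10
    rows = emission_rows.tolist()
    e0, e1 = rows[0]
    f0 = prior0 * e0
    f1 = (1.0 - prior0) * e1
    z = f0 + f1
    log_norm = math.log(z)
    f0 /= z
    f1 /= z
    for e0, e1 in rows[1:]:
        g0 = (f0 * a00 + f1 * a10) * e0
        g1 = (f0 * a01 + f1 * a11) * e1
        z = g0 + g1
        log_norm += math.log(z)
        f0 = g0 / z
        f1 = g1 / z
    return log_norm


def _emission_rows_single(table: np.ndarray, values: np.ndarray) -> np.ndarray:
    return table[:, values].T  # (T, 2)


def common_cause_log_evidence(
    vis: ObservationSeries,
    prop: ObservationSeries,
    params: Exp2Params,
) -> float:
    """Log marginal likelihood of both streams under one shared hidden chain.

    Each timestep emits the visual and proprioceptive observations
    independently given the hidden state, so the per-timestep emission is
    the product of the two channel likelihoods.
    """
    if len(vis) != len(prop):
        raise ValueError("visual and proprioceptive streams must align")
    table = params.emission_table
    v = np.asarray(vis.values, dtype=int)
    p = np.asarray(prop.values, dtype=int)
    rows = _emission_rows_single(table, v) * _emission_rows_single(table, p)
    return _chain_log_evidence(params.cp_0, params.c_trans_00, params.c_trans_10, rows)


def separate_cause_log_evidence(
    vis: ObservationSeries,
    prop: ObservationSeries,
    params: Exp2Params,
) -> float:
    """Log marginal likelihood under two independent chains, one per stream."""
    if len(vis) != len(prop):
        raise ValueError("visual and proprioceptive streams must align")
    table = params.emission_table
    total = 0.0
    for stream in (vis, prop):
        rows = _emission_rows_single(table, np.asarray(stream.values, dtype=int))
        total += _chain_log_evidence(
            params.sp_0, params.s_trans_00, params.s_trans_10, rows
        )
    return total


def chain_spec_common(params: Exp2Params, length: int) -> ChainSpec:
    """Common-cause structure as a :class:`ChainSpec` over paired observations.

    Observation values are (visual, proprioceptive) tuples; useful for
    cross-checking the specialized evidence computation against the generic
    engine and the enumeration oracle.
    """
    table = params.emission_table

    def emission(state: int, value) -> float:
        v, p = value
        return float(table[state, v] * table[state, p])

    return ChainSpec(
        n_states=2,
        length=length,
        prior=np.array([params.cp_0, 1.0 - params.cp_0]),
        transition=np.array(
            [[params.c_trans_00, 1.0 - params.c_trans_00],
             [params.c_trans_10, 1.0 - params.c_trans_10]]
        ),
        emission=emission,
    )


def chain_spec_separate(params: Exp2Params, length: int) -> ChainSpec:
    """One separate-cause chain over a single binary stream."""
    table = params.emission_table
    return ChainSpec(
        n_states=2,
        length=length,
        prior=np.array([params.sp_0, 1.0 - params.sp_0]),
        transition=np.array(
            [[params.s_trans_00, 1.0 - params.s_trans_00],
             [params.s_trans_10, 1.0 - params.s_trans_10]]
        ),
        emission=lambda s, v: float(table[s, int(v)]),
    )


def posterior_separate(
    vis: ObservationSeries,
    prop: ObservationSeries,
    params: Exp2Params,
    prior_separate: float = 0.5,
) -> float:
    """Structure posterior P(W=separate | streams); the delay-detection probability.

    Computed as a logistic of the log-evidence difference, which is the
    numerically stable form of the two-model Bayes posterior.
    """
    log_sc = separate_cause_log_evidence(vis, prop, params)
    log_cc = common_cause_log_evidence(vis, prop, params)
    return float(expit(log_sc - log_cc + logit(prior_separate)))


def detection_curve(
    params: Exp2Params,
    config: DelayConfig = DelayConfig(),
    delays_ms=DELAYS_MS,
) -> np.ndarray:
    """Model delay-detection probability at each delay level."""
    out = []
    for d in delays_ms:
        vis, prop = build_delay_observation_pair(d, config)
        out.append(posterior_separate(vis, prop, params))
    return np.array(out)


@dataclass(frozen=True)
class Exp2ParticipantData:
    """Detection counts per (agency, delay) cell.

    ``counts`` maps (agency, delay_ms) to (n_trials, n_detections); all six
    delay levels must be present for any agency condition that is present.
    """

    counts: dict[tuple[str, int], tuple[int, int]]

    def __post_init__(self):
        agencies = {a for a, _ in self.counts}
        for a in agencies:
            if a not in AGENCIES:
                raise ValueError(f"unknown agency {a!r}")
            for d in DELAYS_MS:
                if (a, d) not in self.counts:
                    raise ValueError(f"missing cell ({a!r}, {d})")
                n, k = self.counts[(a, d)]
                if n <= 0 or k < 0 or k > n:
                    raise ValueError(f"invalid counts in cell ({a!r}, {d})")

    def rate(self, agency: str, delay_ms: int) -> float:
        n, k = self.counts[(agency, delay_ms)]
        return k / n

    def has_agency(self, agency: str) -> bool:
        return any(a == agency for a, _ in self.counts)


def exp2_cost(
    params: Exp2Params,
    data: Exp2ParticipantData,
    agency: str,
    config: DelayConfig = DelayConfig(),
) -> float:
    """Summed Bernoulli KL between model and empirical detection per delay.

    Each delay level contributes
    ``p_sep log(p_sep/q) + (1-p_sep) log((1-p_sep)/(1-q))`` with ``p_sep``
    the structure posterior for that delay's observation pair and the
    empirical rate ``q`` clipped away from 0 and 1.
    """
    if not data.has_agency(agency):
        raise ValueError(f"no data for agency {agency!r}")
    cost = 0.0
    for d in DELAYS_MS:
        vis, prop = build_delay_observation_pair(d, config)
        p_sep = posterior_separate(vis, prop, params)
        q = min(max(data.rate(agency, d), _CLIP), 1.0 - _CLIP)
        if p_sep > 0.0:
            cost += p_sep * math.log(p_sep / q)
        if p_sep < 1.0:
            cost += (1.0 - p_sep) * math.log((1.0 - p_sep) / (1.0 - q))
    return cost


def canonicalize(params: Exp2Params) -> Exp2Params:
    """Resolve the hidden-state relabeling symmetry.

    Jointly swapping state labels 0 <-> 1 in the common and separate chains
    (priors complemented, transition rows exchanged and complemented, the
    shared emission table's rows exchanged) leaves both structures' log
    evidences exactly invariant, so fitted optima come in symmetric pairs.
    The canonical representative has state 0 preferentially emitting
    observation 0 (``c_lik_00 >= c_lik_10``), matching the neutral-position
    reading of state 0.
    """
    if params.c_lik_00 >= params.c_lik_10:
        return params
    return Exp2Params(
        cp_0=1.0 - params.cp_0,
        c_trans_00=1.0 - params.c_trans_10,
        c_trans_10=1.0 - params.c_trans_00,
        c_lik_00=params.c_lik_10,
        c_lik_10=params.c_lik_00,
        sp_0=1.0 - params.sp_0,
        s_trans_00=1.0 - params.s_trans_10,
        s_trans_10=1.0 - params.s_trans_00,
    )


@dataclass(frozen=True)
class Exp2FitResult:
    """Outcome of a multi-start Powell fit for one participant and agency."""

    best_params: Exp2Params
    best_cost: float
    agency: str
    n_function_evals: int
    restart_costs: np.ndarray
    seed: int


#: Hard logit bounds keep fitted probabilities away from exact 0/1;
#: restart logits are drawn from (-1, 1).
LOGIT_HARD_BOUND = 5.0
LOGIT_START_RANGE = (-1.0, 1.0)


def fit_participant_exp2(
    data: Exp2ParticipantData,
    agency: str,
    seed: int = 0,
    config: DelayConfig = DelayConfig(),
    n_restarts: int = 10,
    tol: float = 1e-8,
    maxfev: int = 4000,
) -> Exp2FitResult:
    """Fit the eight free logits to one agency condition by multi-start Powell."""
    rng = np.random.default_rng(seed)
    bounds = [(-LOGIT_HARD_BOUND, LOGIT_HARD_BOUND)] * 8

    # the six observation pairs are fixed; precompute them once
    pairs = [build_delay_observation_pair(d, config) for d in DELAYS_MS]
    qs = np.array(
        [min(max(data.rate(agency, d), _CLIP), 1.0 - _CLIP) for d in DELAYS_MS]
    )

    def objective(x: np.ndarray) -> float:
        params = Exp2Params.from_logits(x)
        cost = 0.0
        for (vis, prop), q in zip(pairs, qs):
            p_sep = posterior_separate(vis, prop, params)
            if p_sep > 0.0:
                cost += p_sep * math.log(p_sep / q)
            if p_sep < 1.0:
                cost += (1.0 - p_sep) * math.log((1.0 - p_sep) / (1.0 - q))
        return cost

    best = None
    restart_costs = []
    n_evals = 0
    failures = []
    for _ in range(n_restarts):
        x0 = rng.uniform(*LOGIT_START_RANGE, size=8)
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
        raise RuntimeError("all restarts failed: " + "; ".join(map(str, failures)))
    return Exp2FitResult(
        best_params=canonicalize(Exp2Params.from_logits(best.x)),
        best_cost=float(best.fun),
        agency=agency,
        n_function_evals=int(n_evals),
        restart_costs=np.array(restart_costs),
        seed=seed,
    )


@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter logistic psychometric function.

    ``threshold`` is the point of subjective equality (the delay at which
    the detection probability crosses 0.5), in the units of the delays
    passed to :func:`fit_psychometric`; ``slope`` is the logistic steepness;
    ``goodness`` is the residual sum of squares.  ``degenerate`` flags flat
    or non-identifiable data.
    """

    threshold: float
    slope: float
    goodness: float
    degenerate: bool = False


def fit_psychometric(detect_probs, delays) -> PsychometricFit:
    """Least-squares fit of ``psi(d) = 1 / (1 + exp(-slope (d - threshold)))``.

    Never raises on poorly conditioned data: flat inputs return a fit with
    the ``degenerate`` flag set instead.
    """
    y = np.asarray(detect_probs, dtype=float)
    d = np.asarray(delays, dtype=float)
    if y.shape != d.shape or len(np.unique(d)) < 4:
        raise ValueError("need matching arrays with at least 4 distinct delays")

    span = d.max() - d.min()
    if np.ptp(y) < 1e-6:
        return PsychometricFit(
            threshold=float(d.mean()), slope=0.0,
            goodness=float(np.sum((y - y.mean()) ** 2)), degenerate=True,
        )

    def residuals(theta):
        thr, log_slope = theta
        return expit(math.exp(log_slope) * (d - thr)) - y

    # start threshold where the data crosses 0.5; moderate slope
    crossing = d[np.argmin(np.abs(y - 0.5))]
    best = None
    for slope0 in (1.0 / max(span / 4.0, 1e-6), 4.0 / max(span, 1e-6), 1.0):
        res = least_squares(
            residuals, x0=[crossing, math.log(slope0)], method="lm", xtol=1e-14,
            ftol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    thr, log_slope = best.x
    rss = float(2.0 * best.cost)
    degenerate = not (d.min() - span <= thr <= d.max() + span)
    return PsychometricFit(
        threshold=float(thr),
        slope=float(math.exp(log_slope)),
        goodness=rss,
        degenerate=degenerate,
    )
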