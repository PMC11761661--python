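"""Exact sum-product inference on chain-structured hidden Markov models.

On a chain, sum-product message passing reduces to the classical
forward-backward algorithm, which yields exact smoothed marginals
``P(M_t | all observations)`` and the exact log marginal likelihood
(log evidence) of an observation series.  The engine is agnostic about
the observation space: emissions are supplied as a callback evaluated
lazily per (state, observation), so discrete probability tables and
continuous densities are handled identically.

Numerical strategy: forward messages are normalized at every timestep and
the log normalizers are accumulated, recovering the evidence without
underflow for chains far longer than the T <= 80 used by the behavioral
models here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ChainSpec",
    "ObservationSeries",
    "PosteriorResult",
    "ImpossibleObservationError",
    "run_forward_backward",
    "enumerate_oracle",
]

_PROB_ATOL = 1e-12


class ImpossibleObservationError(ValueError):
    """No hidden state assigns nonzero likelihood to the observation.

    Raised when the emission column at some timestep is identically zero,
    which makes the observation series impossible under the chain.
    """

    def __init__(self, timestep: int):
        self.timestep = timestep
        super().__init__(
            f"observation at timestep {timestep} has zero likelihood "
            f"under every hidden state"
        )


@dataclass(frozen=True)
class ChainSpec:
    """A chain HMM: hidden-state count, length, prior, transitions, emission.

    Parameters
    ----------
    n_states
        Number of values each hidden node can take.
    length
        Number of timesteps T.
    prior
        Probability vector over states at t=1.
    transition
        Row-stochastic matrix; entry (i, j) = P(state_{t+1}=j | state_t=i).
    emission
        Callable ``emission(state_index, observation_value) -> density``;
        must return finite nonnegative values.
    """

    n_states: int
    length: int
    prior: np.ndarray
    transition: np.ndarray
    emission: Callable[[int, object], float]

    def __post_init__(self):
        prior = np.asarray(self.prior, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "transition", transition)
        if self.n_states < 1 or self.length < 1:
            raise ValueError("n_states and length must be positive")
        if prior.shape != (self.n_states,):
            raise ValueError("prior must have one entry per state")
        if transition.shape != (self.n_states, self.n_states):
            raise ValueError("transition must be n_states x n_states")
        if np.any(prior < -_PROB_ATOL) or np.any(prior > 1 + _PROB_ATOL):
            raise ValueError("prior entries must lie in [0, 1]")
        if np.any(transition < -_PROB_ATOL) or np.any(transition > 1 + _PROB_ATOL):
            raise ValueError("transition entries must lie in [0, 1]")
        if abs(prior.sum() - 1.0) > _PROB_ATOL:
            raise ValueError("prior must sum to 1")
        if np.max(np.abs(transition.sum(axis=1) - 1.0)) > _PROB_ATOL:
            raise ValueError("every transition row must sum to 1")


@dataclass(frozen=True)
class ObservationSeries:
    """One observation per timestep, with per-timestep missingness.

    A missing observation contributes a constant emission factor of 1,
    i.e. it is uninformative about the hidden state.
    """

    values: Sequence
    missing: Sequence[bool] | None = None

    def __post_init__(self):
        if self.missing is not None and len(self.missing) != len(self.values):
            raise ValueError("missing flags must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    def is_missing(self, t: int) -> bool:
        return bool(self.missing[t]) if self.missing is not None else False


@dataclass(frozen=True)
class PosteriorResult:
    """Smoothed marginals and log evidence of an observation series."""

    marginals: np.ndarray  # shape (T, n_states), rows sum to 1
    log_evidence: float


def _emission_matrix(spec: ChainSpec, obs: ObservationSeries) -> np.ndarray:
    """Evaluate the emission callback into a (T, n_states) likelihood matrix."""
    if len(obs) != spec.length:
        raise ValueError(
            f"observation series length {len(obs)} != chain length {spec.length}"
        )
    E = np.empty((spec.length, spec.n_states))
    for t in range(spec.length):
        if obs.is_missing(t):
            E[t, :] = 1.0
            continue
        value = obs.values[t]
        for s in range(spec.n_states):
            e = float(spec.emission(s, value))
            if not np.isfinite(e) or e < 0.0:
                raise ValueError(
                    f"emission({s}, {value!r}) returned invalid value {e}"
                )
            E[t, s] = e
        if not np.any(E[t] > 0.0):
            raise ImpossibleObservationError(t)
    return E


def run_forward_backward(spec: ChainSpec, obs: ObservationSeries) -> PosteriorResult:
    """Exact smoothed posteriors and log evidence by scaled forward-backward.

    Raises
    ------
    ImpossibleObservationError
        If at some timestep no state has nonzero emission likelihood.
    """
    E = _emission_matrix(spec, obs)
    T, S = E.shape
    A = spec.transition

    alpha = np.empty((T, S))
    log_norm = 0.0
    a = spec.prior * E[0]
    z = a.sum()
    if z <= 0.0:
        raise ImpossibleObservationError(0)
    alpha[0] = a / z
    log_norm += np.log(z)
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * E[t]
        z = a.sum()
        if z <= 0.0:
            raise ImpossibleObservationError(t)
        alpha[t] = a / z
        log_norm += np.log(z)

    beta = np.empty((T, S))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = A @ (E[t + 1] * beta[t + 1])
        s = b.sum()
        beta[t] = b / s  # rescale; marginals renormalized below

    marginals = alpha * beta
    marginals /= marginals.sum(axis=1, keepdims=True)
    return PosteriorResult(marginals=marginals, log_evidence=float(log_norm))


def enumerate_oracle(spec: ChainSpec, obs: ObservationSeries) -> PosteriorResult:
    """Brute-force reference: explicit summation over every hidden state path.

    Shares the contract of :func:`run_forward_backward`; intended as an
    independent oracle for testing, it refuses instances with more than
    10^6 paths.
    """
    n_paths = spec.n_states ** spec.length
    if n_paths > 10**6:
        raise ValueError(
            f"enumeration over {n_paths} paths exceeds the 1e6 size limit"
        )
    E = _emission_matrix(spec, obs)
    T, S = E.shape
    A = spec.transition

    marg = np.zeros((T, S))
    total = 0.0
    for flat in range(n_paths):
        path = []
        x = flat
        for _ in range(T):
            path.append(x % S)
            x //= S
        w = spec.prior[path[0]] * E[0, path[0]]
        for t in range(1, T):
            w *= A[path[t - 1], path[t]] * E[t, path[t]]
        total += w
        for t in range(T):
            marg[t, path[t]] += w
    if total <= 0.0:
        # locate the offending timestep for error-path parity
        for t in range(T):
            if not np.any(E[t] > 0.0):
                raise ImpossibleObservationError(t)
        raise ImpossibleObservationError(0)
    marg /= total
    return PosteriorResult(marginals=marg, log_evidence=float(np.log(total)))
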