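"""Learning, connection weights, feedforward inhibition and retrieval.

A memory is an association between ``A`` input and ``B`` output neurons;
each of the A*B potential connections occupies a chain state.  Learning
stabilizes absent connections: per unit of learning time a fraction
``p_{1,2} * mu`` of the state-1 connections onto each output neuron is
promoted to state 2.  Higher states are not directly affected.

Each state carries a weight ``w(i) = alpha * (i - 1) / (S - 1)``; the net
input to an output neuron is the summed weight over active inputs.
Feedforward inhibition sets the firing threshold halfway into the expected
learning increment, so unlearned patterns stay (mostly) subthreshold while
freshly learned ones fire.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .chain import ChainSpec, build_transition_matrix

__all__ = [
    "LearningParams",
    "MemoryTraceEnsemble",
    "RetrievalResult",
    "state_weight",
    "state_weights",
    "learning_step_probability",
    "learn_distribution",
    "new_ensemble",
    "learn_ensemble",
    "drift_ensemble",
    "expected_net_input",
    "feedforward_inhibition",
    "retrieve",
    "learning_curve",
]


@dataclass(frozen=True)
class LearningParams:
    """Learning rate ``mu`` in [0, 1] and weight scale ``alpha`` > 0."""

    mu: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.alpha <= 0.0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass
class MemoryTraceEnsemble:
    """Explicit A x B matrix of connection states (integers 1..S)."""

    A: int
    B: int
    states: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be positive")
        if self.states.shape != (self.A, self.B):
            raise ValueError(
                f"states must have shape ({self.A}, {self.B}), got {self.states.shape}"
            )
        if self.states.min() < 1:
            raise ValueError("state indices must be >= 1")

    def state_fractions(self, S: int) -> np.ndarray:
        """Occupancy fraction per state over the whole ensemble."""
        counts = np.bincount(self.states.ravel(), minlength=S + 1)[1:]
        return counts / self.states.size

    def to_frame(self):
        """Long-format DataFrame: input_idx, output_idx, state (1-based)."""
        import pandas as pd

        a, b = np.meshgrid(np.arange(1, self.A + 1), np.arange(1, self.B + 1), indexing="ij")
        return pd.DataFrame(
            {"input_idx": a.ravel(), "output_idx": b.ravel(), "state": self.states.ravel()}
        )


@dataclass(frozen=True)
class RetrievalResult:
    """Net inputs, inhibition threshold and binary output activations."""

    net: np.ndarray
    F: float
    act: np.ndarray
    fraction_active: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "net": self.net.tolist(),
                "F": self.F,
                "act": self.act.astype(int).tolist(),
                "fraction_active": self.fraction_active,
            }
        )


def state_weight(i: int, S: int, alpha: float = 1.0) -> float:
    """Weight of state i (1-based): alpha * (i - 1) / (S - 1)."""
    if not 1 <= i <= S:
        raise ValueError(f"state index {i} out of range 1..{S}")
    return alpha * (i - 1) / (S - 1)


def state_weights(S: int, alpha: float = 1.0) -> np.ndarray:
    return alpha * np.arange(S) / (S - 1)


def learning_step_probability(spec: ChainSpec) -> float:
    """The chain's own 1→2 transition probability p_{1,2} = x_2 y_1."""
    return spec.x[1] * spec.y[0]


def learn_distribution(
    v: np.ndarray,
    spec: ChainSpec,
    params: LearningParams,
    units: int = 1,
    *,
    interleave_drift: bool = False,
) -> np.ndarray:
    """Distribution-level learning: move mass v_1 * p_{1,2} * mu from 1 to 2.

    Applied once per learning unit.  With ``interleave_drift`` one chain
    step follows each unit (for schedules where study and spontaneous
    drift happen on comparable timescales); by default learning episodes
    are fast relative to drift and the chain is frozen during them.
    """
    if units < 0:
        raise ValueError("units must be >= 0")
    v = np.asarray(v, dtype=float).copy()
    rate = learning_step_probability(spec) * params.mu
    P = build_transition_matrix(spec) if interleave_drift else None
    for _ in range(units):
        moved = v[0] * rate
        v[0] -= moved
        v[1] += moved
        if interleave_drift:
            v = v @ P
    return v


def new_ensemble(
    spec: ChainSpec,
    A: int,
    B: int,
    v0: np.ndarray | None = None,
    seed: int | None = None,
) -> MemoryTraceEnsemble:
    """Draw an A x B ensemble with states i.i.d. from v0 (default: equilibrium)."""
    rng = np.random.default_rng(seed)
    if v0 is None:
        v0 = spec.x_arr
    states = rng.choice(np.arange(1, spec.S + 1), size=(A, B), p=np.asarray(v0, dtype=float))
    return MemoryTraceEnsemble(A=A, B=B, states=states, seed=seed)


def learn_ensemble(
    ens: MemoryTraceEnsemble,
    spec: ChainSpec,
    params: LearningParams,
    units: int = 1,
    seed: int | None = None,
) -> MemoryTraceEnsemble:
    """Stochastic learning: each state-1 connection is independently
    promoted to state 2 with probability p_{1,2} * mu per unit."""
    rng = np.random.default_rng(seed)
    rate = learning_step_probability(spec) * params.mu
    states = ens.states.copy()
    for _ in range(units):
        at_one = states == 1
        promote = at_one & (rng.random(states.shape) < rate)
        states[promote] = 2
    return MemoryTraceEnsemble(A=ens.A, B=ens.B, states=states, seed=ens.seed)


def drift_ensemble(
    ens: MemoryTraceEnsemble,
    spec: ChainSpec,
    steps: int,
    seed: int | None = None,
) -> MemoryTraceEnsemble:
    """Advance every connection `steps` chain steps (spontaneous fluctuations)."""
    rng = np.random.default_rng(seed)
    P = build_transition_matrix(spec)
    cum = np.cumsum(P, axis=1)
    states0 = ens.states - 1
    for _ in range(steps):
        u = rng.random(states0.shape)
        # inverse-CDF draw per connection from its current row of P
        states0 = (u[..., None] >= cum[states0]).sum(axis=-1)
    return MemoryTraceEnsemble(A=ens.A, B=ens.B, states=states0 + 1, seed=ens.seed)


def expected_net_input(v: np.ndarray, A: int, S: int, alpha: float = 1.0) -> float:
    """Expected net input to one output neuron: A * sum_i w(i) v_i."""
    v = np.asarray(v, dtype=float)
    return float(A * np.dot(state_weights(S, alpha), v))


def feedforward_inhibition(
    A_active: int,
    spec: ChainSpec,
    params: LearningParams,
    *,
    policy: str = "half_delta",
) -> float:
    """Inhibition threshold for an input pattern with ``A_active`` active units.

    half_delta (default): equilibrium expected net plus half the expected
    learning increment, linear in the active-input count —
    F = A_active * (S-1)^{-1} * (x_1 p_{1,2} mu / 2 + sum (i-1) x_i).

    two_sigma: equilibrium expected net plus two weighted standard
    deviations of the net input, using the chain's asymptotic occupancy
    variances; admits a small spurious-activation fraction by design.
    """
    if A_active < 0:
        raise ValueError("A_active must be >= 0")
    x = spec.x_arr
    S = spec.S
    alpha = params.alpha
    w = state_weights(S, alpha)
    net_hat = A_active * float(np.dot(w, x))
    if policy == "half_delta":
        delta = x[0] * learning_step_probability(spec) * params.mu * A_active * alpha / (S - 1)
        return net_hat + 0.5 * delta
    if policy == "two_sigma":
        from .chain import asymptotic_variance, build_transition_matrix, fundamental_matrix

        Z = fundamental_matrix(spec, build_transition_matrix(spec))
        sigma2 = asymptotic_variance(Z, x)
        return net_hat + 2.0 * float(np.sqrt(A_active * np.dot(w**2, sigma2)))
    raise ValueError(f"unknown inhibition policy {policy!r}")


def retrieve(
    ens: MemoryTraceEnsemble,
    cue_fraction: float,
    spec: ChainSpec,
    params: LearningParams,
    seed: int | None = None,
    *,
    policy: str = "half_delta",
) -> RetrievalResult:
    """Present a (partial) cue and read out the binary output pattern.

    A cue activates round(cue_fraction * A) input neurons chosen uniformly
    at random; each output fires iff its summed weight over active inputs
    exceeds the inhibition threshold for that cue size.
    """
    if not 0.0 < cue_fraction <= 1.0:
        raise ValueError(f"cue_fraction must be in (0, 1], got {cue_fraction}")
    rng = np.random.default_rng(seed)
    n_active = int(round(cue_fraction * ens.A))
    n_active = max(1, n_active)
    active = rng.choice(ens.A, size=n_active, replace=False)
    w = state_weights(spec.S, params.alpha)
    net = w[ens.states[active] - 1].sum(axis=0)
    F = feedforward_inhibition(n_active, spec, params, policy=policy)
    act = (net - F) > 0.0
    return RetrievalResult(net=net, F=F, act=act, fraction_active=float(act.mean()))


def learning_curve(
    spec: ChainSpec,
    params: LearningParams,
    A: int,
    t: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form expected counts in states 1 and 2 under massed learning.

    Per unit a fraction f = mu * x_2 * y_1 of state-1 connections is
    promoted, so state-1 count decays as x_1 A (1 - f)^t and the state-2
    count rises toward the asymptote A (x_1 + x_2): an exponentially
    decelerating (negatively accelerated) learning curve.

    Returns (state1_counts, state2_counts) for t = 0..t inclusive.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    x = spec.x_arr
    f = params.mu * spec.x[1] * spec.y[0]
    ts = np.arange(t + 1)
    c1 = x[0] * A * (1.0 - f) ** ts
    c2 = A * x[1] + A * x[0] - c1
    return c1, c2
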