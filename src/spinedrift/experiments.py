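"""Experiment drivers for the emergent memory laws.

A learned memory trace is a state distribution ``v`` displaced from
equilibrium; its *strength* (default metric) is the excess expected net
input over the equilibrium baseline,

    strength(t) = A * sum_i w(i) * (v P^t - x)_i,

which starts at the learning increment Delta_net = x1 p12 mu A / (S-1)
and relaxes to zero as the chain drifts back to equilibrium.  On top of
this the drivers realize four classical phenomena: the power-early /
exponential-late forgetting-curve shape, Jost's laws of forgetting and
learning, the spaced-over-massed advantage, and Ribot gradients under
diffuse lesioning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chain import (
    ChainSpec,
    build_transition_matrix,
    evolve_distribution,
    spectral_summary,
)
from .memory import (
    LearningParams,
    expected_net_input,
    learn_distribution,
    state_weights,
)

__all__ = [
    "ForgettingCurve",
    "ShapeReport",
    "LesionModel",
    "RibotGradient",
    "LogisticLink",
    "trace_strength",
    "forgetting_experiment",
    "classify_curve_shape",
    "calibrate_mu",
    "jost_decay_experiment",
    "jost_learning_experiment",
    "spacing_experiment",
    "apply_lesion",
    "apply_lesion_ensemble",
    "lesion_experiment",
]


# --------------------------------------------------------------------------
# strength metric
# --------------------------------------------------------------------------

def trace_strength(
    v: np.ndarray, spec: ChainSpec, params: LearningParams, A: int
) -> float:
    """Excess expected net input of trace distribution v over equilibrium."""
    return expected_net_input(v, A, spec.S, params.alpha) - expected_net_input(
        spec.x_arr, A, spec.S, params.alpha
    )


@dataclass(frozen=True)
class ForgettingCurve:
    """Retention strength as a function of time since learning."""

    times: np.ndarray
    strength: np.ndarray
    metric: str = "delta_net"

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def forgetting_experiment(
    spec: ChainSpec,
    params: LearningParams,
    A: int,
    t_max: int,
    metric: str = "delta_net",
    *,
    learn_units: int = 1,
) -> ForgettingCurve:
    """Learn once at equilibrium, then let the chain drift for t_max steps.

    The default analytic metric tracks the excess expected net input of
    the evolving trace distribution; it equals the learning increment at
    t = 0 and decays toward zero (asymptotically at rate ln(lambda2)).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if metric != "delta_net":
        raise ValueError(f"unknown metric {metric!r}")
    P = build_transition_matrix(spec)
    v = learn_distribution(spec.x_arr, spec, params, units=learn_units)
    w = state_weights(spec.S, params.alpha)
    base = A * float(np.dot(w, spec.x_arr))
    strength = np.empty(t_max + 1)
    vt = v
    for t in range(t_max + 1):
        strength[t] = A * float(np.dot(w, vt)) - base
        vt = vt @ P
    return ForgettingCurve(times=np.arange(t_max + 1), strength=strength)


@dataclass(frozen=True)
class ShapeReport:
    """Goodness-of-fit comparison of power vs exponential curve shapes."""

    early_power_r2: float
    early_exp_r2: float
    late_power_r2: float
    late_exp_r2: float
    late_exp_rate: float
    plateau: float
    early_window: tuple[int, int]
    late_window: tuple[int, int]


def _window_fits(times: np.ndarray, strength: np.ndarray, lo: int, hi: int):
    mask = (times >= lo) & (times <= hi) & (strength > 0) & (times > 0)
    t, s = times[mask].astype(float), strength[mask]
    if t.size < 3:
        raise ValueError(f"window [{lo}, {hi}] has < 3 usable points")
    pw = stats.linregress(np.log(t), np.log(s))
    ex = stats.linregress(t, np.log(s))
    return pw.rvalue**2, ex.rvalue**2, ex.slope


def classify_curve_shape(
    curve: ForgettingCurve,
    *,
    early_window: tuple[int, int] | None = None,
    late_window: tuple[int, int] | None = None,
) -> ShapeReport:
    """Fit power (log-log) and exponential (log-linear) laws on early and
    late windows of a forgetting curve and report R^2 for each.

    Defaults: early window spans t = 1 up to ~2% of the observed range (at
    least 20 points); late window is the final third.  The plateau
    estimate is the mean strength over the final 5% of points — nonzero
    plateaus arise when the top-state plasticity is very small.
    """
    t, s = curve.times, curve.strength
    if t.size < 20:
        raise ValueError("need at least 20 points to classify curve shape")
    if float(np.ptp(s)) <= 0:
        raise ValueError("degenerate (constant) curve")
    t_max = int(t[-1])
    if early_window is None:
        early_window = (1, max(20, t_max // 50))
    if late_window is None:
        late_window = (max(early_window[1] + 1, (2 * t_max) // 3), t_max)
    ep_r2, ee_r2, _ = _window_fits(t, s, *early_window)
    lp_r2, le_r2, le_rate = _window_fits(t, s, *late_window)
    n_tail = max(1, t.size // 20)
    plateau = float(np.mean(s[-n_tail:]))
    return ShapeReport(
        early_power_r2=ep_r2,
        early_exp_r2=ee_r2,
        late_power_r2=lp_r2,
        late_exp_r2=le_r2,
        late_exp_rate=le_rate,
        plateau=plateau,
        early_window=early_window,
        late_window=late_window,
    )


def late_slope_window(spec: ChainSpec, *, width: int = 2000) -> tuple[int, int]:
    """Window where the second eigen-mode dominates the decay.

    Starts once subdominant modes have decayed ~1e-6 relative to the
    second mode (14 e-foldings of the spectral gap between them).
    """
    P = build_transition_matrix(spec)
    ss = spectral_summary(P, spec.x_arr)
    lam2, lam3 = ss.eigenvalues[1], abs(ss.eigenvalues[2])
    if not (0 < lam3 < lam2 < 1):
        return (10, 10 + width)
    gap = math.log(lam2) - math.log(lam3)
    t0 = int(math.ceil(14.0 / gap))
    return (t0, t0 + width)


# --------------------------------------------------------------------------
# Jost's laws and spacing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceComparison:
    """Matched-strength comparison of two memory traces."""

    mu_reference: float
    mu_matched: float
    matched_strength: float
    probe_times: np.ndarray
    strength_a: np.ndarray  # reference trace (older / spaced)
    strength_b: np.ndarray  # matched trace (younger / massed)
    extra: dict = field(default_factory=dict)
    feasible: bool = True


class CalibrationError(RuntimeError):
    """Equal-strength matching is infeasible within mu in [0, 1]."""


def calibrate_mu(
    target: float,
    strength_of_mu,
    *,
    rel_tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Bisection on mu in [0, 1] so that strength_of_mu(mu) == target.

    strength_of_mu must be monotone increasing with strength_of_mu(0)=0.
    Raises CalibrationError when even mu = 1 falls short of the target.
    """
    if target <= 0:
        return 0.0
    hi_val = strength_of_mu(1.0)
    if hi_val < target * (1.0 - rel_tol):
        raise CalibrationError(
            f"target strength {target:.6g} exceeds the maximum attainable "
            f"{hi_val:.6g} at mu=1"
        )
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = strength_of_mu(mid)
        if abs(val - target) <= rel_tol * abs(target):
            return mid
        if val < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _aged_trace(
    spec: ChainSpec, mu: float, age: int, alpha: float, P: np.ndarray
) -> np.ndarray:
    v = learn_distribution(spec.x_arr, spec, LearningParams(mu=mu, alpha=alpha))
    return evolve_distribution(v, P, age)


def jost_decay_experiment(
    spec: ChainSpec,
    params: LearningParams,
    age_old: int,
    t_probe,
) -> TraceComparison:
    """Jost's first law: of two equal-strength traces the older decays slower.

    The old trace is learned with rate mu and aged ``age_old`` steps; a
    fresh trace's learning rate is then bisected so both have identical
    strength at probe time 0, and both are evolved to each probe time.
    """
    P = build_transition_matrix(spec)
    A = 1  # strength is linear in A; comparisons are A-independent
    alpha = params.alpha
    v_old = _aged_trace(spec, params.mu, age_old, alpha, P)
    target = trace_strength(v_old, spec, params, A)

    def young_strength(mu):
        v = learn_distribution(spec.x_arr, spec, LearningParams(mu=mu, alpha=alpha))
        return trace_strength(v, spec, params, A)

    mu_young = calibrate_mu(target, young_strength)
    v_young = learn_distribution(
        spec.x_arr, spec, LearningParams(mu=mu_young, alpha=alpha)
    )
    probes = np.atleast_1d(np.asarray(t_probe, dtype=int))
    s_old = np.array(
        [trace_strength(evolve_distribution(v_old, P, t), spec, params, A) for t in probes]
    )
    s_young = np.array(
        [trace_strength(evolve_distribution(v_young, P, t), spec, params, A) for t in probes]
    )
    return TraceComparison(
        mu_reference=params.mu,
        mu_matched=mu_young,
        matched_strength=target,
        probe_times=probes,
        strength_a=s_old,
        strength_b=s_young,
    )


def jost_learning_experiment(
    spec: ChainSpec,
    params: LearningParams,
    age_old: int,
    relearn_units: int = 1,
) -> TraceComparison:
    """Jost's second law: the older of two equal-strength traces gains more
    from identical additional learning (it has more state-1 mass free)."""
    P = build_transition_matrix(spec)
    A = 1
    alpha = params.alpha
    v_old = _aged_trace(spec, params.mu, age_old, alpha, P)
    target = trace_strength(v_old, spec, params, A)

    def young_strength(mu):
        v = learn_distribution(spec.x_arr, spec, LearningParams(mu=mu, alpha=alpha))
        return trace_strength(v, spec, params, A)

    mu_young = calibrate_mu(target, young_strength)
    v_young = learn_distribution(
        spec.x_arr, spec, LearningParams(mu=mu_young, alpha=alpha)
    )
    inc = []
    state1 = []
    for v in (v_old, v_young):
        v2 = learn_distribution(v, spec, params, units=relearn_units)
        inc.append(trace_strength(v2, spec, params, A) - trace_strength(v, spec, params, A))
        state1.append(float(v[0]))
    return TraceComparison(
        mu_reference=params.mu,
        mu_matched=mu_young,
        matched_strength=target,
        probe_times=np.array([0]),
        strength_a=np.array([inc[0]]),
        strength_b=np.array([inc[1]]),
        extra={"state1_old": state1[0], "state1_young": state1[1]},
    )


def spacing_experiment(
    spec: ChainSpec,
    params: LearningParams,
    k_episodes: int,
    gap: int,
    t_probe,
) -> TraceComparison:
    """Spacing effect: spaced study beats massed study at matched strength.

    The spaced trace gets k learning episodes separated by ``gap`` drift
    steps (none after the last); the massed trace gets k consecutive
    episodes with its rate bisected so both are equally strong immediately
    after their final episode.  Strengths are then compared at each probe
    delay.
    """
    if k_episodes < 1:
        raise ValueError("k_episodes must be >= 1")
    P = build_transition_matrix(spec)
    A = 1
    alpha = params.alpha

    def spaced_trace(mu):
        v = spec.x_arr.copy()
        lp = LearningParams(mu=mu, alpha=alpha)
        for ep in range(k_episodes):
            v = learn_distribution(v, spec, lp)
            if ep < k_episodes - 1:
                v = evolve_distribution(v, P, gap)
        return v

    def massed_trace(mu):
        return learn_distribution(
            spec.x_arr, spec, LearningParams(mu=mu, alpha=alpha), units=k_episodes
        )

    v_spaced = spaced_trace(params.mu)
    target = trace_strength(v_spaced, spec, params, A)
    mu_massed = calibrate_mu(
        target, lambda mu: trace_strength(massed_trace(mu), spec, params, A)
    )
    v_massed = massed_trace(mu_massed)
    probes = np.atleast_1d(np.asarray(t_probe, dtype=int))
    s_spaced = np.array(
        [trace_strength(evolve_distribution(v_spaced, P, t), spec, params, A) for t in probes]
    )
    s_massed = np.array(
        [trace_strength(evolve_distribution(v_massed, P, t), spec, params, A) for t in probes]
    )
    return TraceComparison(
        mu_reference=params.mu,
        mu_matched=mu_massed,
        matched_strength=target,
        probe_times=probes,
        strength_a=s_spaced,
        strength_b=s_massed,
        extra={
            "high_state_mass_spaced": float(v_spaced[2:].sum()),
            "high_state_mass_massed": float(v_massed[2:].sum()),
        },
    )


# --------------------------------------------------------------------------
# diffuse lesioning and Ribot gradients
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionModel:
    """Per-state deletion probabilities for diffuse damage.

    Lesioning sends a connection in state i >= 2 back to state 1 with
    probability q_i; q_1 = 0 (nothing to delete).  Vulnerability must not
    increase with strength: q is non-increasing for i >= 2, reflecting
    that large-spine connections resist diffuse insults.
    """

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("deletion probabilities must lie in [0, 1]")
        if q[0] != 0.0:
            raise ValueError("q_1 must be 0 (state 1 has nothing to delete)")
        if q.size >= 3 and np.any(np.diff(q[1:]) > 1e-12):
            raise ValueError("q must be non-increasing over states >= 2")

    @classmethod
    def from_severity(
        cls, S: int, q_base: float, gamma: float = 1.0, alpha: float = 1.0
    ) -> "LesionModel":
        """Monotone family q_i = q_base * (1 - w(i)/alpha)^gamma for i >= 2.

        gamma = 0 gives uniform lesioning (a control); larger gamma
        concentrates damage on weak connections.
        """
        if not 0.0 <= q_base <= 1.0:
            raise ValueError("q_base must be in [0, 1]")
        if gamma < 0:
            raise ValueError("gamma must be >= 0")
        w = state_weights(S, 1.0)
        q = q_base * (1.0 - w) ** gamma
        q[0] = 0.0
        return cls(q=q)


def apply_lesion(v: np.ndarray, lesion: LesionModel) -> np.ndarray:
    """Distribution-level lesion: state-i mass survives w.p. 1 - q_i,
    deleted mass lands in state 1."""
    v = np.asarray(v, dtype=float)
    out = v * (1.0 - lesion.q)
    out[0] += float(np.dot(v, lesion.q))
    return out


def apply_lesion_ensemble(ens, lesion: LesionModel, seed: int | None = None):
    """Monte-Carlo lesion of an explicit ensemble: each connection in state
    i >= 2 independently drops to state 1 with probability q_i."""
    from .memory import MemoryTraceEnsemble

    rng = np.random.default_rng(seed)
    states = ens.states.copy()
    hit = rng.random(states.shape) < lesion.q[states - 1]
    states[hit] = 1
    return MemoryTraceEnsemble(A=ens.A, B=ens.B, states=states, seed=ens.seed)


@dataclass(frozen=True)
class LogisticLink:
    """Strength -> recall-probability link p = 1 / (1 + exp(-(b0 + b1 s)))."""

    beta0: float = -2.2
    beta1: float = 6.0

    def __call__(self, strength) -> np.ndarray:
        s = np.asarray(strength, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.beta0 + self.beta1 * s)))


@dataclass(frozen=True)
class RibotGradient:
    """Recall before/after a lesion across memory ages, and the relative
    retrograde gradient log(p_patient) / log(p_control)."""

    ages: np.ndarray
    control_p: np.ndarray
    patient_p: np.ndarray
    relative: np.ndarray
    retained_ratio: np.ndarray


def lesion_experiment(
    spec: ChainSpec,
    params: LearningParams,
    lesion: LesionModel,
    ages,
    *,
    A: int = 100,
    link: LogisticLink | None = None,
    eps: float = 1e-6,
) -> RibotGradient:
    """Ribot gradient: lesion memory traces of different ages, compare recall.

    For each age the just-learned trace distribution is drifted ``age``
    steps and then lesioned; strengths before and after are mapped to
    recall probabilities by the link.  The lesion hits the equilibrium
    background too, so post-lesion strength is measured against the
    lesioned baseline.  Older traces keep a larger strength fraction
    (their excess mass sits in strong, low-q states) — Ribot's law.
    """
    if link is None:
        link = LogisticLink()
    ages = np.atleast_1d(np.asarray(ages, dtype=int))
    P = build_transition_matrix(spec)
    v0 = learn_distribution(spec.x_arr, spec, params)
    w = state_weights(spec.S, params.alpha)
    x = spec.x_arr
    pre, post = [], []
    for age in ages:
        v_age = evolve_distribution(v0, P, int(age))
        pre.append(A * float(np.dot(w, v_age - x)))
        post.append(A * float(np.dot(w, apply_lesion(v_age, lesion) - apply_lesion(x, lesion))))
    pre, post = np.asarray(pre), np.asarray(post)
    control_p = np.asarray(link(pre), dtype=float)
    patient_p = np.asarray(link(post), dtype=float)
    for name, p in (("control", control_p), ("patient", patient_p)):
        if np.any(p <= 0):
            warnings.warn(f"{name} recall probabilities floored at eps={eps}")
    control_p = np.clip(control_p, eps, 1.0)
    patient_p = np.clip(patient_p, eps, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.log(patient_p) / np.log(control_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pre > 0, post / pre, np.nan)
    return RibotGradient(
        ages=ages,
        control_p=control_p,
        patient_p=patient_p,
        relative=relative,
        retained_ratio=ratio,
    )
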