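"""Reflecting random-walk Markov chain over discrete connection-strength states.

Each synaptic connection occupies one of ``S`` strength states, numbered
1 (absent / zero strength) to ``S`` (strongest, least plastic).  Per time
step a connection may hop to an adjacent state.  Transition probabilities
are parameterized so that a chosen equilibrium distribution ``x`` is
stationary by construction (detailed balance), while the plasticity scale
factors ``y`` independently set the speed of the dynamics:

    P[i, i+1] = x[i+1] * y[i]      (grow)
    P[i+1, i] = x[i]   * y[i]      (shrink)
    P[i, i]   = 1 - (off-diagonal row mass)

States are 1-based in all user-facing I/O and documentation; arrays are
stored 0-based internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ChainSpec",
    "PassageSummary",
    "SpectralSummary",
    "Tolerances",
    "TOL",
    "build_transition_matrix",
    "verify_equilibrium",
    "state_lifetimes",
    "fundamental_matrix",
    "first_passage_times",
    "asymptotic_variance",
    "evolve_distribution",
    "spectral_summary",
    "simulate_connections",
    "occupancy_to_frame",
]


@dataclass(frozen=True)
class Tolerances:
    """Central numerical tolerance policy."""

    stationarity: float = 1e-12
    row_sum: float = 1e-12
    detailed_balance: float = 1e-14
    eig_real: float = 1e-10
    fundamental: float = 1e-10
    prob_floor: float = 1e-6


TOL = Tolerances()


class SpecValidationError(ValueError):
    """Raised when a chain specification violates its invariants."""


@dataclass(frozen=True)
class ChainSpec:
    """Specification of the connection-strength chain.

    Parameters
    ----------
    x : equilibrium probabilities over the S states; positive, sums to 1.
    y : S-1 positive plasticity scale factors; ``y[j]`` controls the
        transition rate between states j+1 and j+2 (1-based).
    time_unit : label for one step of the chain (default "day").
    """

    x: tuple[float, ...]
    y: tuple[float, ...]
    time_unit: str = "day"

    def __init__(self, x, y, time_unit: str = "day"):
        object.__setattr__(self, "x", tuple(float(v) for v in np.asarray(x, dtype=float)))
        object.__setattr__(self, "y", tuple(float(v) for v in np.asarray(y, dtype=float)))
        object.__setattr__(self, "time_unit", str(time_unit))
        self._validate()

    @property
    def S(self) -> int:
        return len(self.x)

    @property
    def x_arr(self) -> np.ndarray:
        return np.asarray(self.x, dtype=float)

    @property
    def y_arr(self) -> np.ndarray:
        return np.asarray(self.y, dtype=float)

    def _validate(self) -> None:
        x, y = self.x_arr, self.y_arr
        S = x.size
        if S < 2:
            raise SpecValidationError(f"need at least 2 states, got S={S}")
        if y.size != S - 1:
            raise SpecValidationError(
                f"y must have S-1={S - 1} entries, got {y.size}"
            )
        if np.any(x <= 0):
            raise SpecValidationError("all equilibrium probabilities x_i must be > 0")
        if abs(x.sum() - 1.0) > 1e-9:
            raise SpecValidationError(f"x must sum to 1, got {x.sum()!r}")
        if np.any(y <= 0):
            raise SpecValidationError("all plasticity factors y_j must be > 0")
        # Diagonal feasibility: each row's off-diagonal mass must not exceed 1.
        up = np.concatenate([x[1:] * y, [0.0]])     # P[i, i+1]
        down = np.concatenate([[0.0], x[:-1] * y])  # P[i, i-1]
        excess = up + down - 1.0
        bad = np.nonzero(excess > 1e-12)[0]
        if bad.size:
            i = int(bad[0])
            raise SpecValidationError(
                f"row {i + 1} (1-based) has off-diagonal mass "
                f"{up[i] + down[i]:.6g} > 1; the induced diagonal would be "
                "negative — reduce y near that state"
            )

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "x": list(self.x),
            "y": list(self.y),
            "time_unit": self.time_unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainSpec":
        spec = cls(d["x"], d["y"], d.get("time_unit", "day"))
        if "S" in d and int(d["S"]) != spec.S:
            raise SpecValidationError(
                f"declared S={d['S']} does not match len(x)={spec.S}"
            )
        return spec

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ChainSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PassageSummary:
    """Fundamental matrix and quantities derived from it.

    Attributes
    ----------
    Z : fundamental matrix (I - P + X)^{-1}, X the rank-one matrix of
        stationary rows.
    t : first-passage-time matrix, t[i, j] = expected steps to first reach
        state j+1 from state i+1; diagonal is 0 by convention.
    sigma2 : asymptotic variances of state-occupancy frequencies.
    """

    Z: np.ndarray
    t: np.ndarray
    sigma2: np.ndarray


@dataclass(frozen=True)
class SpectralSummary:
    """Spectrum of the chain and the late-time forgetting rate it implies.

    For a reversible chain all eigenvalues are real; convergence of any
    initial distribution to equilibrium is asymptotically ``a2 * lambda2**t``.
    """

    eigenvalues: np.ndarray
    lambda2: float
    tail_rate: float
    tail_coefficient: float


def build_transition_matrix(spec: ChainSpec) -> np.ndarray:
    """Construct the tridiagonal transition matrix with stationary vector x.

    Up-moves are ``x[i+1]*y[i]``, down-moves ``x[i]*y[i]``, the diagonal
    absorbs the remainder so rows sum to 1.  Detailed balance
    ``x_i P[i,i+1] = x_{i+1} P[i+1,i]`` holds by construction, which makes
    x stationary.
    """
    x, y = spec.x_arr, spec.y_arr
    S = spec.S
    P = np.zeros((S, S), dtype=float)
    up = x[1:] * y
    down = x[:-1] * y
    idx = np.arange(S - 1)
    P[idx, idx + 1] = up
    P[idx + 1, idx] = down
    diag = 1.0 - P.sum(axis=1)
    if np.any(diag < -1e-12):
        i = int(np.argmin(diag))
        raise SpecValidationError(
            f"row {i + 1} (1-based) yields negative diagonal {diag[i]:.6g}"
        )
    P[np.arange(S), np.arange(S)] = np.clip(diag, 0.0, 1.0)
    return P


def verify_equilibrium(spec: ChainSpec, P: np.ndarray) -> float:
    """Max-abs residual of the stationarity equation x P = x."""
    x = spec.x_arr
    if P.shape != (x.size, x.size):
        raise ValueError(f"shape mismatch: P is {P.shape}, x has {x.size} entries")
    return float(np.max(np.abs(x @ P - x)))


def state_lifetimes(P: np.ndarray) -> np.ndarray:
    """Expected dwell time per state, ``1 / (1 - P[i, i])``, in time steps.

    An absorbing state (diagonal exactly 1) gets an explicit ``inf``
    sentinel rather than overflowing.
    """
    diag = np.diag(P).astype(float)
    exit_prob = 1.0 - diag
    lifetimes = np.full_like(diag, np.inf)
    live = exit_prob > 0.0
    lifetimes[live] = 1.0 / exit_prob[live]
    return lifetimes


def fundamental_matrix(spec: ChainSpec, P: np.ndarray) -> np.ndarray:
    """Fundamental matrix Z = (I - P + X)^{-1} of the ergodic chain.

    X is the matrix whose every row is the stationary vector x.  Z encodes
    deviations of the transient dynamics from equilibrium and yields
    first-passage times and asymptotic occupancy variances.
    """
    x = spec.x_arr
    S = x.size
    M = np.eye(S) - P + np.tile(x, (S, 1))
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"fundamental system ill-conditioned (condition number {cond:.3g})"
        )
    Z = np.linalg.solve(M, np.eye(S))
    resid = np.max(np.abs(Z @ M - np.eye(S)))
    if resid > TOL.fundamental:
        raise np.linalg.LinAlgError(
            f"fundamental matrix residual {resid:.3g} exceeds tolerance"
        )
    return Z


def first_passage_times(Z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Mean first-passage times t[i, j] = (z_jj - z_ij) / x_j (steps)."""
    x = np.asarray(x, dtype=float)
    if Z.shape != (x.size, x.size):
        raise ValueError("Z and x have inconsistent shapes")
    t = (np.diag(Z)[None, :] - Z) / x[None, :]
    np.fill_diagonal(t, 0.0)
    return t


def asymptotic_variance(Z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Asymptotic variance of occupancy frequency per state.

    sigma2_j = 2 x_j z_jj - x_j - x_j**2; for the fully mixing chain
    (Z = I) this reduces to the Bernoulli variance x_j (1 - x_j).
    """
    x = np.asarray(x, dtype=float)
    return 2.0 * x * np.diag(Z) - x - x**2


def evolve_distribution(v: np.ndarray, P: np.ndarray, t: int) -> np.ndarray:
    """Propagate a state distribution t steps: v P^t.

    Uses matrix power by repeated squaring; t = 0 returns v unchanged.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    v = np.asarray(v, dtype=float)
    if t == 0:
        return v.copy()
    return v @ np.linalg.matrix_power(P, int(t))


def _reversible_eigenvalues(P: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Real spectrum of a reversible chain via symmetrization.

    D^{1/2} P D^{-1/2} is symmetric under detailed balance, so eigh gives
    the exact real spectrum without complex round-off.
    """
    d = np.sqrt(np.asarray(x, dtype=float))
    Psym = (d[:, None] * P) / d[None, :]
    asym = np.max(np.abs(Psym - Psym.T))
    if asym > TOL.eig_real:
        raise ValueError(
            f"chain is not reversible to tolerance (asymmetry {asym:.3g}); "
            "upstream invariant violated"
        )
    w = np.linalg.eigvalsh((Psym + Psym.T) / 2.0)
    return np.sort(w)[::-1]


def spectral_summary(
    P: np.ndarray,
    x: np.ndarray,
    *,
    v0: np.ndarray | None = None,
    fit_window: tuple[int, int] | None = None,
) -> SpectralSummary:
    """Eigenvalues, spectral gap, and the implied late-time forgetting rate.

    ``tail_rate`` is -ln(lambda2): distance from equilibrium shrinks
    asymptotically as lambda2**t.  ``tail_coefficient`` is estimated by
    regressing log distance-from-equilibrium against t over a late-time
    window (from ``v0``, default: unit mass in state 1).
    """
    x = np.asarray(x, dtype=float)
    eig = _reversible_eigenvalues(P, x)
    if abs(eig[0] - 1.0) > 1e-10:
        raise ValueError(f"leading eigenvalue {eig[0]!r} differs from 1")
    lambda2 = float(eig[1])
    tail_rate = float("inf") if lambda2 <= 0 else -math.log(lambda2)

    # Late-time amplitude: ||v P^t - x|| ~ a2 * lambda2^t.
    if v0 is None:
        v0 = np.zeros_like(x)
        v0[0] = 1.0
    if fit_window is None:
        lam3 = abs(eig[2]) if eig.size > 2 else 0.0
        if 0.0 < lambda2 < 1.0:
            # start once subdominant modes are ~1e-4 of the second mode
            if lam3 > 0 and lam3 < lambda2:
                t0 = int(min(2000, max(10, 9.2 / (math.log(lambda2) - math.log(lam3)))))
            else:
                t0 = 10
            t1 = t0 + max(20, t0)
        else:
            t0, t1 = 1, 21
        fit_window = (t0, t1)
    t0, t1 = fit_window
    ts = np.arange(t0, t1 + 1)
    v = evolve_distribution(v0, P, t0)
    dists = []
    for _ in ts:
        dists.append(np.linalg.norm(v - x))
        v = v @ P
    dists = np.asarray(dists)
    if 0.0 < lambda2 < 1.0 and np.all(dists > 0):
        slope, intercept = np.polyfit(ts, np.log(dists), 1)
        tail_coefficient = float(np.exp(intercept))
    else:
        tail_coefficient = float("nan")
    return SpectralSummary(
        eigenvalues=eig,
        lambda2=lambda2,
        tail_rate=tail_rate,
        tail_coefficient=tail_coefficient,
    )


def simulate_connections(
    spec: ChainSpec,
    n: int,
    t_max: int,
    v0: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo occupancy counts for n independent connections.

    Returns an integer array of shape (t_max + 1, S); row t holds the
    number of connections in each state after t steps.  Connections are
    advanced by multinomial resampling of the per-state counts, which is
    exact for independent walkers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    rng = np.random.default_rng(seed)
    P = build_transition_matrix(spec)
    S = spec.S
    if v0 is None:
        v0 = spec.x_arr
    counts = rng.multinomial(n, np.asarray(v0, dtype=float))
    out = np.zeros((t_max + 1, S), dtype=np.int64)
    out[0] = counts
    for t in range(1, t_max + 1):
        nxt = np.zeros(S, dtype=np.int64)
        for i in range(S):
            if counts[i]:
                nxt += rng.multinomial(int(counts[i]), P[i])
        counts = nxt
        out[t] = counts
    return out


def occupancy_to_frame(occupancy: np.ndarray):
    """Occupancy trajectory as a DataFrame with columns t, state_1..state_S."""
    import pandas as pd

    S = occupancy.shape[1]
    df = pd.DataFrame(occupancy, columns=[f"state_{i + 1}" for i in range(S)])
    df.insert(0, "t", np.arange(occupancy.shape[0]))
    return df
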