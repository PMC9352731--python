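"""Biologically-motivated chain specifications for tests, docs and demos.

Empirical distributions of dendritic-spine size are strongly right-skewed
and are commonly described as (stretched-)exponential, gamma-like or
lognormal-like.  The recipes here discretize those families over the S
strength states so that most connections sit in the lowest states, and
pair them with plasticity profiles in which high (large-spine) states are
far less plastic than low ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chain import ChainSpec

__all__ = ["FixtureRecipe", "make_spec", "default_spec", "fixture_grid"]

#: Safety margin: generated rows keep off-diagonal mass below this.
_MAX_ROW_MASS = 0.95


@dataclass(frozen=True)
class FixtureRecipe:
    """Recipe for a valid ChainSpec.

    equilibrium_family: one of {"exponential", "gamma", "lognormal",
    "custom"}; ``family_params`` are the family's shape parameters (or the
    explicit x vector for "custom").  ``y_profile`` is one of {"constant",
    "geometric", "custom"} with ``y_params`` = (y1,) / (y1, ratio) / the
    explicit y vector.
    """

    S: int
    equilibrium_family: str = "exponential"
    family_params: dict = field(default_factory=dict)
    y_profile: str = "geometric"
    y_params: dict = field(default_factory=dict)


def _family_mass(recipe: FixtureRecipe) -> np.ndarray:
    S = recipe.S
    fam = recipe.equilibrium_family
    p = recipe.family_params
    if fam == "custom":
        x = np.asarray(p["x"], dtype=float)
        if x.size != S:
            raise ValueError("custom x length must equal S")
        return x
    edges = np.linspace(0.0, 1.0, S + 1)
    if fam == "exponential":
        rate = float(p.get("rate", 4.0))  # mass in bin i ∝ exp(-rate * left edge)
        mass = np.exp(-rate * edges[:-1]) - np.exp(-rate * edges[1:])
    elif fam == "gamma":
        shape = float(p.get("shape", 1.5))
        scale = float(p.get("scale", 0.2))
        cdf = stats.gamma.cdf(edges, a=shape, scale=scale)
        mass = np.diff(cdf)
    elif fam == "lognormal":
        s = float(p.get("sigma", 1.0))
        med = float(p.get("median", 0.15))
        cdf = stats.lognorm.cdf(edges, s=s, scale=med)
        mass = np.diff(cdf)
    else:
        raise ValueError(f"unknown equilibrium family {fam!r}")
    if np.any(mass <= 0) or mass.sum() <= 0:
        raise ValueError(f"recipe produced non-positive bin mass: {recipe}")
    return mass


def _y_vector(recipe: FixtureRecipe) -> np.ndarray:
    S = recipe.S
    prof = recipe.y_profile
    p = recipe.y_params
    if prof == "custom":
        y = np.asarray(p["y"], dtype=float)
        if y.size != S - 1:
            raise ValueError("custom y length must equal S-1")
        return y
    y1 = float(p.get("y1", 0.2))
    if prof == "constant":
        return np.full(S - 1, y1)
    if prof == "geometric":
        ratio = float(p.get("ratio", 0.3))
        return y1 * ratio ** np.arange(S - 1)
    raise ValueError(f"unknown y profile {prof!r}")


def make_spec(recipe: FixtureRecipe) -> ChainSpec:
    """Build a validated ChainSpec from a recipe.

    x is normalized from the family's mass over S bins.  If any induced
    diagonal would go negative, all y are rescaled down uniformly (with a
    warning) — rescaling y changes the timescale, never the equilibrium.
    """
    if recipe.S < 2:
        raise ValueError("S must be >= 2")
    mass = _family_mass(recipe)
    x = mass / mass.sum()
    y = _y_vector(recipe)
    up = np.concatenate([x[1:] * y, [0.0]])
    down = np.concatenate([[0.0], x[:-1] * y])
    worst = float(np.max(up + down))
    if worst > _MAX_ROW_MASS:
        scale = _MAX_ROW_MASS / worst
        warnings.warn(
            f"recipe y rescaled by {scale:.4g} to keep diagonals nonnegative",
            stacklevel=2,
        )
        y = y * scale
    return ChainSpec(x=x, y=y)


def default_spec() -> ChainSpec:
    """The canonical 5-state chain used throughout the documentation.

    Most equilibrium mass sits in the two lowest states (absent and weak
    connections); the second-highest state has occupancy 0.02 and
    plasticity 0.005, which puts the top state's expected lifetime at
    exactly 10,000 steps (days) — comfortably past the 25-year retention
    the model asks of its most consolidated connections — and the second
    eigenvalue above 0.999 (multi-year convergence to equilibrium).
    """
    return ChainSpec(
        x=(0.60, 0.24, 0.10, 0.02, 0.04),
        y=(0.20, 0.10, 0.02, 0.005),
    )


#: Parameter ranges sampled by fixture_grid (kept well inside validity).
_GRID_S = (4, 5, 7)
_GRID_FAMILIES = ("exponential", "gamma", "lognormal")


def fixture_grid(n: int, seed: int | None = None) -> list[ChainSpec]:
    """n diverse, valid, seeded chain specs for property-test grids.

    Varies state count, equilibrium family and plasticity profile; always
    uses decreasing (geometric) plasticity so high states are stable, the
    regime the theory describes.  Deterministic under a fixed seed and
    guaranteed to include every equilibrium family once n >= 3.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[ChainSpec] = []
    for k in range(n):
        fam = _GRID_FAMILIES[k % len(_GRID_FAMILIES)]
        S = int(rng.choice(_GRID_S))
        if fam == "exponential":
            fp = {"rate": float(rng.uniform(2.5, 6.0))}
        elif fam == "gamma":
            fp = {"shape": float(rng.uniform(1.0, 2.5)), "scale": float(rng.uniform(0.1, 0.3))}
        else:
            fp = {"sigma": float(rng.uniform(0.7, 1.3)), "median": float(rng.uniform(0.08, 0.25))}
        recipe = FixtureRecipe(
            S=S,
            equilibrium_family=fam,
            family_params=fp,
            y_profile="geometric",
            y_params={
                "y1": float(rng.uniform(0.1, 0.3)),
                "ratio": float(rng.uniform(0.2, 0.5)),
            },
        )
        specs.append(make_spec(recipe))
    return specs
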