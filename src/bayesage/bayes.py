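"""Posterior age densities given an observed phase, and HPD age ranges.

Bayes' theorem combines the Gompertz prior age-at-death density f(a) with the
transition-model likelihood Pr(c_j | a):

    Pr(a | c_j) = Pr(c_j | a) f(a) / integral Pr(c_j | x) f(x) dx

The one-dimensional integral is evaluated by trapezoid quadrature on a uniform
age grid (default 0.01-year step from the adult floor to 130), so the
normalization is exact by construction up to quadrature error.  Age ranges are
highest-posterior-density (HPD) regions: the shortest interval holding the
stated coverage, found by a waterline threshold on the density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gompertz import GompertzParams, density
from .transition import TransitionParams, phase_probability

__all__ = [
    "PosteriorDensity",
    "HPDRange",
    "DegeneratePosteriorError",
    "posterior",
    "hpdr",
    "hpdr_table",
    "hpdr_frame",
]

DEFAULT_AGE_MAX = 130.0
DEFAULT_GRID_STEP = 0.01


class DegeneratePosteriorError(ValueError):
    """Raised when a phase's likelihood is numerically zero on the whole grid."""


@dataclass(frozen=True)
class PosteriorDensity:
    """Gridded, trapezoid-normalized posterior density of age given a phase."""

    phase: int
    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        if dens.shape != grid.shape:
            raise ValueError("density must align with grid")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)

    def mass(self) -> float:
        """Trapezoid integral over the full grid (should be 1)."""
        return float(np.trapezoid(self.density, self.grid))

    def mean(self) -> float:
        """Posterior mean age (internal diagnostic; ranges are the product)."""
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def interval_mass(self, lower: float, upper: float) -> float:
        """Trapezoid mass on [lower, upper] (endpoints snapped to the grid)."""
        sel = (self.grid >= lower) & (self.grid <= upper)
        if sel.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.density[sel], self.grid[sel]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.grid, "density": self.density})


@dataclass(frozen=True)
class HPDRange:
    """Highest-posterior-density age interval for one phase.

    ``lower``/``upper`` are the raw grid endpoints used in all computations;
    ``lower_2dp``/``upper_2dp`` give the 2-decimal display form.
    ``achieved_mass`` is the posterior mass actually inside the region, which
    can exceed the nominal coverage on a discrete grid.
    """

    phase: int
    coverage: float
    lower: float
    upper: float
    achieved_mass: float
    disconnected: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must be in (0, 1)")
        if not (self.lower < self.upper):
            raise ValueError("lower must be < upper")

    @property
    def lower_2dp(self) -> float:
        return round(self.lower, 2)

    @property
    def upper_2dp(self) -> float:
        return round(self.upper, 2)

    def contains(self, age: float) -> bool:
        """Inclusive-endpoint membership test against the unrounded bounds."""
        return self.lower <= age <= self.upper


def posterior(
    prior: GompertzParams,
    trans: TransitionParams,
    phase: int,
    age_max: float = DEFAULT_AGE_MAX,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PosteriorDensity:
    """Posterior density of age-at-death given an observed phase.

    The density is proportional to Pr(c_j | a) f(a), normalized by trapezoid
    quadrature of the same product over [age_offset, age_max].
    """
    if age_max <= prior.age_offset:
        raise ValueError("age_max must exceed the prior's age_offset")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    grid = np.arange(prior.age_offset, age_max + 0.5 * grid_step, grid_step)
    like = np.asarray(phase_probability(trans, grid, phase), dtype=float)
    prior_dens = np.asarray(density(prior, grid), dtype=float)
    unnorm = like * prior_dens
    z = np.trapezoid(unnorm, grid)
    if not (z > 0):
        raise DegeneratePosteriorError(
            f"phase {phase}: likelihood x prior is numerically zero on the grid"
        )
    return PosteriorDensity(phase=phase, grid=grid, density=unnorm / z)


def _region_mass(post: PosteriorDensity, mask: np.ndarray) -> tuple[float, int]:
    """Trapezoid mass of the (possibly disconnected) region where mask holds.

    Returns (mass, number of contiguous runs)."""
    if not mask.any():
        return 0.0, 0
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    stops = np.flatnonzero(~padded[1:] & padded[:-1])
    mass = 0.0
    for s, e in zip(starts, stops):
        if e - s >= 2:
            mass += np.trapezoid(post.density[s:e], post.grid[s:e])
    return float(mass), int(starts.size)


def hpdr(post: PosteriorDensity, coverage: float = 0.90, *, n_bisect: int = 60) -> HPDRange:
    """Extract the highest-posterior-density range at the given coverage.

    Waterline algorithm: bisection finds the largest density threshold c* whose
    super-level set {a : density(a) >= c*} still holds at least ``coverage``
    mass; the reported interval spans the smallest and largest grid ages in
    that set.  Ties at the threshold are included, which can only push the
    achieved mass above the nominal coverage.  A disconnected super-level set
    (multimodal posterior) is reported as its bounding interval with the
    ``disconnected`` flag set.
    """
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    dens = post.density
    lo_c, hi_c = 0.0, float(dens.max())
    # invariant: mass at lo_c >= coverage; mass at hi_c may be below
    for _ in range(n_bisect):
        mid = 0.5 * (lo_c + hi_c)
        mass, _ = _region_mass(post, dens >= mid)
        if mass >= coverage:
            lo_c = mid
        else:
            hi_c = mid
    mask = dens >= lo_c
    mass, n_runs = _region_mass(post, mask)
    idx = np.flatnonzero(mask)
    lower = float(post.grid[idx[0]])
    upper = float(post.grid[idx[-1]])
    if idx[0] == 0:
        lower = float(post.grid[0])  # region touches the age floor exactly
    return HPDRange(
        phase=post.phase,
        coverage=coverage,
        lower=lower,
        upper=upper,
        achieved_mass=mass,
        disconnected=n_runs > 1,
    )


def hpdr_table(
    prior: GompertzParams,
    trans: TransitionParams,
    coverage: float = 0.90,
    age_max: float = DEFAULT_AGE_MAX,
    grid_step: float = DEFAULT_GRID_STEP,
) -> list[HPDRange]:
    """One HPD range per phase (1..n_phases) for a prior/transition pair."""
    return [
        hpdr(posterior(prior, trans, phase, age_max=age_max, grid_step=grid_step),
             coverage)
        for phase in range(1, trans.n_phases + 1)
    ]


def hpdr_frame(ranges: Sequence[HPDRange]) -> pd.DataFrame:
    """2-decimal display table: phase, lower, upper, coverage, achieved mass."""
    return pd.DataFrame({
        "phase": [r.phase for r in ranges],
        "lower": [r.lower_2dp for r in ranges],
        "upper": [r.upper_2dp for r in ranges],
        "coverage": [r.coverage for r in ranges],
        "achieved_mass": [round(r.achieved_mass, 6) for r in ranges],
        "disconnected": [r.disconnected for r in ranges],
    })
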