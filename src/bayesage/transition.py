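"""Transition analysis: log-age cumulative probit over ordinal skeletal phases.

An individual of age ``a`` is observed in ordinal phase j (1..K, e.g. the
8-phase auricular-surface scoring) with probability

    Pr(c_j | a) = Phi((tau_j - ln a) / sigma) - Phi((tau_{j-1} - ln a) / sigma)

where tau_1 < ... < tau_{K-1} are transition locations on the natural-log-age
scale (tau_0 = -inf, tau_K = +inf) and sigma is a spread shared across
transitions (the "proportional" form standard in transition analysis;
per-transition spreads are weakly identified with 8 phases at modest n).
exp(tau_j) is the median age of the j -> j+1 transition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .gompertz import FitError

__all__ = [
    "TransitionParams",
    "PhaseObservation",
    "TransitionFit",
    "phase_probability",
    "phase_probability_matrix",
    "transition_age",
    "fit_transition",
    "read_phase_csv",
    "observations_to_arrays",
]

_MIN_ADULT_AGE = 18.0


@dataclass(frozen=True)
class TransitionParams:
    """Cumulative-probit transition parameters on the log-age scale.

    Parameters
    ----------
    tau : tuple of float
        Strictly increasing transition locations (ln years); length K-1 for a
        K-phase system.  An empty tuple describes a degenerate single-phase
        system whose only phase has probability 1 at every age.
    sigma : float
        Common spread on the log-age scale, > 0.
    """

    tau: tuple[float, ...]
    sigma: float

    def __post_init__(self) -> None:
        tau = tuple(float(x) for x in self.tau)
        if len(tau) > 1 and np.any(np.diff(tau) <= 0):
            raise ValueError(f"tau must be strictly increasing, got {tau}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        object.__setattr__(self, "tau", tau)

    @property
    def n_phases(self) -> int:
        return len(self.tau) + 1

    def to_dict(self) -> dict:
        return {"n_phases": self.n_phases, "tau": list(self.tau), "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionParams":
        return cls(tau=tuple(d["tau"]), sigma=float(d["sigma"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PhaseObservation:
    """A documented age-at-death paired with an observed ordinal phase."""

    age: float
    phase: int

    def __post_init__(self) -> None:
        if self.age < _MIN_ADULT_AGE:
            raise ValueError(f"age must be >= {_MIN_ADULT_AGE}, got {self.age}")
        if int(self.phase) != self.phase or self.phase < 1:
            raise ValueError(f"phase must be a positive integer, got {self.phase}")
        object.__setattr__(self, "phase", int(self.phase))


def _check_phase(params: TransitionParams, phase: int) -> None:
    if not (1 <= phase <= params.n_phases):
        raise ValueError(f"phase must be in 1..{params.n_phases}, got {phase}")


def phase_probability(params: TransitionParams, age, phase: int) -> np.ndarray | float:
    """Pr(phase | age) under the cumulative probit; vectorized over age."""
    _check_phase(params, phase)
    age = np.asarray(age, dtype=float)
    la = np.log(age)
    tau = params.tau
    upper = norm.cdf((tau[phase - 1] - la) / params.sigma) if phase <= len(tau) else np.ones_like(la)
    lower = norm.cdf((tau[phase - 2] - la) / params.sigma) if phase >= 2 else np.zeros_like(la)
    out = upper - lower
    return out if out.ndim else float(out)


def phase_probability_matrix(params: TransitionParams, age) -> np.ndarray:
    """All phase probabilities at once: shape (n_ages, n_phases), rows sum to 1."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    la = np.log(age)[:, None]
    z = (np.asarray(params.tau)[None, :] - la) / params.sigma
    cdf = np.concatenate(
        [np.zeros((la.size, 1)), norm.cdf(z), np.ones((la.size, 1))], axis=1
    )
    return np.diff(cdf, axis=1)


def transition_age(params: TransitionParams, j: int) -> float:
    """Median age (years) of the j -> j+1 transition, exp(tau_j)."""
    if not (1 <= j <= len(params.tau)):
        raise ValueError(f"transition index must be in 1..{len(params.tau)}, got {j}")
    return float(np.exp(params.tau[j - 1]))


@dataclass(frozen=True)
class TransitionFit:
    """Result of a cumulative-probit transition-analysis fit."""

    params: TransitionParams
    loglik: float
    converged: bool
    n_obs: int
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(loglik=self.loglik, converged=self.converged, n_obs=self.n_obs,
                 warnings=list(self.warnings))
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def observations_to_arrays(
    observations: Sequence[PhaseObservation],
) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array([o.age for o in observations], dtype=float)
    phases = np.array([o.phase for o in observations], dtype=int)
    return ages, phases


def _initial_theta(la: np.ndarray, phases: np.ndarray, n_phases: int) -> np.ndarray:
    """Seed tau at log-midpoints between mean ages of adjacent observed phases,
    sigma at the pooled within-phase SD of ln age."""
    means = np.full(n_phases, np.nan)
    for j in range(1, n_phases + 1):
        sel = phases == j
        if sel.any():
            means[j - 1] = la[sel].mean()
    # interpolate over unobserved phases so midpoints stay defined and ordered
    idx = np.arange(n_phases)
    ok = ~np.isnan(means)
    means = np.interp(idx, idx[ok], means[ok])
    tau0 = 0.5 * (means[:-1] + means[1:])
    # enforce strict ordering of the seed
    tau0 = np.maximum.accumulate(tau0 + 1e-6 * idx[:-1])
    resid = la - means[phases - 1]
    sigma0 = max(float(np.std(resid)), 0.05)
    gaps = np.diff(tau0)
    return np.concatenate([[tau0[0]], np.log(np.maximum(gaps, 1e-3)), [np.log(sigma0)]])


def fit_transition(
    observations: Sequence[PhaseObservation] | pd.DataFrame,
    n_phases: int = 8,
    *,
    tol: float = 1e-10,
) -> TransitionFit:
    """Maximum-likelihood cumulative-probit fit to (age, phase) observations.

    The ordering constraint tau_1 < ... < tau_{K-1} is enforced by optimizing
    tau_1 plus positive log-gaps; sigma is optimized as ln sigma.  Phases with
    no observations are retained in the model (their boundaries are estimated,
    possibly poorly, and a warning is recorded on the fit).

    Raises
    ------
    ValueError
        On empty input or phases outside 1..n_phases.
    FitError
        If the optimizer fails to converge.
    """
    if n_phases < 2:
        raise ValueError("fitting requires at least 2 phases")
    if isinstance(observations, pd.DataFrame):
        ages = observations["age"].to_numpy(dtype=float)
        phases = observations["phase"].to_numpy(dtype=int)
    else:
        if len(observations) == 0:
            raise ValueError("observations must be non-empty")
        ages, phases = observations_to_arrays(observations)
    if ages.size == 0:
        raise ValueError("observations must be non-empty")
    if phases.min() < 1 or phases.max() > n_phases:
        raise ValueError(f"phases must lie in 1..{n_phases}")
    if np.any(ages < _MIN_ADULT_AGE):
        raise ValueError(f"ages must be >= {_MIN_ADULT_AGE}")

    fit_warnings: list[str] = []
    occupied = np.isin(np.arange(1, n_phases + 1), phases)
    if not occupied.all():
        empty = [int(j) for j in np.arange(1, n_phases + 1)[~occupied]]
        fit_warnings.append(
            f"phases {empty} have no observations; their transition boundaries "
            "are weakly identified"
        )
        warnings.warn(fit_warnings[-1], stacklevel=2)

    la = np.log(ages)
    n = la.size
    eps = 1e-300

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, float]:
        tau = np.concatenate([[theta[0]], theta[0] + np.cumsum(np.exp(theta[1:-1]))])
        return tau, float(np.exp(theta[-1]))

    def nll(theta: np.ndarray) -> float:
        tau, sigma = unpack(theta)
        z = (tau[None, :] - la[:, None]) / sigma
        cdf = np.concatenate(
            [np.zeros((n, 1)), norm.cdf(z), np.ones((n, 1))], axis=1
        )
        p = cdf[np.arange(n), phases] - cdf[np.arange(n), phases - 1]
        return -np.sum(np.log(np.maximum(p, eps))) / n

    x0 = _initial_theta(la, phases, n_phases)
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": tol, "maxiter": 50_000, "maxfev": 50_000,
                 "adaptive": True},
    )
    if not res.success:
        raise FitError(f"transition fit did not converge: {res.message}", diagnostics=res)
    tau, sigma = unpack(res.x)
    if sigma < 1e-4 or np.any(np.diff(tau) < 1e-8):
        fit_warnings.append(
            "near-degenerate solution (possible complete separation between phases)"
        )
        warnings.warn(fit_warnings[-1], stacklevel=2)
    params = TransitionParams(tau=tuple(tau), sigma=sigma)
    return TransitionFit(
        params=params,
        loglik=float(-res.fun * n),
        converged=bool(res.success),
        n_obs=int(n),
        warnings=tuple(fit_warnings),
    )


def read_phase_csv(path: str | Path) -> list[PhaseObservation]:
    """Read phase observations from CSV with columns ``age,phase``."""
    df = pd.read_csv(path, comment="#")
    missing = {"age", "phase"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    obs = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            obs.append(PhaseObservation(age=float(row.age), phase=int(row.phase)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad record at data row {i}: {exc}") from exc
    return obs
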