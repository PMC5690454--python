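"""Hold-out coverage evaluation of HPD age ranges with exact binomial tests.

Each hold-out individual (documented age, assigned phase) is a *success* if
their age falls inside their phase's HPD range (inclusive endpoints, compared
on unrounded bounds).  Realized coverage is tested against the nominal level
with an exact cumulative binomial test; the headline p-value is the lower
tail P(X <= successes | n, nominal) — "does the coverage fall short of
nominal?" — with the exact two-sided value reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .bayes import HPDRange
from .transition import PhaseObservation

__all__ = [
    "PhaseCoverage",
    "CoverageReport",
    "classify",
    "binomial_coverage_test",
    "coverage_report",
]


@dataclass(frozen=True)
class PhaseCoverage:
    """Success/failure tally for one phase; p_success is None when untested."""

    phase: int
    n_successes: int
    n_failures: int

    @property
    def n(self) -> int:
        return self.n_successes + self.n_failures

    @property
    def p_success(self) -> float | None:
        return None if self.n == 0 else self.n_successes / self.n


@dataclass(frozen=True)
class CoverageReport:
    """Per-phase and pooled realized coverage with exact binomial tests."""

    per_phase: tuple[PhaseCoverage, ...]
    nominal_coverage: float
    p_value: float            # lower tail: P(X <= successes | n, nominal)
    p_value_two_sided: float

    @property
    def total_successes(self) -> int:
        return sum(p.n_successes for p in self.per_phase)

    @property
    def total_failures(self) -> int:
        return sum(p.n_failures for p in self.per_phase)

    @property
    def p_success_overall(self) -> float:
        return self.total_successes / (self.total_successes + self.total_failures)

    def per_phase_frame(self, sample: str = "") -> pd.DataFrame:
        """Long table mirroring a per-phase success/failure breakdown."""
        rows = [
            {
                "sample": sample,
                "phase": p.phase,
                "successes": p.n_successes,
                "failures": p.n_failures,
                "p_success": None if p.p_success is None else round(p.p_success, 2),
            }
            for p in self.per_phase
        ]
        return pd.DataFrame(rows)

    def summary_frame(self, sample: str = "") -> pd.DataFrame:
        """One-row pooled summary with both binomial p-values."""
        return pd.DataFrame([{
            "sample": sample,
            "coverage": self.nominal_coverage,
            "successes": self.total_successes,
            "failures": self.total_failures,
            "p_value_lower": self.p_value,
            "p_value_two_sided": self.p_value_two_sided,
            "p_success": round(self.p_success_overall, 4),
        }])


def classify(
    holdout: Sequence[PhaseObservation],
    ranges: Sequence[HPDRange],
) -> dict[int, PhaseCoverage]:
    """Partition hold-out observations into per-phase success/failure counts.

    An observation succeeds iff ``lower <= age <= upper`` for its phase's
    range.  Phases present in ``ranges`` but absent from the hold-out get a
    (0, 0) tally.  An observation whose phase has no range raises ValueError.
    """
    by_phase: dict[int, HPDRange] = {r.phase: r for r in ranges}
    succ = {p: 0 for p in by_phase}
    fail = {p: 0 for p in by_phase}
    for obs in holdout:
        rng = by_phase.get(obs.phase)
        if rng is None:
            raise ValueError(f"no HPD range supplied for phase {obs.phase}")
        if rng.contains(obs.age):
            succ[obs.phase] += 1
        else:
            fail[obs.phase] += 1
    return {
        p: PhaseCoverage(phase=p, n_successes=succ[p], n_failures=fail[p])
        for p in sorted(by_phase)
    }


def binomial_coverage_test(
    successes: int, failures: int, nominal: float
) -> tuple[float, float]:
    """Exact cumulative binomial test of realized vs nominal coverage.

    Returns ``(p_success, p_value)`` where p_value is the lower-tail
    probability P(X <= successes | n, nominal) under Binomial(n, nominal):
    small values mean the ranges cover fewer individuals than designed.
    """
    n = successes + failures
    if n <= 0:
        raise ValueError("at least one trial is required")
    if not (0 < nominal < 1):
        raise ValueError("nominal coverage must be in (0, 1)")
    p_success = successes / n
    p_value = float(stats.binom.cdf(successes, n, nominal))
    return p_success, p_value


def coverage_report(
    holdout: Sequence[PhaseObservation],
    ranges: Sequence[HPDRange],
    nominal: float = 0.90,
) -> CoverageReport:
    """Full coverage evaluation: per-phase tallies plus pooled exact tests.

    Pooling treats every hold-out individual as one Bernoulli trial at the
    nominal coverage, regardless of phase; empty phases are reported with
    (0, 0) counts and excluded from the pool by construction.
    """
    per_phase = classify(holdout, ranges)
    s = sum(p.n_successes for p in per_phase.values())
    f = sum(p.n_failures for p in per_phase.values())
    _, p_lower = binomial_coverage_test(s, f, nominal)
    p_two = float(stats.binomtest(s, s + f, nominal, alternative="two-sided").pvalue)
    return CoverageReport(
        per_phase=tuple(per_phase[p] for p in sorted(per_phase)),
        nominal_coverage=nominal,
        p_value=p_lower,
        p_value_two_sided=p_two,
    )
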