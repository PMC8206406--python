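"""Exposure-by-status 2x2 tables, Fisher's exact test, and bootstrap
odds-ratio distributions.

The effect size throughout is the sample odds ratio (a*d)/(b*c) from the
exposure-by-status table; when any cell is zero the Haldane-Anscombe
correction (+0.5 to every cell) is applied to the odds ratio only.  The
two-sided p-value follows the point-probability rule: the total probability,
under the hypergeometric distribution with margins fixed, of every table
whose point probability does not exceed that of the observed table.  A
bootstrap of the whole cohort draw (``reps`` independent resamples of ``n``
members per arm) turns the single test into a sampling distribution of odds
ratios, summarized by its median and 2.5/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class Table2x2:
    """Exposure-by-arm counts: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise AssociationError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    p_value: float
    table: Table2x2
    replicate_index: int = 0
    n: int | None = None


@dataclass(frozen=True)
class BootstrapSummary:
    """Summary of a replicate odds-ratio distribution."""

    median_or: float
    ci_low: float
    ci_high: float
    n_nonsignificant: int
    reps: int
    n: int | None = None
    variant: str | None = None
    matched: bool | None = None
    alpha: float = 0.05

    @property
    def ci_range(self) -> float:
        return self.ci_high - self.ci_low


def contingency(case_exposed: Sequence[bool] | np.ndarray,
                control_exposed: Sequence[bool] | np.ndarray) -> Table2x2:
    """Count exposure flags into the 2x2 table; empty arms are an error."""
    case_exposed = np.asarray(case_exposed, dtype=bool)
    control_exposed = np.asarray(control_exposed, dtype=bool)
    if case_exposed.size == 0 or control_exposed.size == 0:
        raise AssociationError("contingency requires a non-empty case and control arm")
    a = int(case_exposed.sum())
    c = int(control_exposed.sum())
    return Table2x2(a, case_exposed.size - a, c, control_exposed.size - c)


def sample_odds_ratio(t: Table2x2) -> float:
    """(a*d)/(b*c), with +0.5 to all cells iff any cell is zero."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact(t: Table2x2, replicate_index: int = 0,
                 n: int | None = None) -> AssociationResult:
    """Fisher's exact test on a 2x2 table with positive margins.

    The p-value conditions on both margins (hypergeometric, two-sided by the
    point-probability rule); the reported odds ratio is the sample odds
    ratio, not the conditional MLE.
    """
    if min(t.margins()) == 0:
        raise AssociationError(f"table has a zero margin: {t}")
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return AssociationResult(sample_odds_ratio(t), float(min(p, 1.0)), t,
                             replicate_index=replicate_index, n=n)


def odds_ratio_from_prevalence(p1: float, p0: float) -> float:
    """Population odds ratio implied by two exposure prevalences."""
    if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0):
        raise AssociationError("prevalences must lie strictly inside (0, 1)")
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


def prevalence_from_odds_ratio(p1: float, theta: float) -> float:
    """Control prevalence p0 such that the p1-vs-p0 odds ratio equals theta."""
    if not 0.0 < p1 < 1.0 or theta <= 0.0:
        raise AssociationError("need 0 < p1 < 1 and theta > 0")
    q = (p1 / (1.0 - p1)) / theta
    return q / (1.0 + q)


def bootstrap_association(case_exposed: Sequence[bool] | np.ndarray,
                          control_exposed: Sequence[bool] | np.ndarray,
                          n: int, reps: int = 200,
                          seed: int | np.random.Generator | None = None,
                          replace: bool = True) -> list[AssociationResult]:
    """Bootstrap the cohort draw: ``reps`` resamples of ``n`` members per arm.

    Each replicate draws ``n`` members (with replacement by default) from
    each arm's exposure flags, forms the 2x2 table and runs Fisher's exact
    test.  ``replace=False`` switches to subsampling without replacement and
    requires ``n`` to be at most each population size.
    """
    case_exposed = np.asarray(case_exposed, dtype=bool)
    control_exposed = np.asarray(control_exposed, dtype=bool)
    if case_exposed.size == 0 or control_exposed.size == 0:
        raise AssociationError("both populations must be non-empty")
    if n <= 0:
        raise AssociationError("n must be positive")
    if not replace and (n > case_exposed.size or n > control_exposed.size):
        raise AssociationError(
            f"n={n} exceeds a population size under sampling without replacement"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    results = []
    for rep in range(reps):
        if replace:
            cs = case_exposed[rng.integers(0, case_exposed.size, size=n)]
            ks = control_exposed[rng.integers(0, control_exposed.size, size=n)]
        else:
            cs = case_exposed[rng.choice(case_exposed.size, size=n, replace=False)]
            ks = control_exposed[rng.choice(control_exposed.size, size=n, replace=False)]
        results.append(fisher_exact(contingency(cs, ks), replicate_index=rep, n=n))
    return results


def simulate_two_arm_trials(p_case: float, p_control: float, n: int,
                            reps: int = 200,
                            seed: int | np.random.Generator | None = None
                            ) -> list[AssociationResult]:
    """Replicated two-arm Bernoulli-exposure experiments at fixed prevalences.

    Each replicate draws ``n`` Bernoulli(p_case) exposures for the case arm
    and ``n`` Bernoulli(p_control) for the control arm, then runs Fisher's
    exact test on the resulting table.  This is the analytic-prevalence
    counterpart of :func:`bootstrap_association`, used to reproduce
    association statistics directly from published prevalences.
    """
    for p in (p_case, p_control):
        if not 0.0 < p < 1.0:
            raise AssociationError("prevalences must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = rng.binomial(n, p_case, size=reps)
    c = rng.binomial(n, p_control, size=reps)
    return [
        fisher_exact(Table2x2(int(ai), n - int(ai), int(ci), n - int(ci)),
                     replicate_index=i, n=n)
        for i, (ai, ci) in enumerate(zip(a, c))
    ]


def summarize_replicates(results: Sequence[AssociationResult],
                         alpha: float = 0.05, variant: str | None = None,
                         matched: bool | None = None) -> BootstrapSummary:
    """Median and 95% percentile interval of the replicate odds ratios,
    plus the count of non-significant replicates (two-sided p >= alpha)."""
    if len(results) < 2:
        raise AssociationError("need at least 2 replicates to summarize")
    ors = np.array([r.odds_ratio for r in results], dtype=float)
    ps = np.array([r.p_value for r in results], dtype=float)
    lo, hi = np.percentile(ors, [2.5, 97.5])
    ns = {r.n for r in results}
    return BootstrapSummary(
        median_or=float(np.median(ors)), ci_low=float(lo), ci_high=float(hi),
        n_nonsignificant=int((ps >= alpha).sum()), reps=len(results),
        n=ns.pop() if len(ns) == 1 else None, variant=variant, matched=matched,
        alpha=alpha,
    )


def ci_width_ratio(s_small_n: BootstrapSummary, s_large_n: BootstrapSummary) -> float:
    """How much wider the replicate-OR 95% interval is at the smaller n."""
    if s_large_n.ci_range == 0:
        raise AssociationError("denominator summary has zero CI width")
    return s_small_n.ci_range / s_large_n.ci_range
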