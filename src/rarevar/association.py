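"""2x2 burden statistics: right-tailed Fisher exact test, sample odds
ratio, confidence intervals and Bonferroni correction.

The right tail is taken because the alternative of interest is an
excess of carriers among cases.  The reported odds ratio is the plain
cross-product (a*d)/(b*c); confidence intervals are available as Woolf
log-interval (default, with Haldane 0.5 correction for zero cells) or
as the exact conditional interval from the noncentral hypergeometric
tail equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import optimize
from scipy.stats import hypergeom, nchypergeom_fisher, norm

from .errors import DomainError


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_carriers(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class AssociationResult:
    a: int
    b: int
    c: int
    d: int
    p_right: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_corrected: float
    ci_method: str = "woolf_log"


def fisher_right(table: ContingencyTable) -> float:
    """Right-tailed Fisher exact P: hypergeometric tail sum over tables
    with at least the observed number of case carriers at fixed margins."""
    if table.n_cases == 0 or table.n_controls == 0:
        raise DomainError("both margins must be positive")
    # X ~ Hypergeom(N, K=carriers, n=cases); P(X >= a)
    return float(
        hypergeom.sf(table.a - 1, table.n_total, table.n_carriers, table.n_cases)
    )


def sample_odds_ratio(table: ContingencyTable) -> float:
    """Cross-product odds ratio (a*d)/(b*c); +inf for a > 0 with c = 0."""
    if table.a == 0 and table.c == 0:
        raise DomainError("degenerate table: no carriers in either group")
    if table.b == 0 or table.c == 0:
        return math.inf
    return (table.a * table.d) / (table.b * table.c)


def _woolf_ci(table: ContingencyTable, level: float) -> tuple[float, float]:
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:  # Haldane-Anscombe correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def _conditional_ci(table: ContingencyTable, level: float) -> tuple[float, float]:
    """Exact conditional CI: endpoints solve the noncentral
    hypergeometric tail equations at alpha/2 each side."""
    alpha = 1 - level
    a = table.a
    N, K, n = table.n_total, table.n_carriers, table.n_cases
    a_min, a_max = max(0, K - table.n_controls), min(K, n)

    def upper_tail(psi):  # P(X >= a | psi)
        return nchypergeom_fisher.sf(a - 1, N, K, n, psi)

    def lower_tail(psi):  # P(X <= a | psi)
        return nchypergeom_fisher.cdf(a, N, K, n, psi)

    if a == a_min:
        low = 0.0
    else:
        low = optimize.brentq(
            lambda lp: upper_tail(math.exp(lp)) - alpha / 2, -50, 50, xtol=1e-12
        )
        low = math.exp(low)
    if a == a_max:
        high = math.inf
    else:
        high = optimize.brentq(
            lambda lp: lower_tail(math.exp(lp)) - alpha / 2, -50, 50, xtol=1e-12
        )
        high = math.exp(high)
    return low, high


def odds_ratio_ci(
    table: ContingencyTable,
    level: float = 0.95,
    method: Literal["woolf_log", "exact_conditional"] = "woolf_log",
) -> tuple[float, float]:
    if not 0 < level < 1:
        raise DomainError("level must be in (0, 1)")
    if method == "woolf_log":
        return _woolf_ci(table, level)
    if method == "exact_conditional":
        return _conditional_ci(table, level)
    raise DomainError(f"unknown CI method: {method!r}")


def bonferroni(p: float, m: int) -> float:
    """min(1, m*p)."""
    if not 0 < p <= 1:
        raise DomainError("p must be in (0, 1]")
    if m < 1:
        raise DomainError("m must be >= 1")
    return min(1.0, m * p)


def associate(
    table: ContingencyTable,
    bonferroni_m: int = 1,
    ci_level: float = 0.95,
    ci_method: Literal["woolf_log", "exact_conditional"] = "woolf_log",
) -> AssociationResult:
    """Full 2x2 analysis bundle for one carrier comparison."""
    p = fisher_right(table)
    ci_low, ci_high = odds_ratio_ci(table, ci_level, ci_method)
    return AssociationResult(
        a=table.a,
        b=table.b,
        c=table.c,
        d=table.d,
        p_right=p,
        odds_ratio=sample_odds_ratio(table),
        ci_low=ci_low,
        ci_high=ci_high,
        p_corrected=bonferroni(p, bonferroni_m),
        ci_method=ci_method,
    )
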