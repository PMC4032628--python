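"""Max-enrichment-ratio permutation test.

The statistic is the largest, over the conservation measures, of the
ratio (case carrier proportion) / (control carrier proportion).  Its
null distribution is obtained by permuting case/control labels over
subjects with group sizes fixed; an exact enumeration oracle over
multivariate hypergeometric pattern splits is provided for small
carrier counts.

Conventions (applied identically to observed and permuted data, which
makes the test well-defined even with empty cells): a measure with a
zero control proportion but positive case proportion has ratio +inf; a
measure with both proportions zero has ratio 1.  A permuted statistic
exactly equal to the observed one counts toward the P value (the
conservative choice), and the P value is the plain proportion of
permuted statistics at or above the observed statistic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .conservation import FunctionalMatrix
from .errors import DomainError

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12  # absolute guard for float ties in the >= comparison


@dataclass(frozen=True)
class PermutationResult:
    per_measure_ratios: tuple[float, ...]
    observed_stat: float
    n_permutations: int
    null_geq_count: int
    p_value: float
    seed: int
    mc_standard_error: float


def _ratios_from_counts(
    case_counts: np.ndarray, ctrl_counts: np.ndarray, n_cases: int, n_controls: int
) -> np.ndarray:
    case_prop = case_counts / n_cases
    ctrl_prop = ctrl_counts / n_controls
    out = np.empty(len(case_counts))
    for j in range(len(case_counts)):
        if ctrl_prop[j] == 0:
            out[j] = math.inf if case_prop[j] > 0 else 1.0
        else:
            out[j] = case_prop[j] / ctrl_prop[j]
    return out


def enrichment_ratios(matrix: FunctionalMatrix) -> tuple[float, ...]:
    """Per-measure case/control carrier-proportion ratios."""
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise DomainError("matrix must contain both case and control rows")
    case_counts, ctrl_counts = matrix.column_sums()
    return tuple(
        _ratios_from_counts(case_counts, ctrl_counts, matrix.n_cases, matrix.n_controls)
    )


def permutation_test(
    matrix: FunctionalMatrix, n_permutations: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Label-permutation P value for the max-ratio statistic.

    Each permutation shuffles an index vector over all subjects
    (preserving group sizes) and recomputes the statistic with the same
    zero-cell conventions.  Reproducible given (seed, n_permutations).
    """
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    ratios = enrichment_ratios(matrix)
    observed = max(ratios)

    n = len(matrix.subject_ids)
    n_cases = matrix.n_cases
    n_controls = matrix.n_controls
    # Only rows with a nonzero indicator can change the counts.
    carrier_rows = np.flatnonzero(matrix.indicators.any(axis=1))
    patterns = matrix.indicators[carrier_rows].astype(np.int64)
    totals = patterns.sum(axis=0)

    rng = np.random.default_rng(seed)
    perm = np.arange(n)
    geq = 0
    all_nonfinite = True
    for _ in range(n_permutations):
        rng.shuffle(perm)
        case_mask = perm[carrier_rows] < n_cases
        case_counts = patterns[case_mask].sum(axis=0)
        stat = max(
            _ratios_from_counts(case_counts, totals - case_counts, n_cases, n_controls)
        )
        if math.isfinite(stat):
            all_nonfinite = False
        if stat >= observed - _TIE_EPS:
            geq += 1
    if not math.isfinite(observed) and all_nonfinite:
        logger.warning(
            "observed statistic and every permuted statistic are non-finite; "
            "p_value = 1"
        )
        geq = n_permutations
    p = geq / n_permutations
    return PermutationResult(
        per_measure_ratios=ratios,
        observed_stat=observed,
        n_permutations=n_permutations,
        null_geq_count=geq,
        p_value=p,
        seed=seed,
        mc_standard_error=math.sqrt(p * (1 - p) / n_permutations),
    )


def exact_p(
    matrix: FunctionalMatrix,
    max_carriers: int = 200,
    max_compositions: int = 5_000_000,
) -> float:
    """Exact permutation-null P by enumeration.

    Groups carrier rows into distinct indicator patterns and sums
    multivariate hypergeometric probabilities over every composition of
    pattern counts into the case group.  Feasible only for small
    carrier counts / few distinct patterns; refuses (directing to
    :func:`permutation_test`) beyond the bounds.
    """
    ratios = enrichment_ratios(matrix)
    observed = max(ratios)
    n_cases, n_controls = matrix.n_cases, matrix.n_controls
    N = n_cases + n_controls

    carrier_rows = np.flatnonzero(matrix.indicators.any(axis=1))
    if len(carrier_rows) == 0:
        return 1.0
    if len(carrier_rows) > max_carriers:
        raise DomainError(
            f"{len(carrier_rows)} carriers exceed the enumeration bound "
            f"({max_carriers}); use permutation_test"
        )
    patterns_arr = matrix.indicators[carrier_rows]
    uniq, counts = np.unique(patterns_arr, axis=0, return_counts=True)
    n_comp = int(np.prod(counts + 1))
    if n_comp > max_compositions:
        raise DomainError(
            f"{n_comp} compositions exceed the enumeration bound; "
            "use permutation_test"
        )
    n_noncarriers = N - int(counts.sum())

    def lchoose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    # Vectorized enumeration over the composition grid.
    grids = np.meshgrid(*[np.arange(c + 1) for c in counts], indexing="ij")
    ks = np.stack([g.ravel() for g in grids], axis=1)  # (n_comp, n_patterns)
    s = ks.sum(axis=1)
    feasible = (n_cases - s >= 0) & (n_cases - s <= n_noncarriers)
    ks, s = ks[feasible], s[feasible]
    logp = (
        lchoose(counts[None, :], ks).sum(axis=1)
        + lchoose(n_noncarriers, n_cases - s)
        - lchoose(N, n_cases)
    )
    case_counts = ks @ uniq  # (n_comp, n_measures)
    totals = (counts[:, None] * uniq).sum(axis=0)
    ctrl_counts = totals[None, :] - case_counts

    case_prop = case_counts / n_cases
    ctrl_prop = ctrl_counts / n_controls
    with np.errstate(divide="ignore", invalid="ignore"):
        r = case_prop / ctrl_prop
    r[(ctrl_prop == 0) & (case_prop > 0)] = np.inf
    r[(ctrl_prop == 0) & (case_prop == 0)] = 1.0
    stats = r.max(axis=1)
    hits = stats >= observed - _TIE_EPS
    return float(np.exp(logp[hits]).sum())
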