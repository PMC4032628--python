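"""Synthetic inputs with the statistical structure each stage assumes.

The generators emulate the study designs the analysis modules consume:

* carrier matrices with a controllable per-measure case/control
  enrichment ratio and cross-measure pattern correlation (the binary
  permutation-test input);
* genotype matrices with population structure and a planted set of
  ancestry outliers drawn from a strongly diverged population;
* per-site sequencing QC statistics with violations planted per rule;
* log2 expression matrices with one latent co-expression module.

Defaults mirror the study's conditions: 2,196 cases vs 3,389 controls,
a control carrier rate around 0.27% per measure and case enrichment
near threefold (about 29 carriers in total), 8,210-SNP-scale genotyping
reduced to 1,000 independent SNPs, and a 15,132-gene brain expression
matrix scaled down to 2,000 genes.  All outputs are bit-reproducible
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .ancestry import GenotypeMatrix
from .coexpression import ExpressionMatrix
from .conservation import MEASURES, FunctionalMatrix
from .errors import DomainError
from .filters import CallSiteStats


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of every generator, with study-scale defaults."""

    seed: int = 0
    # carrier / enrichment structure
    n_cases: int = 2196
    n_controls: int = 3389
    carrier_rate_control: float = 9 / 3389
    enrichment_ratio: tuple[float, float, float] = (2.9, 2.4, 2.3)
    measure_correlation: float = 0.8
    # ancestry structure
    n_snps: int = 1000
    n_populations: int = 2
    fst_like_divergence: float = 0.02
    outlier_divergence: float = 0.5
    outlier_fraction: float = 0.0
    n_subjects_genotyped: int = 500
    # expression structure
    n_genes: int = 2000
    n_samples: int = 100
    module_size: int = 300
    factor_loading: float = 0.8
    noise_sd: float = 0.6
    expression_baseline: float = 8.0
    # per-site QC violation rates
    n_sites: int = 1000
    qc_violation_rates: dict = field(
        default_factory=lambda: {
            "missingness": 0.0,
            "low_coverage": 0.0,
            "allele_balance": 0.0,
        }
    )

    def __post_init__(self):
        for name in ("carrier_rate_control", "measure_correlation", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1]")
        for r in self.enrichment_ratio:
            if r < 0:
                raise DomainError("enrichment ratios must be >= 0")
        for rate in self.qc_violation_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise DomainError("QC violation rates must be in [0, 1]")


def gen_functional_matrix(spec: SimulationSpec) -> FunctionalMatrix:
    """Binary carrier matrix with planted per-measure enrichment.

    Per-measure marginal carrier rates are exact by construction:
    controls carry at ``carrier_rate_control``, cases at that rate
    times the per-measure enrichment ratio.  Cross-measure pattern
    correlation is induced by a Gaussian copula — a shared latent
    "functionality" normal per subject mixed with per-measure noise at
    weight ``measure_correlation`` — which reproduces the mostly
    111/110/100/000 row patterns of real carrier tables.
    """
    rates_case = np.array(
        [spec.carrier_rate_control * r for r in spec.enrichment_ratio]
    )
    rates_ctrl = np.full(3, spec.carrier_rate_control)
    if (rates_case > 1).any():
        raise DomainError("case carrier rate exceeds 1; infeasible spec")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    labels = np.zeros(n, dtype=bool)
    labels[: spec.n_cases] = True
    m = spec.measure_correlation
    z0 = rng.standard_normal(n)
    eps = rng.standard_normal((n, 3))
    z = np.sqrt(m) * z0[:, None] + np.sqrt(1 - m) * eps
    cut_case = norm.ppf(1 - rates_case)
    cut_ctrl = norm.ppf(1 - rates_ctrl)
    cuts = np.where(labels[:, None], cut_case[None, :], cut_ctrl[None, :])
    indicators = (z > cuts).astype(np.int8)
    ids = tuple(
        f"{'case' if is_case else 'control'}_{i:06d}"
        for i, is_case in enumerate(labels)
    )
    return FunctionalMatrix(ids, labels, indicators, MEASURES)


def gen_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Genotypes with population structure and planted outliers.

    Ancestral allele frequencies are uniform on [0.1, 0.9]; each
    population's frequencies drift by a Balding-Nichols Beta step of
    magnitude ``fst_like_divergence``.  A fraction of case subjects is
    drawn instead from a strongly diverged population
    (``outlier_divergence``); their ids are recorded on the returned
    matrix for recovery experiments.
    """
    if spec.n_populations < 1:
        raise DomainError("need at least one population")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects_genotyped
    p_anc = rng.uniform(0.1, 0.9, spec.n_snps)

    def drift(p, f):
        if f <= 0:
            return p
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        return np.clip(rng.beta(a, b), 0.01, 0.99)

    pop_freqs = [drift(p_anc, spec.fst_like_divergence) for _ in range(spec.n_populations)]
    outlier_freq = drift(p_anc, spec.outlier_divergence)

    pop_of = rng.integers(0, spec.n_populations, n)
    half = n // 2
    group = tuple("case" if i < half else "control" for i in range(n))
    n_out = int(round(spec.outlier_fraction * half))
    outlier_rows = rng.choice(half, size=n_out, replace=False) if n_out else np.array([], int)
    genotypes = np.empty((n, spec.n_snps))
    for i in range(n):
        freqs = outlier_freq if i in set(outlier_rows) else pop_freqs[pop_of[i]]
        genotypes[i] = rng.binomial(2, freqs)
    ids = tuple(f"subj_{i:05d}" for i in range(n))
    return GenotypeMatrix(
        subject_ids=ids,
        group=group,
        genotypes=genotypes,
        planted_outlier_ids=tuple(ids[i] for i in sorted(outlier_rows)),
    )


def gen_expression(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, list[str], str]:
    """One-factor expression matrix with a planted co-expression module.

    Returns (matrix, module gene ids, target gene id).  Target and
    module genes load on a shared latent factor at ``factor_loading``
    plus Gaussian noise of sd ``noise_sd``; background genes are
    independent noise.  Values are on a log2-like scale around
    ``expression_baseline``.
    """
    if spec.module_size >= spec.n_genes:
        raise DomainError("module_size must be smaller than n_genes")
    rng = np.random.default_rng(spec.seed)
    factor = rng.standard_normal(spec.n_samples)
    values = np.empty((spec.n_genes, spec.n_samples))
    loaded = spec.module_size + 1  # module genes + target (gene 0)
    values[:loaded] = (
        spec.factor_loading * factor[None, :]
        + spec.noise_sd * rng.standard_normal((loaded, spec.n_samples))
    )
    values[loaded:] = rng.standard_normal((spec.n_genes - loaded, spec.n_samples))
    values += spec.expression_baseline
    genes = tuple(f"gene_{i:05d}" for i in range(spec.n_genes))
    samples = tuple(f"sample_{i:04d}" for i in range(spec.n_samples))
    matrix = ExpressionMatrix(genes, samples, values)
    target = genes[0]
    module = list(genes[1:loaded])
    return matrix, module, target


def gen_callsites(
    spec: SimulationSpec, profile: str = "Broad"
) -> tuple[list[CallSiteStats], list[frozenset[str]]]:
    """Per-site QC statistics with violations planted per rule.

    Returns (sites, planted) where ``planted[i]`` is the set of rule
    names site i was built to violate (empty set = clean site).  Clean
    sites are drawn comfortably inside every cutoff; violating sites
    are drawn just past the relevant cutoff only.
    """
    from .core_io import Thresholds

    profile_cfg = Thresholds().qc_profiles[profile]
    rng = np.random.default_rng(spec.seed)
    sites: list[CallSiteStats] = []
    planted: list[frozenset[str]] = []
    rates = spec.qc_violation_rates
    for _ in range(spec.n_sites):
        violations = frozenset(
            rule for rule, rate in rates.items() if rng.random() < rate
        )
        if "missingness" in violations:
            missing = rng.uniform(0.10, 0.5)
        else:
            missing = rng.uniform(0.0, 0.08)
        if "low_coverage" in violations:
            coverage = rng.uniform(1.0, profile_cfg.min_mean_coverage - 0.5)
        else:
            coverage = rng.uniform(profile_cfg.min_mean_coverage + 1, 80.0)
        n_calls = int(rng.integers(2, 9))
        calls = []
        if "allele_balance" in violations:
            n_bad = n_calls // 2 + 1  # strict majority
        else:
            n_bad = 0
        for j in range(n_calls):
            if j < n_bad:
                total = int(rng.integers(profile_cfg.minor_read_min, 60))
                ref = int(
                    np.ceil(total * min(0.99, profile_cfg.balance_of_depth_max + 0.1))
                )
                ref = min(ref, total)
            else:
                total = int(rng.integers(profile_cfg.minor_read_min, 60))
                ref = int(np.floor(total * (profile_cfg.balance_of_depth_max - 0.2)))
                ref = max(ref, 0)
            calls.append((total, ref))
        sites.append(
            CallSiteStats(
                site_profile=profile,
                missing_fraction=float(missing),
                mean_coverage=float(coverage),
                minor_allele_calls=tuple(calls),
            )
        )
        planted.append(violations)
    return sites, planted
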