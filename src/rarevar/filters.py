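"""Inclusion/exclusion rules for the case/control screen.

Three families of rules:

* novel-singleton selection — keep alleles seen exactly once in their
  sequenced cohort, absent from the reference allele sets (dbSNP-style
  and exome-server-style lists supplied locally), and rare;
* exome site QC — missingness, mean coverage, and minor-allele read
  support / allele balance, with per-centre cutoff profiles;
* the index-de-novo rule — the mutation that motivated the screen is
  excluded from the overall burden comparison but kept for the
  deleteriousness (conservation/structure) analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .core_io import Thresholds, VariantRecord
from .errors import ConfigurationError, LookupMissingError

logger = logging.getLogger(__name__)

AlleleKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class ReferenceAlleleSet:
    """A named set of known alleles; membership is exact on all four fields."""

    name: str
    alleles: frozenset[AlleleKey]

    def __contains__(self, key: AlleleKey) -> bool:
        return key in self.alleles

    @classmethod
    def from_tsv(cls, name: str, path: str | Path) -> "ReferenceAlleleSet":
        """Load from a 4-column TSV: chrom, pos, ref, alt (no header)."""
        alleles = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, ref, alt = line.split("\t")[:4]
                alleles.add((chrom, int(pos), ref, alt))
        return cls(name=name, alleles=frozenset(alleles))


@dataclass(frozen=True)
class CallSiteStats:
    """Per-site sequencing QC summary for one exome production centre."""

    site_profile: str  # "Broad" or "Baylor"
    missing_fraction: float
    mean_coverage: float
    minor_allele_calls: tuple[tuple[int, int], ...]  # (reads_total, reference_reads)

    def __post_init__(self):
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        for total, ref in self.minor_allele_calls:
            if ref > total:
                raise ValueError("reference_reads cannot exceed reads_total")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be true iff reasons is empty")


def count_alleles(
    variants: Sequence[VariantRecord], pooled: bool = False
) -> dict[AlleleKey, int]:
    """Allele counts within each variant's sequenced cohort.

    With ``pooled=True`` counts are over the full case+control set
    instead of per sequencing screen.
    """
    counts: dict = {}
    for v in variants:
        key = v.allele_key if pooled else (v.cohort_group.sequencing_set, v.allele_key)
        counts[key] = counts.get(key, 0) + 1
    if pooled:
        return counts
    return counts  # keyed by (sequencing_set, allele_key)


def singleton_decisions(
    variants: Sequence[VariantRecord],
    cohort_allele_counts: Mapping[AlleleKey, int],
    refsets: Sequence[ReferenceAlleleSet],
    thresholds: Thresholds,
    cohort_sizes: Optional[Mapping[str, int]] = None,
) -> list[FilterDecision]:
    """Per-variant novel-singleton decision with failure reasons.

    ``cohort_allele_counts`` maps each variant's allele key to its count
    within the relevant cohort (caller decides per-screen vs pooled; see
    :func:`count_alleles`).  ``cohort_sizes`` optionally maps sequencing
    set name to the number of subjects sequenced, enabling the explicit
    rare-frequency check (allele count / 2n subjects); singletons pass
    it trivially when sizes are not supplied.
    """
    decisions = []
    for v in variants:
        key = v.allele_key
        if key not in cohort_allele_counts:
            raise LookupMissingError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} missing from "
                "cohort_allele_counts"
            )
        count = cohort_allele_counts[key]
        if count < 1:
            raise LookupMissingError(f"allele count must be >= 1, got {count}")
        reasons = []
        if count != 1:
            reasons.append("not_singleton")
        for refset in refsets:
            if key in refset:
                reasons.append(f"in_reference_set:{refset.name}")
        if cohort_sizes is not None:
            n = cohort_sizes.get(v.cohort_group.sequencing_set)
            if n and count / (2 * n) >= thresholds.rare_freq:
                reasons.append("not_rare")
        decisions.append(FilterDecision(keep=not reasons, reasons=tuple(reasons)))
    return decisions


def select_novel_singletons(
    variants: Sequence[VariantRecord],
    cohort_allele_counts: Mapping[AlleleKey, int],
    refsets: Sequence[ReferenceAlleleSet],
    thresholds: Thresholds,
    cohort_sizes: Optional[Mapping[str, int]] = None,
) -> list[VariantRecord]:
    """Retain novel singletons: count exactly 1, in no refset, rare.

    Deterministic and order-preserving.
    """
    decisions = singleton_decisions(
        variants, cohort_allele_counts, refsets, thresholds, cohort_sizes
    )
    return [v for v, d in zip(variants, decisions) if d.keep]


def burden_inclusion(
    variants: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into the burden set and the deleteriousness set.

    The index de novo mutation is excluded from the overall burden
    comparison (it motivated the screen, so counting it would bias the
    burden) but retained when assessing deleteriousness.  Both outputs
    preserve input order.
    """
    burden_set = [v for v in variants if not v.is_index_de_novo]
    conservation_set = list(variants)
    return burden_set, conservation_set


def apply_exome_site_qc(stats: CallSiteStats, thresholds: Thresholds) -> FilterDecision:
    """Exome site QC: missingness, coverage, minor-allele support/balance.

    Rule operators mirror the screening criteria verbatim: missingness
    is excluded at >= 10% (inclusive); coverage at strictly less than
    the profile minimum; the read-support/balance rule fires when a
    strict majority (>50%) of minor-allele calls have fewer reads than
    the profile minimum OR a balance of depth (reference reads / total
    reads) strictly above the profile ceiling.  Reasons accumulate.
    """
    profile = thresholds.qc_profiles.get(stats.site_profile)
    if profile is None:
        raise ConfigurationError(f"unknown QC profile: {stats.site_profile!r}")
    reasons = []
    if stats.missing_fraction >= thresholds.qc_missing_max:
        reasons.append("missingness")
    if stats.mean_coverage < profile.min_mean_coverage:
        reasons.append("low_coverage")
    calls = stats.minor_allele_calls
    if not calls:
        logger.warning(
            "site with no minor allele calls: balance-of-depth rule is vacuous"
        )
    else:
        bad = sum(
            1
            for total, ref in calls
            if total < profile.minor_read_min
            or (total > 0 and ref / total > profile.balance_of_depth_max)
        )
        if bad * 2 > len(calls):  # strict majority; a tie keeps the site
            reasons.append("allele_balance")
    return FilterDecision(keep=not reasons, reasons=tuple(reasons))
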