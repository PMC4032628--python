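"""PCA-based ancestry matching QC.

Genotype dosages (0/1/2, NaN for missing) are mean-imputed per SNP,
standardised, and decomposed by SVD.  Subjects whose leading
principal-component scores lie more than k interquartile ranges above
the third quartile (default k = 5, first 3 components) are flagged as
ancestry outliers.  A two-sided variant and a joint distance-from-median
variant of the rule are also provided, since the one-sided per-component
rule is one of several defensible readings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix; NaN marks missing genotypes."""

    subject_ids: tuple[str, ...]
    group: tuple[str, ...]  # "case" / "control" per subject
    genotypes: np.ndarray  # float array, entries in {0,1,2} or NaN
    planted_outlier_ids: tuple[str, ...] = ()  # set by synthetic generators

    def __post_init__(self):
        n = len(self.subject_ids)
        if len(self.group) != n or self.genotypes.shape[0] != n:
            raise ValueError("inconsistent genotype matrix dimensions")
        if np.isnan(self.genotypes).all(axis=0).any():
            raise ValueError("a SNP with all calls missing is not allowed")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.genotypes,
            index=pd.Index(self.subject_ids, name="subject_id"),
        )
        df.insert(0, "group", self.group)
        df.to_csv(path, sep="\t", na_rep=".")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="subject_id", na_values=".")
        group = tuple(df.pop("group"))
        return cls(
            subject_ids=tuple(df.index.astype(str)),
            group=group,
            genotypes=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray  # descending, non-negative
    scores: np.ndarray  # subjects x components
    n_components_retained: int


def run_pca(genotypes: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Principal components of the standardized genotype matrix.

    Missing calls are mean-imputed per SNP; columns are centred and
    scaled to unit variance (zero-variance columns dropped with a
    warning).  Deterministic up to sign; the sign of each component is
    fixed so that its largest-magnitude SNP loading is positive.
    """
    X = np.asarray(genotypes.genotypes, dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise DomainError("PCA needs at least 2 subjects and 2 SNPs")
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance SNP column(s)", (~keep).sum())
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigenvalues = S**2 / (n - 1)
    scores = U * S
    k = min(n_components, len(S))
    return PcaResult(
        eigenvalues=eigenvalues, scores=scores, n_components_retained=k
    )


def iqr_outlier_filter(
    pca: PcaResult,
    subject_ids: Sequence[str],
    k: float = 5.0,
    n_pcs: int = 3,
    mode: str = "above_q3",
    reference_ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Subjects beyond k IQRs of the component-score quartiles.

    Quartiles use linear interpolation between order statistics and are
    computed over ``reference_ids`` (the study-population cluster) when
    given, else over all subjects.  Modes:

    * ``above_q3`` — exclude score > Q3 + k*IQR on any of the first
      n_pcs components (the default, one-sided rule);
    * ``two_sided`` — additionally exclude score < Q1 - k*IQR;
    * ``distance`` — exclude on Euclidean distance from the
      component-wise median, thresholded at Q3_d + k*IQR_d of the
      distance distribution.
    """
    if k <= 0:
        raise DomainError("k must be positive")
    if n_pcs > pca.scores.shape[1]:
        raise DomainError("n_pcs exceeds retained components")
    scores = pca.scores[:, :n_pcs]
    if scores.shape[0] == 0:
        raise DomainError("empty score set")
    subject_ids = list(subject_ids)
    if reference_ids is not None:
        ref_set = set(reference_ids)
        ref_mask = np.array([s in ref_set for s in subject_ids])
        if not ref_mask.any():
            raise DomainError("no reference subjects found")
    else:
        ref_mask = np.ones(len(subject_ids), dtype=bool)

    if mode == "distance":
        med = np.median(scores[ref_mask], axis=0)
        d = np.sqrt(((scores - med[None, :]) ** 2).sum(axis=1))
        q1, q3 = np.quantile(d[ref_mask], [0.25, 0.75])
        out = d > q3 + k * (q3 - q1)
    elif mode in ("above_q3", "two_sided"):
        q1 = np.quantile(scores[ref_mask], 0.25, axis=0)
        q3 = np.quantile(scores[ref_mask], 0.75, axis=0)
        iqr = q3 - q1
        out = (scores > q3 + k * iqr).any(axis=1)
        if mode == "two_sided":
            out |= (scores < q1 - k * iqr).any(axis=1)
    else:
        raise DomainError(f"unknown mode: {mode!r}")
    return [s for s, o in zip(subject_ids, out) if o]
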