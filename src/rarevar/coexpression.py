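"""Target-gene vs gene-module co-expression contrast.

Spearman correlations between a target gene's expression profile and
every gene of a module are contrasted with its correlations to a
background set (by default all other genes on the array) with a
two-sided Wilcoxon rank-sum test.  Kernel-density export of the
correlation-coefficient distributions and a deterministic top-k
co-expressed gene list support downstream reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, LookupMissingError


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 expression values."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("value matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            raise LookupMissingError(f"gene {gene!r} not in matrix") from None

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.sample_ids),
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(
            gene_ids=tuple(df.index.astype(str)),
            sample_ids=tuple(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class CoexpressionResult:
    target: str
    module_rhos: np.ndarray
    background_rhos: np.ndarray
    median_module: float
    median_background: float
    wilcoxon_p: float
    n_module_used: int
    n_module_missing: int


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def spearman_profile(
    matrix: ExpressionMatrix, target: str, gene_set: Sequence[str]
) -> pd.Series:
    """Spearman rho of the target against each gene of the set.

    Ties get average ranks.  Genes absent from the matrix are skipped;
    the returned Series is indexed by the genes actually used, so the
    number skipped is ``len(gene_set) - len(result)``.
    """
    if matrix.n_samples < 3:
        raise DomainError("need at least 3 samples for correlation")
    t = matrix.row(target)
    if np.ptp(t) == 0:
        raise DomainError("target expression is constant; correlation undefined")
    present = [g for g in gene_set if g in set(matrix.gene_ids)]
    if not present:
        return pd.Series(dtype=float, name=f"rho_{target}")
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    sub = matrix.values[[idx[g] for g in present]]
    tr = stats.rankdata(t)
    tr = (tr - tr.mean()) / tr.std()
    ranks = _rank_rows(sub)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhos = centered @ tr / (len(t) * sd)
    rhos[sd == 0] = np.nan  # constant gene: undefined, reported as NaN
    return pd.Series(rhos, index=present, name=f"rho_{target}")


def module_contrast(
    matrix: ExpressionMatrix,
    target: str,
    module: Iterable[str],
    background: Optional[Iterable[str]] = None,
    exclude_module_from_background: bool = False,
) -> CoexpressionResult:
    """Two-sided Wilcoxon rank-sum contrast of module vs background rhos.

    ``background=None`` means all matrix genes except the target
    (module genes retained in the background unless
    ``exclude_module_from_background``).  Uses the exact null
    distribution for combined n <= 50 without ties, else the
    tie-corrected normal approximation.
    """
    module = [g for g in module if g != target]
    if background is None:
        background = [g for g in matrix.gene_ids if g != target]
    else:
        background = [g for g in background if g != target]
    if exclude_module_from_background:
        mset = set(module)
        background = [g for g in background if g not in mset]
    mod_rhos = spearman_profile(matrix, target, module).dropna()
    bg_rhos = spearman_profile(matrix, target, background).dropna()
    if len(mod_rhos) == 0 or len(bg_rhos) == 0:
        raise DomainError("empty module or background after intersection")
    n_total = len(mod_rhos) + len(bg_rhos)
    values = np.concatenate([mod_rhos, bg_rhos])
    method = "exact" if (n_total <= 50 and len(np.unique(values)) == n_total) else "asymptotic"
    res = stats.mannwhitneyu(
        mod_rhos, bg_rhos, alternative="two-sided", method=method
    )
    return CoexpressionResult(
        target=target,
        module_rhos=mod_rhos.to_numpy(),
        background_rhos=bg_rhos.to_numpy(),
        median_module=float(np.median(mod_rhos)),
        median_background=float(np.median(bg_rhos)),
        wilcoxon_p=float(res.pvalue),
        n_module_used=len(mod_rhos),
        n_module_missing=len(module) - len(mod_rhos),
    )


def top_coexpressed(matrix: ExpressionMatrix, target: str, k: int) -> list[str]:
    """The k genes most positively correlated with the target.

    Ties are broken by gene id for determinism; the target itself is
    excluded.
    """
    if k <= 0:
        raise DomainError("k must be positive")
    others = [g for g in matrix.gene_ids if g != target]
    if k > len(others):
        raise DomainError("k must be smaller than the number of other genes")
    rhos = spearman_profile(matrix, target, others)
    order = sorted(rhos.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:k]]


def density_export(
    rhos: Sequence[float], bandwidth: float = 0.1, n_grid: int = 512
) -> pd.DataFrame:
    """Gaussian-kernel density of a rho sample on an even grid.

    Fixed absolute bandwidth h; the grid spans [min - 3h, max + 3h] so
    the density integrates to 1 (trapezoid rule, within 1e-3).
    """
    rhos = np.asarray(rhos, dtype=float)
    if bandwidth <= 0:
        raise DomainError("bandwidth must be positive")
    if len(rhos) < 2:
        raise DomainError("need at least 2 values")
    grid = np.linspace(rhos.min() - 3 * bandwidth, rhos.max() + 3 * bandwidth, n_grid)
    z = (grid[:, None] - rhos[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (
        len(rhos) * bandwidth * math.sqrt(2 * math.pi)
    )
    return pd.DataFrame({"grid": grid, "density": density})
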