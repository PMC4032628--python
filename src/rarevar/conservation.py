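"""Conservation-based binarization and the carriers x measures matrix.

Each variant's three conservation scores are reduced to binary
"functional by this measure" indicators:

* PhyloP >= 1.3 (per-nucleotide phylogenetic conservation, ~P = 0.05),
* GERP >= 5 (strong evolutionary constraint),
* ConSurf < 0 (residue more conserved than the protein average).

Because every analysed variant is a singleton, carriers and variants
are in bijection, and the permutation unit is the subject: the
functional matrix holds one row per subject in the full cohort, with
all-zero rows for subjects carrying no analysed variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CohortConfig, Thresholds, VariantRecord
from .errors import AnnotationError, DomainError

MEASURES = ("phylop", "gerp", "consurf")


@dataclass(frozen=True)
class FunctionalMatrix:
    """Subjects x measures binary indicator matrix with case labels."""

    subject_ids: tuple[str, ...]
    labels: np.ndarray  # bool, True = case
    indicators: np.ndarray  # (n_subjects, n_measures) of {0,1}
    measure_names: tuple[str, ...] = MEASURES

    def __post_init__(self):
        n = len(self.subject_ids)
        if self.labels.shape != (n,) or self.indicators.shape[0] != n:
            raise ValueError("inconsistent matrix dimensions")
        if not np.isin(self.indicators, (0, 1)).all():
            raise ValueError("indicators must be binary")

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.labels).sum())

    def column_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-measure carrier counts over (case rows, control rows)."""
        return (
            self.indicators[self.labels].sum(axis=0),
            self.indicators[~self.labels].sum(axis=0),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.indicators, columns=list(self.measure_names))
        df.insert(0, "is_case", self.labels.astype(int))
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FunctionalMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        measures = tuple(c for c in df.columns if c not in ("subject_id", "is_case"))
        return cls(
            subject_ids=tuple(df["subject_id"]),
            labels=df["is_case"].to_numpy(dtype=bool),
            indicators=df[list(measures)].to_numpy(dtype=np.int8),
            measure_names=measures,
        )


def binarize(variant: VariantRecord, thresholds: Thresholds) -> tuple[int, int, int]:
    """(phylop, gerp, consurf) indicators for one variant.

    PhyloP and GERP cutoffs are inclusive; the ConSurf cutoff is a
    strict less-than (scores exactly at the average are not counted as
    conserved).
    """
    for name in MEASURES:
        if not math.isfinite(getattr(variant, name)):
            raise AnnotationError(f"non-finite {name} score")
    return (
        int(variant.phylop >= thresholds.phylop_min),
        int(variant.gerp >= thresholds.gerp_min),
        int(variant.consurf < thresholds.consurf_max_exclusive),
    )


def build_functional_matrix(
    variants: Sequence[VariantRecord],
    cohort: CohortConfig,
    thresholds: Thresholds,
) -> FunctionalMatrix:
    """Assemble the full-cohort binary matrix from carrier variants.

    Carrier rows get their binarized triples; the remaining
    (n_cases + n_controls - #carriers) subjects are appended as
    synthetic non-carrier rows with all-zero indicators, so column sums
    equal per-measure carrier counts within each group.
    """
    case_rows = [(v.subject_id, True, binarize(v, thresholds)) for v in variants if v.is_case]
    ctrl_rows = [(v.subject_id, False, binarize(v, thresholds)) for v in variants if not v.is_case]
    if len(case_rows) > cohort.n_cases:
        raise DomainError(
            f"{len(case_rows)} case carriers exceed n_cases={cohort.n_cases}"
        )
    if len(ctrl_rows) > cohort.n_controls:
        raise DomainError(
            f"{len(ctrl_rows)} control carriers exceed n_controls={cohort.n_controls}"
        )
    ids = [s for s, _, _ in case_rows]
    ids += [f"case_noncarrier_{i:05d}" for i in range(cohort.n_cases - len(case_rows))]
    ids += [s for s, _, _ in ctrl_rows]
    ids += [
        f"control_noncarrier_{i:05d}"
        for i in range(cohort.n_controls - len(ctrl_rows))
    ]
    labels = np.zeros(cohort.n_total, dtype=bool)
    labels[: cohort.n_cases] = True
    indicators = np.zeros((cohort.n_total, 3), dtype=np.int8)
    for i, (_, _, triple) in enumerate(case_rows):
        indicators[i] = triple
    offset = cohort.n_cases
    for i, (_, _, triple) in enumerate(ctrl_rows):
        indicators[offset + i] = triple
    return FunctionalMatrix(tuple(ids), labels, indicators)
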