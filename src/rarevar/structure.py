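"""Crystal-structure-informed deleteriousness rubric.

Residue-level structural annotations (core vs surface, environment
hydrophobicity, surface-patch conservation, size/charge change,
truncation) are combined by a transparent additive score; a total at or
above the configurable threshold (default 3) classes the variant
deleterious.  Residues beyond the yeast-structure alignment limit
(default 451) are not assessable regardless of score, as are variants
without a residue-level annotation or protein change.

The per-criterion weights are one consistent instantiation of the
published criteria hierarchy and are fully configurable; the bundled
fixture's printed classifications, not the rubric, are authoritative
for the study counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_io import CrystalClass, Thresholds, VariantRecord

_RESIDUE_RE = re.compile(r"^[A-Z*](\d+)")


def residue_index(protein_change: Optional[str]) -> Optional[int]:
    """First residue index named by an HGVS-like protein change.

    ``R70C`` -> 70, ``R161*`` -> 161, ``G216Sfs*12`` -> 216,
    ``I576_A577insI`` -> 576; None (e.g. splice-site) -> None.
    """
    if not protein_change:
        return None
    m = _RESIDUE_RE.match(protein_change)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class StructuralAnnotation:
    residue_index: int
    location: str  # "core" or "surface"
    environment_hydrophobic: bool = False
    surface_patch_conserved: bool = False
    wt_aa: Optional[str] = None
    mut_aa: Optional[str] = None
    size_change: str = "none"  # "none" / "moderate" / "large"
    charge_change: bool = False
    hydrophilic_into_hydrophobic: bool = False
    is_truncating: bool = False

    def __post_init__(self):
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if self.location not in ("core", "surface"):
            raise ValueError("location must be 'core' or 'surface'")
        if self.size_change not in ("none", "moderate", "large"):
            raise ValueError("size_change must be none/moderate/large")


@dataclass(frozen=True)
class RubricWeights:
    """Additive criterion weights; all overridable."""

    truncating: int = 3
    core_hydrophilic_into_hydrophobic: int = 2
    core_size_large: int = 2
    core_size_moderate: int = 1
    surface_conserved_charge: int = 2
    surface_conserved_size_large: int = 2
    surface_conserved_size_moderate: int = 1


@dataclass(frozen=True)
class GradingResult:
    score: int
    classification: CrystalClass
    rationale: tuple[str, ...] = ()


def grade(
    annotation: Optional[StructuralAnnotation],
    thresholds: Thresholds,
    weights: RubricWeights = RubricWeights(),
) -> GradingResult:
    """Score one annotated residue; never raises on missing data."""
    if annotation is None:
        return GradingResult(0, CrystalClass.not_assessable, ("no_annotation",))
    if annotation.residue_index > thresholds.alignment_limit_residue:
        return GradingResult(
            0, CrystalClass.not_assessable, ("beyond_alignment_limit",)
        )
    score = 0
    fired = []
    if annotation.is_truncating:
        score += weights.truncating
        fired.append("truncating")
    if annotation.location == "core":
        if annotation.hydrophilic_into_hydrophobic:
            score += weights.core_hydrophilic_into_hydrophobic
            fired.append("core_hydrophilic_into_hydrophobic")
        if annotation.size_change == "large":
            score += weights.core_size_large
            fired.append("core_size_large")
        elif annotation.size_change == "moderate":
            score += weights.core_size_moderate
            fired.append("core_size_moderate")
    elif annotation.surface_patch_conserved:
        if annotation.charge_change:
            score += weights.surface_conserved_charge
            fired.append("surface_conserved_charge")
        if annotation.size_change == "large":
            score += weights.surface_conserved_size_large
            fired.append("surface_conserved_size_large")
        elif annotation.size_change == "moderate":
            score += weights.surface_conserved_size_moderate
            fired.append("surface_conserved_size_moderate")
    cls = (
        CrystalClass.deleterious
        if score >= thresholds.crystal_score_min
        else CrystalClass.benign
    )
    return GradingResult(score, cls, tuple(fired))


def classify_variants(
    variants: Sequence[VariantRecord],
    annotations: Mapping[str, StructuralAnnotation],
    thresholds: Thresholds,
    weights: RubricWeights = RubricWeights(),
) -> list[GradingResult]:
    """Grade each variant via its protein-change annotation.

    Variants without a protein change or annotation degrade to
    not_assessable.
    """
    results = []
    for v in variants:
        ann = annotations.get(v.protein_change) if v.protein_change else None
        results.append(grade(ann, thresholds, weights))
    return results


def consistency_report(
    variants: Sequence[VariantRecord],
    results: Sequence[GradingResult],
) -> pd.DataFrame:
    """Computed classes vs the recorded crystal_class column."""
    rows = [
        {
            "protein_change": v.protein_change or ".",
            "is_case": v.is_case,
            "computed": r.classification.value,
            "recorded": v.crystal_class.value,
            "agree": r.classification == v.crystal_class,
            "score": r.score,
        }
        for v, r in zip(variants, results)
    ]
    return pd.DataFrame(rows)


def read_annotations(path: str | Path) -> dict[str, StructuralAnnotation]:
    """Load the annotation TSV keyed by protein change."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)

    def _b(x) -> bool:
        return str(x).strip().lower() in ("true", "1", "yes")

    out = {}
    for row in df.itertuples(index=False):
        out[row.protein_change] = StructuralAnnotation(
            residue_index=int(row.residue_index),
            location=row.location,
            environment_hydrophobic=_b(row.environment_hydrophobic),
            surface_patch_conserved=_b(row.surface_patch_conserved),
            size_change=row.size_change,
            charge_change=_b(row.charge_change),
            hydrophilic_into_hydrophobic=_b(row.hydrophilic_into_hydrophobic),
            is_truncating=_b(row.is_truncating),
        )
    return out


def load_demo_annotations() -> dict[str, StructuralAnnotation]:
    """Synthetic residue-level annotations for the bundled fixture.

    Constructed by the package authors so that the default rubric
    reproduces the fixture's printed classifications for every
    assessable variant; illustrative of the rubric's mechanics, not a
    curation of the original structural assessment.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("rarevar.data").joinpath(
            "efr3a_structure_annotations_synthetic.tsv"
        )
    ) as p:
        return read_annotations(p)
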