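"""Domain types and tabular I/O for the rare-variant association pipeline.

The central record is :class:`VariantRecord`: one novel nonsynonymous
singleton variant carried by one subject, annotated with three
conservation scores (PhyloP, GERP, ConSurf) and a crystal-structure
classification.  A transcription of the study's printed variant table is
bundled as a fixture and loaded by :func:`load_table1`.

All tables are plain TSV, UTF-8, ``.`` for missing values.  Coordinates
are 1-based (hg19) as printed; insertions keep the table's ``*`` /
``I:<seq>`` convention rather than VCF left-normalisation (the VCF
reader converts).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import (
    DuplicateRecordError,
    RowParseError,
    SchemaError,
)

__version__ = "0.1.0"


class CohortGroup(str, enum.Enum):
    SSC_case = "SSC_case"
    AASC_case = "AASC_case"
    NINDS_control = "NINDS_control"
    NE_control = "NE_control"
    AASC_control = "AASC_control"

    @property
    def is_case(self) -> bool:
        return self in (CohortGroup.SSC_case, CohortGroup.AASC_case)

    @property
    def sequencing_set(self) -> str:
        """Which sequencing screen the subgroup went through.

        SSC cases and NINDS controls were Sanger-sequenced together; NE
        controls and the AASC case/control set each came from their own
        whole-exome screen.  Singleton status is evaluated within these
        sets by default.
        """
        if self in (CohortGroup.SSC_case, CohortGroup.NINDS_control):
            return "sanger"
        if self is CohortGroup.NE_control:
            return "ne_exome"
        return "aasc_exome"


class CrystalClass(str, enum.Enum):
    deleterious = "deleterious"
    benign = "benign"
    not_assessable = "not_assessable"


@dataclass(frozen=True)
class Transmission:
    """Tri-state carrier status of family members (None = unknown)."""

    father_carrier: Optional[bool] = None
    mother_carrier: Optional[bool] = None
    sib_carrier: Optional[bool] = None


@dataclass(frozen=True)
class VariantRecord:
    cohort_group: CohortGroup
    subject_id: str
    exon: str
    protein_change: Optional[str]  # None for the splice-site variant
    chrom: str
    pos: int
    ref: str
    alt: str
    sex: str  # "M" / "F" / "unknown"
    transmission: Transmission
    phylop: float
    gerp: float
    consurf: float
    crystal_class: CrystalClass
    is_index_de_novo: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("phylop", "gerp", "consurf"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    @property
    def is_case(self) -> bool:
        return self.cohort_group.is_case

    @property
    def allele_key(self) -> tuple[str, int, str, str]:
        """Exact-match identity of the allele: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes.  Defaults are the study's final matched cohorts."""

    n_cases: int = 2196
    n_controls: int = 3389
    subgroup_sizes: dict = field(
        default_factory=lambda: {
            CohortGroup.SSC_case: 1157,
            CohortGroup.AASC_case: 1039,
            CohortGroup.NINDS_control: 912,
            CohortGroup.NE_control: 1614,
            CohortGroup.AASC_control: 863,
        }
    )

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        cases = sum(
            n for g, n in self.subgroup_sizes.items() if g.is_case
        )
        controls = sum(
            n for g, n in self.subgroup_sizes.items() if not g.is_case
        )
        if self.subgroup_sizes and (cases != self.n_cases or controls != self.n_controls):
            raise ValueError(
                f"subgroup sizes ({cases} cases, {controls} controls) do not "
                f"sum to n_cases={self.n_cases} / n_controls={self.n_controls}"
            )

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class QcProfile:
    """Per-site sequencing QC cutoffs for one exome production centre."""

    min_mean_coverage: float
    minor_read_min: int
    balance_of_depth_max: float


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff of the analysis in one configurable record.

    phylop_min
        Site counts as conserved when PhyloP >= this (1.3 ~ P = 0.05).
    gerp_min
        Conserved when GERP >= this.
    consurf_max_exclusive
        Conserved when ConSurf < this (ConSurf normalises so conserved
        residues are negative).
    rare_freq
        Cohort allele-frequency ceiling for "rare" (< 1%).
    crystal_score_min
        Structure-rubric total at or above which a variant is classed
        deleterious.
    iqr_multiplier, n_pcs
        Ancestry outlier rule: exclusion beyond Q3 + k*IQR on any of the
        first n_pcs principal components.
    n_permutations
        Label permutations for the enrichment test.
    bonferroni_m
        Multiplicity factor for the overall burden P (two genes were
        screened initially).
    alignment_limit_residue
        Last residue covered by the yeast-structure alignment; higher
        residues are not assessable by the rubric.
    qc_missing_max, qc_profiles
        Exome site QC: missingness ceiling and per-centre coverage /
        read-support / allele-balance cutoffs.
    kde_bandwidth, top_k_coexpressed
        Co-expression reporting parameters.
    """

    phylop_min: float = 1.3
    gerp_min: float = 5.0
    consurf_max_exclusive: float = 0.0
    rare_freq: float = 0.01
    crystal_score_min: int = 3
    iqr_multiplier: float = 5.0
    n_pcs: int = 3
    n_permutations: int = 10_000
    bonferroni_m: int = 2
    alignment_limit_residue: int = 451
    qc_missing_max: float = 0.10
    qc_profiles: dict = field(
        default_factory=lambda: {
            "Broad": QcProfile(17.0, 17, 0.66),
            "Baylor": QcProfile(12.0, 12, 0.75),
        }
    )
    kde_bandwidth: float = 0.1
    top_k_coexpressed: int = 100

    def __post_init__(self):
        for name in (
            "phylop_min", "gerp_min", "rare_freq", "iqr_multiplier",
            "kde_bandwidth", "qc_missing_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Variant table I/O

VARIANT_COLUMNS = [
    "cohort_group", "subject_id", "exon", "protein_change", "chrom", "pos",
    "ref", "alt", "sex", "father", "mother", "sib", "phylop", "gerp",
    "consurf", "crystal_class", "is_index_de_novo",
]

_NUMERIC_COLUMNS = ("pos", "phylop", "gerp", "consurf")

_TRISTATE = {"+": True, "-": False, ".": None, "n/a": None, "": None}


def _parse_tristate(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return _TRISTATE.get(str(value).strip(), None)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a canonical variant TSV into a list of :class:`VariantRecord`.

    Raises :class:`SchemaError` on missing columns,
    :class:`RowParseError` (with the 0-based data-row index) on
    unparseable numerics and :class:`DuplicateRecordError` on repeated
    (subject_id, pos, alt) identities.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[VariantRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            pos = int(raw["pos"])
            scores = {c: float(raw[c]) for c in ("phylop", "gerp", "consurf")}
        except ValueError as exc:
            raise RowParseError(i, str(exc)) from exc
        protein_change = raw["protein_change"] or None
        if protein_change == ".":
            protein_change = None
        try:
            rec = VariantRecord(
                cohort_group=CohortGroup(raw["cohort_group"]),
                subject_id=raw["subject_id"],
                exon=raw["exon"],
                protein_change=protein_change,
                chrom=raw["chrom"],
                pos=pos,
                ref=raw["ref"],
                alt=raw["alt"],
                sex=raw["sex"] if raw["sex"] in ("M", "F") else "unknown",
                transmission=Transmission(
                    _parse_tristate(raw["father"]),
                    _parse_tristate(raw["mother"]),
                    _parse_tristate(raw["sib"]),
                ),
                phylop=scores["phylop"],
                gerp=scores["gerp"],
                consurf=scores["consurf"],
                crystal_class=CrystalClass(raw["crystal_class"]),
                is_index_de_novo=str(raw["is_index_de_novo"]).lower()
                in ("true", "1", "yes"),
            )
        except ValueError as exc:
            raise RowParseError(i, str(exc)) from exc
        ident = (rec.subject_id, rec.pos, rec.alt)
        if ident in seen:
            raise DuplicateRecordError(
                f"duplicate record (subject_id={rec.subject_id}, pos={rec.pos}, "
                f"alt={rec.alt})"
            )
        seen.add(ident)
        records.append(rec)
    return records


def _tristate_str(v: Optional[bool]) -> str:
    return "." if v is None else ("+" if v else "-")


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "cohort_group": v.cohort_group.value,
                "subject_id": v.subject_id,
                "exon": v.exon,
                "protein_change": v.protein_change or ".",
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "sex": v.sex,
                "father": _tristate_str(v.transmission.father_carrier),
                "mother": _tristate_str(v.transmission.mother_carrier),
                "sib": _tristate_str(v.transmission.sib_carrier),
                "phylop": repr(v.phylop),
                "gerp": repr(v.gerp),
                "consurf": repr(v.consurf),
                "crystal_class": v.crystal_class.value,
                "is_index_de_novo": str(v.is_index_de_novo).lower(),
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_table1() -> list[VariantRecord]:
    """The bundled transcription of the study's printed variant table."""
    with resources.as_file(
        resources.files("rarevar.data").joinpath("efr3a_table1.tsv")
    ) as p:
        return read_variant_table(p)


# ---------------------------------------------------------------------------
# Generic result writer / reader

def write_results(
    result,
    path: str | Path,
    *,
    seed: Optional[int] = None,
    thresholds: Optional[Thresholds] = None,
) -> None:
    """Write a result dataclass (or list thereof) as TSV.

    A ``#``-prefixed header comment records the tool version, the seed
    and any non-default thresholds, so outputs are self-describing.
    Floats are serialised with ``repr`` and survive a round-trip to full
    double precision.
    """
    rows = result if isinstance(result, (list, tuple)) else [result]
    if not rows:
        raise ValueError("nothing to write")
    first = rows[0]
    if not dataclasses.is_dataclass(first):
        raise TypeError("write_results expects dataclass instances")

    def _cell(v):
        if isinstance(v, float):
            return repr(v)
        if isinstance(v, enum.Enum):
            return v.value
        if isinstance(v, (list, tuple)):
            return ",".join(repr(float(x)) for x in v)
        return v

    header_lines = [f"# rarevar {__version__}"]
    if seed is not None:
        header_lines.append(f"# seed={seed}")
    if thresholds is not None:
        header_lines.append(f"# thresholds={dataclasses.asdict(thresholds)}")
    frames = []
    for r in rows:
        d = {}
        for f in dataclasses.fields(r):
            v = getattr(r, f.name)
            if dataclasses.is_dataclass(v):
                for sub in dataclasses.fields(v):
                    d[sub.name] = _cell(getattr(v, sub.name))
            else:
                d[f.name] = _cell(v)
        frames.append(d)
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        pd.DataFrame(frames).to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a :func:`write_results` TSV (comments stripped)."""
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Minimal VCF reader

def read_variant_vcf(
    path: str | Path,
    cohort_group: CohortGroup = CohortGroup.NE_control,
) -> list[VariantRecord]:
    """Read a minimal VCF (INFO keys PHYLOP, GERP, CONSURF) into records.

    VCF insertions (REF one base, ALT the base plus inserted sequence)
    are converted to the table convention: ref ``*``, alt ``I:<seq>``,
    position after the anchor base.  Subject id is taken from INFO key
    SUBJECT when present, else synthesised from the site.
    """
    from cyvcf2 import VCF  # optional dependency

    records = []
    for v in VCF(str(path)):
        ref, alt, pos = v.REF, v.ALT[0], v.POS
        if len(ref) == 1 and len(alt) > 1 and alt.startswith(ref):
            ref, alt, pos = "*", "I:" + alt[1:], pos + 1
        records.append(
            VariantRecord(
                cohort_group=cohort_group,
                subject_id=v.INFO.get("SUBJECT") or f"{v.CHROM}:{v.POS}:{alt}",
                exon=".",
                protein_change=v.INFO.get("PCHANGE"),
                chrom=v.CHROM,
                pos=pos,
                ref=ref,
                alt=alt,
                sex="unknown",
                transmission=Transmission(),
                phylop=float(v.INFO.get("PHYLOP")),
                gerp=float(v.INFO.get("GERP")),
                consurf=float(v.INFO.get("CONSURF")),
                crystal_class=CrystalClass.not_assessable,
            )
        )
    return records


# ---------------------------------------------------------------------------
# key = value config files overriding Thresholds

def load_config(path: str | Path, base: Optional[Thresholds] = None) -> Thresholds:
    """Parse a ``key = value`` file into a :class:`Thresholds` override."""
    base = base or Thresholds()
    overrides = {}
    valid = {f.name: f.type for f in dataclasses.fields(Thresholds)}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise SchemaError(f"unknown threshold key: {key!r}")
            current = getattr(base, key)
            if isinstance(current, bool):
                overrides[key] = value.lower() in ("true", "1", "yes")
            elif isinstance(current, int):
                overrides[key] = int(value)
            elif isinstance(current, float):
                overrides[key] = float(value)
            else:
                raise SchemaError(f"key {key!r} cannot be set from a config file")
    return base.replace(**overrides)
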