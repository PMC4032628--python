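"""End-to-end orchestration: variant table -> burden statistics ->
permutation test -> structure grading, with per-stage TSV outputs and a
reproducibility manifest.

Stages communicate only via files, so every intermediate is auditable;
the manifest records the tool version, the seed, the thresholds in
force and a checksum of each input.  Rerunning with the same
configuration reproduces deterministic outputs bit-identically and
stochastic ones identically given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import structure
from .association import ContingencyTable, associate
from .conservation import build_functional_matrix
from .core_io import (
    CohortConfig,
    CrystalClass,
    Thresholds,
    __version__,
    load_table1,
    read_variant_table,
    write_results,
)
from .errors import ConfigurationError
from .filters import burden_inclusion
from .permutation import exact_p, permutation_test

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("annotate", "burden", "permtest", "grade")


@dataclass(frozen=True)
class PipelineConfig:
    variant_table: Optional[Path] = None  # None = bundled fixture
    annotations: Optional[Path] = None  # None = bundled synthetic demo
    out_dir: Path = Path("rarevar_out")
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple[str, ...] = KNOWN_STAGES

    def __post_init__(self):
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {
        "tool": "rarevar",
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(th),
        "inputs": {},
        "stages": {},
    }

    if config.variant_table is not None:
        variants = read_variant_table(config.variant_table)
        manifest["inputs"]["variant_table"] = _sha256(Path(config.variant_table))
    else:
        variants = load_table1()
        manifest["inputs"]["variant_table"] = "bundled:efr3a_table1"
    burden_set, conservation_set = burden_inclusion(variants)
    logger.info(
        "loaded %d variants (%d in burden set)", len(variants), len(burden_set)
    )

    matrix = None
    for stage in config.stages:
        try:
            if stage == "annotate":
                matrix = build_functional_matrix(conservation_set, config.cohort, th)
                matrix.to_tsv(out / "functional_matrix.tsv")
                case_sums, ctrl_sums = matrix.column_sums()
                manifest["stages"]["annotate"] = {
                    "case_counts": [int(x) for x in case_sums],
                    "control_counts": [int(x) for x in ctrl_sums],
                }
            elif stage == "burden":
                n_case_carriers = sum(1 for v in burden_set if v.is_case)
                n_ctrl_carriers = sum(1 for v in burden_set if not v.is_case)
                table = ContingencyTable(
                    n_case_carriers,
                    config.cohort.n_cases - n_case_carriers,
                    n_ctrl_carriers,
                    config.cohort.n_controls - n_ctrl_carriers,
                )
                result = associate(table, bonferroni_m=th.bonferroni_m)
                write_results(
                    result, out / "burden.tsv", seed=config.seed, thresholds=th
                )
                manifest["stages"]["burden"] = {
                    "case_carriers": n_case_carriers,
                    "control_carriers": n_ctrl_carriers,
                    "p_right": result.p_right,
                    "p_corrected": result.p_corrected,
                    "odds_ratio": result.odds_ratio,
                }
            elif stage == "permtest":
                if matrix is None:
                    matrix = build_functional_matrix(
                        conservation_set, config.cohort, th
                    )
                perm = permutation_test(matrix, th.n_permutations, config.seed)
                write_results(
                    perm, out / "permutation.tsv", seed=config.seed, thresholds=th
                )
                manifest["stages"]["permtest"] = {
                    "observed_stat": perm.observed_stat,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                }
            elif stage == "grade":
                if config.annotations is not None:
                    annotations = structure.read_annotations(config.annotations)
                    manifest["inputs"]["annotations"] = _sha256(
                        Path(config.annotations)
                    )
                else:
                    annotations = structure.load_demo_annotations()
                    manifest["inputs"]["annotations"] = "bundled:synthetic_demo"
                results = structure.classify_variants(
                    conservation_set, annotations, th
                )
                report = structure.consistency_report(conservation_set, results)
                report.to_csv(out / "grading.tsv", sep="\t", index=False)
                deleterious = [
                    r.classification is CrystalClass.deleterious for r in results
                ]
                manifest["stages"]["grade"] = {
                    "case_deleterious": sum(
                        d for d, v in zip(deleterious, conservation_set) if v.is_case
                    ),
                    "control_deleterious": sum(
                        d
                        for d, v in zip(deleterious, conservation_set)
                        if not v.is_case
                    ),
                }
        except Exception:
            partial = out / "manifest.partial.json"
            partial.write_text(json.dumps(manifest, indent=2))
            logger.error("stage %r failed; partial manifest at %s", stage, partial)
            raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
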