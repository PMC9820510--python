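"""The two stringent filtration modes: tumor-informed reference-set
construction and tumor-naive plasma detection.

Tumor calls form the "solid reference" a plasma sample is later compared
against, so the tumor filter trades sensitivity for precision: a VAF floor
(raised for FFPE tissue, whose fixation artifacts inflate low-VAF calls)
plus membership in either the COSMIC or TCGA somatic databases.

Plasma detection without tumor knowledge applies no VAF floor at all —
a real ctDNA molecule at 0.03% VAF is signal — and instead demands exonic
impact, joint COSMIC and TCGA-BC membership, and "duplex" read support:
at least two supporting fragments whose alignments start at different
genomic coordinates, which PCR copies of a single errored molecule cannot
produce.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Set

import pandas as pd

from .candidate_calling import Variant
from .formats_io import AnnotationRecord

TUMOR_VAF_THRESHOLDS = {"fresh_frozen": 0.05, "FFPE": 0.2}


@dataclass(frozen=True, slots=True)
class AnnotationFlags:
    """Database-membership and region flags for one variant."""

    in_cosmic: bool = False
    in_tcga_bc: bool = False
    in_tcga_all: bool = False
    exonic: bool = False
    gene: str = ""

    @classmethod
    def from_record(cls, rec: AnnotationRecord) -> "AnnotationFlags":
        return cls(
            in_cosmic=rec.in_cosmic,
            in_tcga_bc=rec.in_tcga_bc,
            in_tcga_all=rec.in_tcga_all,
            exonic=rec.exonic,
            gene=rec.gene,
        )


@dataclass(slots=True)
class DetectionResult:
    """Per-variant outcome of a detection path."""

    variant: Variant
    sample_id: str
    vaf: float | None
    method: str  # caller_stringent | rescue
    duplex_coord_count: int
    flags: AnnotationFlags
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duplex_coord_count < 0:
            raise ValueError("duplex_coord_count must be >= 0")
        if self.passed and self.fail_reasons:
            raise ValueError("a passing detection cannot carry fail reasons")


def tumor_stringent_filter(
    variant: Variant,
    vaf: float,
    flags: AnnotationFlags,
    tissue_prep: str,
) -> tuple[bool, list[str]]:
    """Accept a tumor call iff VAF clears the tissue threshold (strict >)
    and the variant is known to COSMIC or TCGA (any-cancer or BC set)."""
    if tissue_prep not in TUMOR_VAF_THRESHOLDS:
        raise ValueError(
            f"tumor filter applies to fresh_frozen/FFPE tissue, got {tissue_prep!r}"
        )
    reasons = []
    if not vaf > TUMOR_VAF_THRESHOLDS[tissue_prep]:
        reasons.append("vaf_threshold")
    if not (flags.in_cosmic or flags.in_tcga_all or flags.in_tcga_bc):
        reasons.append("database")
    return (not reasons, reasons)


def duplex_support_check(supporting_coords: Set[int]) -> bool:
    """True iff supporting fragments map to >=2 distinct start coordinates."""
    return len(set(supporting_coords)) >= 2


def plasma_stringent_filter(
    variant: Variant,
    flags: AnnotationFlags,
    supporting_coords: Set[int],
    require_tcga_all: bool = False,
    require_both_orientations: bool = False,
    orientations: Set[str] | None = None,
) -> DetectionResult:
    """Tumor-naive plasma detection: exonic, in COSMIC and TCGA-BC, and
    duplex-supported. No VAF condition is applied.

    Splice-site variants satisfy the exonic criterion (the published call
    set itself contains splice variants, so "exonic" is read as
    exonic-or-splice). The optional stricter duplex mode additionally
    requires both strand orientations among supporting reads.
    """
    reasons: list[str] = []
    if not (flags.exonic or variant.var_class == "splice"):
        reasons.append("exonic")
    database_ok = flags.in_cosmic and flags.in_tcga_bc
    if require_tcga_all:
        database_ok = database_ok and flags.in_tcga_all
    if not database_ok:
        reasons.append("database")
    if not duplex_support_check(supporting_coords):
        reasons.append("duplex")
    if require_both_orientations and (
        orientations is None or {"F1R2", "F2R1"} - set(orientations)
    ):
        reasons.append("orientation")
    return DetectionResult(
        variant=variant,
        sample_id=variant.sample_id,
        vaf=variant.vaf,
        method="caller_stringent",
        duplex_coord_count=len(set(supporting_coords)),
        flags=flags,
        passed=not reasons,
        fail_reasons=reasons,
    )


def apply_control_screen(
    detections_by_control: Mapping[str, Iterable[DetectionResult]],
) -> tuple[pd.DataFrame, int]:
    """Per-control positivity after running the identical case pipeline.

    A control is positive when it carries at least one passing detection.
    Returns the per-control table and the positive count.
    """
    rows = []
    for sample_id, detections in detections_by_control.items():
        passing = [d for d in detections if d.passed]
        rows.append(
            {
                "sample_id": sample_id,
                "positive": bool(passing),
                "n_passing": len(passing),
            }
        )
    table = pd.DataFrame(rows, columns=["sample_id", "positive", "n_passing"])
    n_positive = int(table["positive"].sum()) if len(table) else 0
    return table, n_positive
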