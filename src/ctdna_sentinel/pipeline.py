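"""End-to-end orchestration of the two published detection modes.

Tumor-informed: build a stringent somatic reference from the tumor
(consensus with min family size 3, VAF floor, database membership), then
look for exactly those variants in the paired plasma — first through the
candidate caller, then through the Fisher rescue test for caller-missed
variants.

Non-tumor-informed: plasma only, consensus with min family size 1 and no
VAF threshold, database + exonic + duplex criteria; cases and controls run
through the identical pipeline, and cohort-level diagnostics follow.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .candidate_calling import (
    PileupCounts,
    Variant,
    build_pileup,
    call_candidates,
)
from .cohort_metrics import ConfusionCounts, diagnostic_metrics, positivity_table
from .formats_io import AnnotationIndex
from .rescue_testing import RescueResult, coordinate_support_rule, interrogate_site, rescue_pass
from .simulate import SampleBundle
from .umi_consensus import (
    call_consensus_batch,
    filter_consensus_reads,
    group_reads_by_umi,
)
from .variant_filtering import (
    AnnotationFlags,
    DetectionResult,
    plasma_stringent_filter,
    tumor_stringent_filter,
)


@dataclass(slots=True)
class RunConfig:
    """Mode-consistent pipeline settings, serialized into every report."""

    mode: str = "tumor_informed"  # tumor_informed | non_informed
    min_family_size_tumor: int = 3
    min_family_size_plasma: int = 1
    min_base_quality: int = 30
    tumor_min_alt_fragments: int = 2
    plasma_min_alt_fragments: int = 2
    naive_min_alt_fragments: int = 1
    tissue_prep: str = "fresh_frozen"
    require_tcga_all: bool = False
    rescue_pool: str = "healthy"  # healthy | mixed
    rescue_sided: str = "greater"
    rescue_alpha: float = 0.05
    seed: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(slots=True)
class TumorInformedReport:
    tumor_variants: list[Variant]
    caller_detections: list[DetectionResult]
    rescue_results: list[RescueResult]
    detections: list[DetectionResult]
    concordance: dict
    dropped: list[dict]
    config: dict


@dataclass(slots=True)
class NonInformedReport:
    positivity: pd.DataFrame
    confusion: ConfusionCounts
    metrics: dict
    detections_by_sample: dict
    dropped: list[dict]
    config: dict


def _flags(annotation: AnnotationIndex, variant: Variant) -> AnnotationFlags:
    rec = annotation.lookup(variant.chrom, variant.pos, variant.ref, variant.alt)
    return AnnotationFlags.from_record(rec)


def consensus_pileups(
    bundle: SampleBundle, min_family_size: int, min_base_quality: int = 30
) -> dict[tuple[str, int], PileupCounts]:
    """reads -> UMI families -> consensus -> family-size filter -> pileup."""
    families = group_reads_by_umi(bundle.reads)
    consensus = call_consensus_batch(families, min_base_quality)
    kept = filter_consensus_reads(consensus, min_family_size)
    return build_pileup(kept, bundle.panel, bundle.reference)


def run_tumor_informed(
    tumor_bundle: SampleBundle,
    plasma_bundle: SampleBundle,
    control_bundles: Sequence[SampleBundle],
    annotation: AnnotationIndex,
    config: RunConfig | None = None,
) -> TumorInformedReport:
    """Tumor-informed mode on one tumor/plasma pair against a control pool."""
    config = config or RunConfig(mode="tumor_informed")
    dropped: list[dict] = []

    tumor_pileups = consensus_pileups(
        tumor_bundle, config.min_family_size_tumor, config.min_base_quality
    )
    tumor_candidates = call_candidates(
        tumor_pileups, config.tumor_min_alt_fragments,
        panel=tumor_bundle.panel, sample_id=tumor_bundle.sample_id,
    )
    tumor_variants: list[Variant] = []
    for cand in tumor_candidates:
        ok, reasons = tumor_stringent_filter(
            cand, cand.vaf, _flags(annotation, cand), tumor_bundle.tissue_prep
        )
        if ok:
            tumor_variants.append(cand)
        else:
            dropped.append({"stage": "tumor_filter", "sample": tumor_bundle.sample_id,
                            "variant": cand.key, "fail_reasons": reasons})

    plasma_pileups = consensus_pileups(
        plasma_bundle, config.min_family_size_plasma, config.min_base_quality
    )
    plasma_candidates = {
        v.key: v
        for v in call_candidates(
            plasma_pileups, config.plasma_min_alt_fragments,
            panel=plasma_bundle.panel, sample_id=plasma_bundle.sample_id,
        )
    }

    caller_detections: list[DetectionResult] = []
    caller_missed: list[Variant] = []
    for tv in tumor_variants:
        hit = plasma_candidates.get(tv.key)
        if hit is None:
            caller_missed.append(tv)
            continue
        si = interrogate_site(plasma_pileups, hit, plasma_bundle.panel)
        if coordinate_support_rule(si):
            caller_detections.append(
                DetectionResult(
                    variant=hit, sample_id=plasma_bundle.sample_id, vaf=hit.vaf,
                    method="caller_stringent",
                    duplex_coord_count=len(si.supporting_coords),
                    flags=_flags(annotation, hit), passed=True,
                )
            )
        else:
            dropped.append({"stage": "caller_duplex", "sample": plasma_bundle.sample_id,
                            "variant": tv.key, "fail_reasons": ["duplex"]})
            caller_missed.append(tv)

    control_pileups = {
        b.sample_id: consensus_pileups(
            b, config.min_family_size_plasma, config.min_base_quality
        )
        for b in control_bundles
    }
    rescue_results = rescue_pass(
        caller_missed, plasma_pileups, control_pileups,
        panel=plasma_bundle.panel, alpha=config.rescue_alpha,
        sided=config.rescue_sided,
    )
    rescue_by_key = {r.variant_key: r for r in rescue_results}

    detections = list(caller_detections)
    for tv in caller_missed:
        rr = rescue_by_key.get(tv.key)
        if rr is None:
            continue
        if rr.passed:
            si = interrogate_site(plasma_pileups, tv, plasma_bundle.panel)
            vaf = (
                rr.sample_alt / (rr.sample_alt + rr.sample_ref)
                if rr.sample_alt + rr.sample_ref else None
            )
            detections.append(
                DetectionResult(
                    variant=tv, sample_id=plasma_bundle.sample_id, vaf=vaf,
                    method="rescue",
                    duplex_coord_count=len(si.supporting_coords),
                    flags=_flags(annotation, tv), passed=True,
                )
            )
        else:
            dropped.append({"stage": "rescue", "sample": plasma_bundle.sample_id,
                            "variant": tv.key,
                            "fail_reasons": [f"p={rr.p_value:.4g}"]})

    n_tumor = len(tumor_variants)
    concordance = {
        "n_tumor_variants": n_tumor,
        "caller_detected": len(caller_detections),
        "overall_detected": len(detections),
        "caller_fraction": len(caller_detections) / n_tumor if n_tumor else None,
        "overall_fraction": len(detections) / n_tumor if n_tumor else None,
    }
    return TumorInformedReport(
        tumor_variants=tumor_variants,
        caller_detections=caller_detections,
        rescue_results=rescue_results,
        detections=detections,
        concordance=concordance,
        dropped=dropped,
        config=config.to_dict(),
    )


def limit_of_detection_study(
    n_replicates: int = 200,
    depth: int = 10_000,
    truth_vaf: float = 3e-4,
    n_controls: int = 22,
    control_depth: int = 2500,
    seed: int = 0,
    per_base_error_rate: float = 1e-3,
    config: RunConfig | None = None,
) -> dict:
    """Detection rate at the claimed limit of detection (3 in 10,000).

    Per replicate, a plasma sample is simulated at the given consensus
    depth with one variant spiked at truth_vaf, and pushed through the
    full tumor-informed plasma path — UMI grouping, consensus, family-size
    filter 1, pileup, candidate caller, coordinate rule, Fisher rescue —
    against a fixed pool of mutation-free control plasmas (simulated once;
    the same donors back every patient). A replicate is duplex-eligible
    when the spike realized >=2 mutant fragments at >=2 distinct
    coordinates; the detection rate is reported over eligible replicates.
    """
    import dataclasses as _dc

    import numpy as np

    from .formats_io import PanelRegion
    from .simulate import SimConfig, SpikeSpec, build_reference, simulate_sample

    config = config or RunConfig()
    panel = [PanelRegion("sim1", 0, 200, "LODSITE")]
    site = 100
    reference = build_reference(panel, SimConfig(seed=0, panel=panel).reference_seed)
    ref_allele = reference.base("sim1", site)
    alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[ref_allele]
    base = SimConfig(
        seed=seed, panel=panel, consensus_depth_target=depth,
        per_base_error_rate=per_base_error_rate,
        spikes=[SpikeSpec("sim1", site, alt, truth_vaf, "LODSITE")],
    )
    rng = np.random.default_rng(seed)

    controls = [
        simulate_sample(
            _dc.replace(base, seed=int(rng.integers(2**31 - 1)), spikes=[],
                        consensus_depth_target=control_depth,
                        per_base_error_rate=0.0),
            "plasma_control", sample_id=f"ctrl{i}",
        )
        for i in range(n_controls)
    ]
    control_pileups = {
        b.sample_id: consensus_pileups(b, config.min_family_size_plasma,
                                       config.min_base_quality)
        for b in controls
    }

    n_eligible = n_detected = 0
    for _ in range(n_replicates):
        bundle = simulate_sample(
            _dc.replace(base, seed=int(rng.integers(2**31 - 1))),
            "plasma_case", sample_id="case",
            paired_tumor_truth=pd.DataFrame(
                [{"chrom": "sim1", "pos": site, "ref": ref_allele, "alt": alt,
                  "gene": "LODSITE", "truth_vaf": truth_vaf}]
            ),
        )
        row = bundle.truth.iloc[0]
        if row.realized_alt_fragments < 2 or len(row.supporting_coords) < 2:
            continue
        n_eligible += 1
        pileups = consensus_pileups(bundle, config.min_family_size_plasma,
                                    config.min_base_quality)
        tumor_variant = Variant(
            chrom="sim1", pos=site + 1, ref=row.ref, alt=alt, gene="LODSITE",
        )
        si = interrogate_site(pileups, tumor_variant, panel)
        caller_hit = (
            si.alt_count >= config.plasma_min_alt_fragments
            and coordinate_support_rule(si)
        )
        if caller_hit:
            n_detected += 1
            continue
        results = rescue_pass(
            [tumor_variant], pileups, control_pileups, panel=panel,
            alpha=config.rescue_alpha, sided=config.rescue_sided,
        )
        if results and results[0].passed:
            n_detected += 1
    return {
        "n_replicates": n_replicates,
        "n_eligible": n_eligible,
        "n_detected": n_detected,
        "detection_rate": n_detected / n_eligible if n_eligible else None,
        "depth": depth,
        "truth_vaf": truth_vaf,
    }


def run_non_informed(
    plasma_bundles: Sequence[SampleBundle],
    annotation: AnnotationIndex,
    config: RunConfig | None = None,
    sample_sheet: pd.DataFrame | None = None,
) -> NonInformedReport:
    """Tumor-naive mode over case and control plasmas, treated identically.

    This mode never sees tumor inputs: the signature only accepts plasma
    bundles. Positivity and diagnostic metrics are computed against the
    sheet's case/control roles.
    """
    config = config or RunConfig(mode="non_informed")
    dropped: list[dict] = []
    detections_by_sample: dict[str, list[DetectionResult]] = {}
    sheet_rows = []
    for bundle in plasma_bundles:
        if bundle.role == "tumor":
            raise ValueError("non-informed mode accepts plasma samples only")
        pileups = consensus_pileups(
            bundle, config.min_family_size_plasma, config.min_base_quality
        )
        candidates = call_candidates(
            pileups, config.naive_min_alt_fragments,
            panel=bundle.panel, sample_id=bundle.sample_id,
        )
        passing = []
        for cand in candidates:
            pc = pileups[(cand.chrom, cand.pos - 1)]
            det = plasma_stringent_filter(
                cand, _flags(annotation, cand),
                pc.supporting_coords.get(cand.alt, set()),
                require_tcga_all=config.require_tcga_all,
            )
            if det.passed:
                passing.append(det)
            else:
                dropped.append({"stage": "plasma_filter", "sample": bundle.sample_id,
                                "variant": cand.key,
                                "fail_reasons": det.fail_reasons})
        detections_by_sample[bundle.sample_id] = passing
        sheet_rows.append({"sample_id": bundle.sample_id, "role": bundle.role,
                           "has_plasma": "Y"})

    sheet = sample_sheet if sample_sheet is not None else pd.DataFrame(sheet_rows)
    positivity, confusion = positivity_table(
        {s: d for s, d in detections_by_sample.items() if d}, sheet
    )
    metrics = diagnostic_metrics(confusion)
    return NonInformedReport(
        positivity=positivity,
        confusion=confusion,
        metrics=metrics,
        detections_by_sample=detections_by_sample,
        dropped=dropped,
        config=config.to_dict(),
    )
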