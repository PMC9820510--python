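"""Synthetic UMI-tagged read generator with known truth.

The generator emulates the study conditions of an ultra-deep targeted
cfDNA experiment: original fragments are drawn at a target consensus
depth (default 2,500 molecules over a site, the published post-UMI plasma
median), each fragment is tagged with a degenerate UMI and expanded into a
PCR/sequencing family of 1 + Poisson(lambda) read copies (lambda = 6
approximates the published ~15,000x raw to ~1,700-2,500x consensus
collapse), and every read base is then perturbed at the pre-consensus
error rate (default 1e-3). Mutant fragments carry the spiked allele;
spiked indel/splice alleles are carried as the "*" token so they survive
consensus and pileup without a gapped-alignment model.

All randomness flows through numpy Generators seeded from the caller's
seed; the same seed reproduces byte-identical output. A "polymerase" error
mode (errors shared by a whole family, hence consensus-proof) is available
to stress-test the Fisher screen.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .candidate_calling import Reference
from .formats_io import AnnotationIndex, AnnotationRecord, PanelRegion
from .umi_consensus import TaggedRead, _ALPHABET

_UMI_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class SpikeSpec:
    """One variant to spike, at a known truth VAF."""

    chrom: str
    pos: int  # 0-based site position
    alt: str  # A/C/G/T or "*" for an indel/splice token
    truth_vaf: float
    gene: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.truth_vaf <= 1.0:
            raise ValueError("truth_vaf must be in [0,1]")


@dataclass(slots=True)
class SimConfig:
    """Study-condition knobs for the read simulator."""

    seed: int
    panel: Sequence[PanelRegion]
    n_sites: int = 1
    consensus_depth_target: int = 2500
    family_size_lambda: float = 6.0
    per_base_error_rate: float = 1e-3
    polymerase_error_rate: float = 0.0
    spikes: list[SpikeSpec] = field(default_factory=list)
    umi_length: int = 10
    read_length: int = 25
    base_quality: int = 37
    fraction_duplex_sites: float = 1.0
    reference_seed: int = 20221221


@dataclass(slots=True)
class SampleBundle:
    """Reads + truth + reference for one simulated sample."""

    sample_id: str
    role: str  # tumor | plasma_case | plasma_control
    tissue_prep: str
    reads: list[TaggedRead]
    truth: pd.DataFrame
    reference: Reference
    panel: Sequence[PanelRegion]
    sheet_row: dict


def build_reference(panel: Sequence[PanelRegion], seed: int) -> Reference:
    """Deterministic random reference over the panel regions.

    Each region's sequence depends only on (seed, chrom, start), never on
    region order, so tumor/plasma/control samples agree on the reference.
    """
    ref = Reference()
    for region in panel:
        material = (seed, zlib.crc32(region.chrom.encode()), region.start)
        rng = np.random.default_rng(material)
        ref.add_segment(
            region.chrom, region.start,
            rng.integers(0, 4, len(region)).astype(np.uint8),
        )
    return ref


def auto_sites(
    panel: Sequence[PanelRegion], n: int, read_length: int
) -> list[tuple[str, int, str]]:
    """Deterministic, non-overlapping site positions across panel regions.

    Returns (chrom, 0-based pos, gene label) triples, spaced >= 3 read
    lengths apart so simulated windows never overlap.
    """
    sites: list[tuple[str, int, str]] = []
    stride = 3 * read_length
    slots_per_region = [
        max(0, (len(r) - 2 * read_length) // stride + 1) for r in panel
    ]
    region_idx, slot = 0, 0
    while len(sites) < n:
        if region_idx >= len(panel):
            raise ValueError(f"panel too small for {n} sites")
        if slot >= slots_per_region[region_idx]:
            region_idx, slot = region_idx + 1, 0
            continue
        r = panel[region_idx]
        pos = r.start + read_length + slot * stride
        sites.append((r.chrom, pos, r.label))
        slot += 1
    return sites


def _region_of(panel: Sequence[PanelRegion], chrom: str, pos: int) -> PanelRegion:
    for r in panel:
        if r.contains(chrom, pos):
            return r
    raise ValueError(f"spiked site {chrom}:{pos} lies outside the panel")


def _simulate_site(
    config: SimConfig,
    rng: np.random.Generator,
    reference: Reference,
    chrom: str,
    pos: int,
    alt: str | None,
    truth_vaf: float,
    site_tag: str,
    duplex_site: bool,
) -> tuple[list[TaggedRead], int, tuple[int, ...]]:
    """Simulate all reads covering one site; returns (reads, n_mutant, coords)."""
    region = _region_of(config.panel, chrom, pos)
    L = config.read_length
    if pos - L + 1 < region.start or pos + L > region.end:
        raise ValueError(
            f"site {chrom}:{pos} too close to the edge of region "
            f"{region.label or region.start} for read length {L}"
        )
    n_frag = config.consensus_depth_target
    window_lo = pos - L + 1
    if duplex_site:
        frag_starts = rng.integers(window_lo, pos + 1, n_frag)
    else:
        frag_starts = np.full(n_frag, pos - L // 2, dtype=np.int64)
    n_mut = int(rng.binomial(n_frag, truth_vaf)) if truth_vaf > 0 else 0
    alt_code = _ALPHABET.index(alt) if alt is not None else None

    # per-fragment template bases (reference, then spike, then polymerase errors)
    col = np.arange(L)
    frag_bases = reference.codes_at(
        chrom, (frag_starts[:, None] + col[None, :]).ravel()
    ).reshape(n_frag, L)
    site_col = pos - frag_starts  # column of the site within each fragment
    if n_mut:
        frag_bases[np.arange(n_mut), site_col[:n_mut]] = alt_code
    if config.polymerase_error_rate > 0:
        err = rng.random(frag_bases.shape) < config.polymerase_error_rate
        err &= frag_bases < 4
        shift = rng.integers(1, 4, frag_bases.shape)
        frag_bases[err] = (frag_bases[err] + shift[err]) % 4

    umis = _UMI_BASES[rng.integers(0, 4, (n_frag, config.umi_length))]
    orientations = np.where(rng.random(n_frag) < 0.5, "F1R2", "F2R1")
    sizes = 1 + rng.poisson(config.family_size_lambda, n_frag)

    read_bases = np.repeat(frag_bases, sizes, axis=0)
    if config.per_base_error_rate > 0:
        err = rng.random(read_bases.shape) < config.per_base_error_rate
        err &= read_bases < 4  # spiked indel tokens are not substitutable
        shift = rng.integers(1, 4, read_bases.shape)
        read_bases[err] = (read_bases[err] + shift[err]) % 4
    quals = np.full(L, config.base_quality, dtype=np.uint8)

    frag_of_read = np.repeat(np.arange(n_frag), sizes)
    copy_idx = np.concatenate([np.arange(k) for k in sizes])
    reads: list[TaggedRead] = []
    for i in range(len(read_bases)):
        f = frag_of_read[i]
        reads.append(
            TaggedRead(
                read_id=f"{site_tag}:{f}:{copy_idx[i]}",
                umi=umis[f].tobytes().decode(),
                chrom=chrom,
                fragment_start=int(frag_starts[f]),
                fragment_end=int(frag_starts[f]) + L,
                strand_orientation=str(orientations[f]),
                mate="read1",
                start=int(frag_starts[f]),
                bases=read_bases[i],
                quals=quals.copy(),
            )
        )
    coords = tuple(sorted({int(s) for s in frag_starts[:n_mut]}))
    return reads, n_mut, coords


def simulate_read_families(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[TaggedRead], pd.DataFrame, Reference]:
    """Simulate UMI families over spiked and background sites.

    Returns the tagged reads, a truth table (one row per simulated site,
    with the realized mutant-fragment count and supporting coordinates for
    spiked sites), and the reference the reads were drawn from.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reference = build_reference(config.panel, config.reference_seed)
    n_background = max(0, config.n_sites - len(config.spikes))
    taken = {(s.chrom, s.pos) for s in config.spikes}
    background = [
        site for site in auto_sites(
            config.panel, config.n_sites + len(config.spikes), config.read_length
        )
        if (site[0], site[1]) not in taken
    ][:n_background]

    all_reads: list[TaggedRead] = []
    truth_rows = []
    for i, spike in enumerate(config.spikes):
        duplex = rng.random() < config.fraction_duplex_sites
        reads, n_mut, coords = _simulate_site(
            config, rng, reference, spike.chrom, spike.pos, spike.alt,
            spike.truth_vaf, f"s{i}", duplex,
        )
        all_reads.extend(reads)
        truth_rows.append(
            {
                "chrom": spike.chrom,
                "pos": spike.pos,
                "ref": _ALPHABET[reference.codes_at(spike.chrom, np.array([spike.pos]))[0]],
                "alt": spike.alt,
                "gene": spike.gene,
                "truth_vaf": spike.truth_vaf,
                "n_fragments": config.consensus_depth_target,
                "realized_alt_fragments": n_mut,
                "supporting_coords": coords,
            }
        )
    for j, (chrom, pos, gene) in enumerate(background):
        reads, _, _ = _simulate_site(
            config, rng, reference, chrom, pos, None, 0.0, f"b{j}", True
        )
        all_reads.extend(reads)
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": _ALPHABET[reference.codes_at(chrom, np.array([pos]))[0]],
                "alt": None,
                "gene": gene,
                "truth_vaf": 0.0,
                "n_fragments": config.consensus_depth_target,
                "realized_alt_fragments": 0,
                "supporting_coords": (),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "truth_vaf",
                 "n_fragments", "realized_alt_fragments", "supporting_coords"],
    )
    return all_reads, truth, reference


TUMOR_VAF_RANGE = (0.03, 0.8)  # published tumor VAF span
PLASMA_VAF_RANGE = (1e-4, 5e-2)  # published plasma detection span


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_sample(
    config: SimConfig,
    role: str,
    sample_id: str = "",
    paired_tumor_truth: pd.DataFrame | None = None,
    n_variants: int | None = None,
) -> SampleBundle:
    """Simulate one sample of the given role.

    Tumors spike 1..3 variants at high VAF; plasma cases re-spike the
    paired tumor's variants at low VAF (ctDNA shedding); controls spike
    nothing and carry background error only.
    """
    if role not in {"tumor", "plasma_case", "plasma_control"}:
        raise ValueError(f"unknown role {role!r}")
    rng = np.random.default_rng(config.seed)
    cfg = config
    if role == "tumor" and not cfg.spikes:
        k = n_variants if n_variants is not None else int(rng.integers(1, 4))
        sites = auto_sites(cfg.panel, k, cfg.read_length)
        reference = build_reference(cfg.panel, cfg.reference_seed)
        spikes = []
        for chrom, pos, gene in sites:
            ref_code = reference.codes_at(chrom, np.array([pos]))[0]
            alt = _ALPHABET[(int(ref_code) + int(rng.integers(1, 4))) % 4]
            spikes.append(
                SpikeSpec(chrom, pos, alt, rng.uniform(*TUMOR_VAF_RANGE), gene)
            )
        cfg = replace(cfg, spikes=spikes)
    elif role == "plasma_case":
        if paired_tumor_truth is None:
            raise ValueError("plasma_case requires the paired tumor truth")
        # shed VAFs in the paired truth are honored when provided (the
        # shedding model upstream decides them); absent values are drawn
        # from the plasma detection range
        spikes = []
        for row in paired_tumor_truth.itertuples(index=False):
            if row.alt is None:
                continue
            vaf = getattr(row, "truth_vaf", None)
            if vaf is None or not np.isfinite(vaf) or vaf <= 0:
                vaf = _loguniform(rng, *PLASMA_VAF_RANGE)
            spikes.append(SpikeSpec(row.chrom, int(row.pos), row.alt,
                                    float(vaf), row.gene))
        cfg = replace(cfg, spikes=spikes)
    elif role == "plasma_control":
        cfg = replace(cfg, spikes=[], n_sites=max(1, cfg.n_sites))

    reads, truth, reference = simulate_read_families(cfg, rng)
    tissue_prep = "fresh_frozen" if role == "tumor" else "plasma"
    sheet_row = {
        "sample_id": sample_id,
        "role": role,
        "tissue_prep": tissue_prep,
        "n_spiked": int((truth["truth_vaf"] > 0).sum()),
    }
    return SampleBundle(
        sample_id=sample_id,
        role=role,
        tissue_prep=tissue_prep,
        reads=reads,
        truth=truth,
        reference=reference,
        panel=cfg.panel,
        sheet_row=sheet_row,
    )


# ---------------------------------------------------------------------------
# Cohort-level generation


@dataclass(frozen=True, slots=True)
class SheddingModel:
    """Stage-dependent ctDNA shedding: P(shed) and the shed-VAF range."""

    shed_prob: dict = None  # stage_group -> probability
    vaf_range: tuple = PLASMA_VAF_RANGE

    def __post_init__(self):
        if self.shed_prob is None:
            object.__setattr__(
                self, "shed_prob", {"1": 0.25, "2": 0.30, "3": 0.50}
            )

    def draw(self, stage_group: str, rng: np.random.Generator) -> float:
        """Returns the shed VAF, or 0.0 when the tumor does not shed."""
        if rng.random() >= self.shed_prob.get(stage_group, 0.3):
            return 0.0
        return _loguniform(rng, *self.vaf_range)


_STAGE_GROUPS = ["1", "2", "3"]
_STAGE_WEIGHTS = [0.32, 0.55, 0.13]  # published stage mix (1A+1B, 2A+2B, 3A+3C)


def default_covariate_model(rng: np.random.Generator) -> dict:
    """Draw Table-1-like clinicopathological covariates."""
    return {
        "stage_group": rng.choice(_STAGE_GROUPS, p=_STAGE_WEIGHTS),
        "grade": rng.choice(["I", "II", "III"], p=[0.20, 0.50, 0.30]),
        "er": rng.choice(["positive", "negative"], p=[0.90, 0.10]),
        "pr": rng.choice(["positive", "negative"], p=[0.77, 0.23]),
        "her2": rng.choice(["positive", "negative"], p=[0.08, 0.92]),
        "relapse": rng.choice(["Y", "N"], p=[0.11, 0.89]),
    }


@dataclass(slots=True)
class CohortBundle:
    """Lazily realized cohort: sheet + truths now, reads on demand."""

    sample_sheet: pd.DataFrame
    truths: dict
    _configs: dict
    _roles: dict
    _paired_truths: dict

    def realize(self, sample_id: str) -> SampleBundle:
        return simulate_sample(
            self._configs[sample_id],
            self._roles[sample_id],
            sample_id=sample_id,
            paired_tumor_truth=self._paired_truths.get(sample_id),
        )

    def sample_ids(self) -> list[str]:
        return list(self._configs)


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    base_config: SimConfig,
    shedding_model: SheddingModel | None = None,
    covariate_model: Callable[[np.random.Generator], dict] | None = None,
    tumor_mutated_prob: float = 0.5633,
) -> CohortBundle:
    """Simulate a case/control cohort with known per-sample truth.

    Each case gets covariates, a tumor sample (mutated with the published
    prevalence) and a plasma sample whose spikes follow the stage-dependent
    shedding model; controls get clean plasma. Reads are generated lazily
    per sample, deterministically from the master seed.
    """
    shedding = shedding_model or SheddingModel()
    covars = covariate_model or default_covariate_model

    def child_seed(*material) -> int:
        seq = np.random.SeedSequence([int(base_config.seed), *material])
        return int(seq.generate_state(1)[0] % (2**31 - 1))

    rows, truths = [], {}
    configs, roles, paired = {}, {}, {}
    empty_truth = pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "gene", "truth_vaf",
                 "n_fragments", "realized_alt_fragments", "supporting_coords"]
    )
    for i in range(n_cases):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(child_seed(i, 0))
        cov = covars(rng)
        mutated = rng.random() < tumor_mutated_prob
        n_var = 1 + int(rng.poisson(0.5)) if mutated else 0
        tumor_id, plasma_id = f"{pid}T", f"{pid}P"

        shed_truth = empty_truth
        if n_var:
            tumor_cfg = replace(
                base_config, seed=child_seed(i, 1), n_sites=n_var
            )
            tumor_truth = simulate_sample(
                tumor_cfg, "tumor", sample_id=tumor_id, n_variants=n_var
            ).truth
            configs[tumor_id] = tumor_cfg
            roles[tumor_id] = "tumor"
            truths[tumor_id] = tumor_truth
            rows.append({"sample_id": tumor_id, "patient_id": pid,
                         "role": "tumor", "links": plasma_id, **cov})
            shed_rng = np.random.default_rng(child_seed(i, 2))
            shed_truth = tumor_truth.copy()
            shed_truth["truth_vaf"] = [
                shedding.draw(cov["stage_group"], shed_rng)
                for _ in range(len(shed_truth))
            ]
            shed_truth = shed_truth[shed_truth["truth_vaf"] > 0]

        plasma_cfg = replace(
            base_config, seed=child_seed(i, 3), n_sites=max(1, len(shed_truth))
        )
        configs[plasma_id] = plasma_cfg
        roles[plasma_id] = "plasma_case"
        paired[plasma_id] = shed_truth
        truths[plasma_id] = simulate_sample(
            plasma_cfg, "plasma_case", sample_id=plasma_id,
            paired_tumor_truth=shed_truth,
        ).truth
        rows.append({"sample_id": plasma_id, "patient_id": pid,
                     "role": "plasma_case", "links": tumor_id if n_var else "",
                     **cov})

    for j in range(n_controls):
        cid = f"HC{j + 1:02d}"
        cfg = replace(
            base_config, seed=child_seed(n_cases + j, 4), spikes=[], n_sites=1
        )
        configs[cid] = cfg
        roles[cid] = "plasma_control"
        truths[cid] = empty_truth
        rows.append({"sample_id": cid, "patient_id": cid,
                     "role": "plasma_control", "links": ""})

    sheet = pd.DataFrame(rows)
    return CohortBundle(sheet, truths, configs, roles, paired)


def annotation_from_truth(truths) -> AnnotationIndex:
    """Mark every spiked variant as a known exonic COSMIC/TCGA mutation.

    Spikes emulate recurrent breast-cancer hotspot mutations, which is what
    the database criteria of the naive pipeline key on; background errors
    are absent from the index and therefore look database-negative.
    """
    index = AnnotationIndex()
    frames = truths.values() if isinstance(truths, dict) else [truths]
    seen = set()
    for truth in frames:
        if truth is None or len(truth) == 0:
            continue
        for row in truth.itertuples(index=False):
            if row.alt is None or row.truth_vaf == 0:
                continue
            key = (row.chrom, int(row.pos) + 1, row.ref, row.alt)
            if key in seen:
                continue
            seen.add(key)
            index.add(
                AnnotationRecord(
                    chrom=row.chrom, pos=int(row.pos) + 1, ref=row.ref,
                    alt=row.alt, in_cosmic=True, in_tcga_bc=True,
                    in_tcga_all=True, exonic=True, gene=row.gene,
                )
            )
    return index


def consensus_error_rate_by_family_size(
    family_sizes: Sequence[int],
    n_families: int,
    error_rate: float,
    seed: int,
    base_quality: int = 37,
    min_base_quality: int = 30,
) -> dict[int, float]:
    """Monte-Carlo consensus error rate per family size.

    Simulates n_families single-base families per size from a fixed true
    base with the given per-read error rate, calls consensus, and reports
    the fraction of families whose consensus differs from the truth (an N
    counts as an error). Vectorized; used for the error-suppression
    property of molecular consensus.
    """
    from .umi_consensus import _consensus_arrays

    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for k in family_sizes:
        bases = np.zeros((n_families, k, 1), dtype=np.uint8)  # true base A
        err = rng.random(bases.shape) < error_rate
        shift = rng.integers(1, 4, bases.shape)
        bases[err] = (bases[err] + shift[err]) % 4
        quals = np.full(bases.shape, base_quality, dtype=np.uint8)
        cons, _ = _consensus_arrays(bases, quals, min_base_quality)
        out[int(k)] = float((cons[:, 0] != 0).mean())
    return out
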