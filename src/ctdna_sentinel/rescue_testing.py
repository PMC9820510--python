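"""The exploratory "rescue" path: recover tumor-known mutations that the
caller missed in plasma.

For each variant in the paired tumor's stringent call set, the plasma
pileup is interrogated directly (the programmatic equivalent of eyeballing
alignments in a genome browser): mutant and wild-type consensus-fragment
counts are tallied at the site, in the patient's plasma and in a pool of
control plasmas sequenced identically. A one-sided Fisher exact test asks
whether the patient's mutant-allele proportion exceeds the pooled
background; a variant is rescued when the test is significant *and* the
mutant support comes from at least two fragments starting at different
genomic coordinates.

The default control pool is healthy donors only — adding mutation-negative
patient plasmas is supported but noisier (their cfDNA can carry trace
amounts of the same mutation). No multiple-testing correction gates the
decision; a Benjamini-Hochberg column is attached as supplementary output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .candidate_calling import PileupCounts, Variant
from .formats_io import PanelRegion

DEFAULT_ALPHA = 0.05

_SIDED = {"greater": "greater", "two-sided": "two-sided", "one": "greater", "two": "two-sided"}


@dataclass(slots=True)
class SiteInterrogation:
    """Allele counts for one variant site in one sample."""

    variant_key: tuple
    alt_count: int
    ref_count: int
    supporting_coords: frozenset[int]

    def __post_init__(self) -> None:
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(slots=True)
class RescueResult:
    """Outcome of the Fisher rescue test for one variant."""

    variant_key: tuple
    sample_alt: int
    sample_ref: int
    pooled_alt: int
    pooled_ref: int
    p_value: float
    control_pool_used: str  # healthy_only | healthy_plus_negative_patients
    passed: bool
    bh_q: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0,1]")


def _site_allele(variant: Variant) -> str:
    return "*" if variant.var_class in ("indel", "splice") else variant.alt


def interrogate_site(
    consensus_pileups: Mapping[tuple[str, int], PileupCounts],
    variant: Variant,
    panel: Sequence[PanelRegion] | None = None,
) -> SiteInterrogation:
    """Count mutant and wild-type consensus fragments at a variant site.

    Indel and splice variants are carried as the simulator/caller's
    single-token "*" allele at the variant's leftmost reference position.
    A covered panel site simply absent from the pileup map yields zero
    counts; a site outside the panel is an error.
    """
    pos0 = variant.pos - 1
    if panel is not None and not any(r.contains(variant.chrom, pos0) for r in panel):
        raise ValueError(
            f"site {variant.chrom}:{variant.pos} lies outside the capture panel"
        )
    pc = consensus_pileups.get((variant.chrom, pos0))
    allele = _site_allele(variant)
    if pc is None:
        return SiteInterrogation(variant.key, 0, 0, frozenset())
    return SiteInterrogation(
        variant_key=variant.key,
        alt_count=pc.alt_count(allele),
        ref_count=pc.ref_count(),
        supporting_coords=frozenset(pc.supporting_coords.get(allele, ())),
    )


def coordinate_support_rule(interrogation: SiteInterrogation) -> bool:
    """True iff >=2 supporting reads at >=2 distinct start coordinates."""
    return (
        interrogation.alt_count >= 2
        and len(interrogation.supporting_coords) >= 2
    )


def pool_control_counts(
    interrogations: Iterable[SiteInterrogation],
) -> tuple[int, int]:
    """Element-wise sums of alt and ref counts over a control pool."""
    alt = ref = 0
    n = 0
    for si in interrogations:
        alt += si.alt_count
        ref += si.ref_count
        n += 1
    if n == 0:
        raise ValueError("control pool is empty")
    return alt, ref


def fisher_rescue_test(
    sample: SiteInterrogation,
    pooled_controls: tuple[int, int],
    alpha: float = DEFAULT_ALPHA,
    sided: str = "greater",
    control_pool_used: str = "healthy_only",
) -> RescueResult:
    """Fisher exact test of the 2x2 table
    [[sample alt, sample ref], [pooled alt, pooled ref]].

    passed requires p < alpha AND the two-distinct-coordinates support rule.
    An all-zero table gives p = 1 and never passes.
    """
    pooled_alt, pooled_ref = pooled_controls
    table = [[sample.alt_count, sample.ref_count], [pooled_alt, pooled_ref]]
    if sum(table[0]) + sum(table[1]) == 0:
        p = 1.0
    else:
        _, p = fisher_exact(table, alternative=_SIDED[sided])
    return RescueResult(
        variant_key=sample.variant_key,
        sample_alt=sample.alt_count,
        sample_ref=sample.ref_count,
        pooled_alt=pooled_alt,
        pooled_ref=pooled_ref,
        p_value=float(p),
        control_pool_used=control_pool_used,
        passed=bool(p < alpha and coordinate_support_rule(sample)),
    )


def null_rescue_screen(
    n_sites: int,
    depth: int = 2500,
    error_rate: float = 3e-4,
    n_controls: int = 22,
    control_depth: int = 2500,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    coord_window: int = 25,
) -> float:
    """Type-I behaviour of the rescue screen under the null.

    Simulates the screen at the allele-count level: the case sample and
    every control carry the identical post-consensus error rate and a true
    VAF of zero; supporting coordinates for the spurious case alleles are
    drawn from a read-length window. Returns the fraction of sites the
    screen (Fisher + coordinate rule) wrongly rescues; the one-sided test
    is conservative, so this sits at or below alpha.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    rejected = 0
    sample_alts = rng.binomial(depth, error_rate, n_sites)
    control_alts = rng.binomial(control_depth, error_rate, (n_sites, n_controls))
    for i in range(n_sites):
        alt = int(sample_alts[i])
        coords = frozenset(rng.integers(0, coord_window, alt).tolist())
        si = SiteInterrogation(("null", i), alt, depth - alt, coords)
        pooled = (int(control_alts[i].sum()),
                  n_controls * control_depth - int(control_alts[i].sum()))
        if fisher_rescue_test(si, pooled, alpha=alpha).passed:
            rejected += 1
    return rejected / n_sites


def rescue_pass(
    tumor_variants: Sequence[Variant],
    plasma_pileups: Mapping[tuple[str, int], PileupCounts],
    control_pileups: Mapping[str, Mapping[tuple[str, int], PileupCounts]],
    panel: Sequence[PanelRegion] | None = None,
    negative_patient_pileups: Mapping[str, Mapping[tuple[str, int], PileupCounts]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    sided: str = "greater",
) -> list[RescueResult]:
    """Run the rescue test for every caller-missed tumor variant.

    One pooled 2x2 table per variant; the pool is healthy controls only
    unless negative-patient pileups are supplied, in which case they are
    added (the noisier published sensitivity analysis). Results come back
    in deterministic (chrom, pos, alt) order with a supplementary BH
    column; BH never gates the pass decision.
    """
    pool_label = (
        "healthy_plus_negative_patients"
        if negative_patient_pileups
        else "healthy_only"
    )
    ordered = sorted(tumor_variants, key=lambda v: (v.chrom or "", v.pos, v.alt))
    results: list[RescueResult] = []
    for variant in ordered:
        sample_si = interrogate_site(plasma_pileups, variant, panel)
        pool_sites = [
            interrogate_site(pileups, variant, panel)
            for pileups in control_pileups.values()
        ]
        if negative_patient_pileups:
            pool_sites.extend(
                interrogate_site(pileups, variant, panel)
                for pileups in negative_patient_pileups.values()
            )
        pooled = pool_control_counts(pool_sites)
        results.append(
            fisher_rescue_test(
                sample_si, pooled, alpha=alpha, sided=sided,
                control_pool_used=pool_label,
            )
        )
    if results:
        _, qvals, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, q in zip(results, qvals):
            r.bh_q = float(q)
    return results
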