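"""Pileup construction over panel regions, VAF computation, a
frequency-based candidate caller, and the region coverage QC rule.

The candidate caller is deliberately simple — one candidate per site and
non-reference allele with enough supporting consensus fragments. The
discriminating power of the pipeline lives downstream in the stringent
filters and the rescue test, which are caller-agnostic: externally
produced VCFs are accepted interchangeably.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import PanelRegion
from .umi_consensus import ConsensusRead, N, decode_bases, _ALPHABET


class Reference:
    """Sparse reference sequence: per-chromosome (start, base-code) segments.

    Panel regions on one chromosome can sit megabases apart, so the
    reference is held as disjoint segments rather than one array.
    """

    def __init__(self) -> None:
        self._segments: dict[str, list[tuple[int, np.ndarray]]] = {}

    def add_segment(self, chrom: str, start: int, codes: np.ndarray) -> None:
        self._segments.setdefault(chrom, []).append((start, codes))
        self._segments[chrom].sort(key=lambda seg: seg[0])

    def codes_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        out = np.empty(len(positions), dtype=np.uint8)
        covered = np.zeros(len(positions), dtype=bool)
        for start, seq in self._segments.get(chrom, ()):
            sel = (positions >= start) & (positions < start + len(seq))
            out[sel] = seq[positions[sel] - start]
            covered |= sel
        if not covered.all():
            bad = positions[~covered][:3]
            raise KeyError(f"positions not covered by reference: {chrom}:{bad}")
        return out

    def base(self, chrom: str, pos: int) -> str:
        return _ALPHABET[self.codes_at(chrom, np.array([pos]))[0]]

    def segments(self, chrom: str) -> list[tuple[int, np.ndarray]]:
        return list(self._segments.get(chrom, ()))

    def chroms(self) -> list[str]:
        return list(self._segments)

    def to_tsv(self, path) -> None:
        """Serialize segments as TSV (chrom, 0-based start, base string)."""
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tseq\n")
            for chrom in self._segments:
                for start, seq in self._segments[chrom]:
                    fh.write(f"{chrom}\t{start}\t{decode_bases(seq)}\n")

    @classmethod
    def from_tsv(cls, path) -> "Reference":
        from .umi_consensus import encode_bases

        ref = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom\t"):
                raise ValueError("reference TSV must start with a chrom header")
            for line in fh:
                chrom, start, seq = line.rstrip("\n").split("\t")
                ref.add_segment(chrom, int(start), encode_bases(seq))
        return ref


@dataclass(slots=True)
class Variant:
    """A genomic substitution or simple indel/splice token."""

    chrom: str | None
    pos: int  # 1-based; 0 when unknown (fixture variants key on HGVS)
    ref: str
    alt: str
    gene: str = ""
    sample_id: str = ""
    vaf: float | None = None
    var_class: str = "substitution"  # substitution | indel | splice

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be a fraction in [0,1], got {self.vaf}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(slots=True)
class PileupCounts:
    """Allele-resolved consensus-fragment counts at one site (0-based pos)."""

    chrom: str
    pos: int
    ref: str
    counts: dict[str, int] = field(default_factory=dict)
    supporting_coords: dict[str, set[int]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def alt_count(self, allele: str) -> int:
        return self.counts.get(allele, 0)

    def ref_count(self) -> int:
        return self.counts.get(self.ref, 0)


def _panel_mask(
    positions: np.ndarray, regions: Sequence[PanelRegion]
) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for r in regions:
        mask |= (positions >= r.start) & (positions < r.end)
    return mask


def build_pileup(
    consensus_reads: Iterable[ConsensusRead],
    panel: Sequence[PanelRegion],
    reference: Reference,
) -> dict[tuple[str, int], PileupCounts]:
    """Count consensus fragments per site and allele inside panel regions.

    N bases are excluded from all counts; each fragment contributes once
    per position (overlap clipping upstream guarantees mates never double
    count). Positions never covered are absent from the returned map.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    by_chrom: dict[str, list[ConsensusRead]] = {}
    for cr in consensus_reads:
        by_chrom.setdefault(cr.chrom, []).append(cr)

    pileups: dict[tuple[str, int], PileupCounts] = {}
    for chrom, reads in by_chrom.items():
        regions = [r for r in panel if r.chrom == chrom]
        if not regions:
            continue
        positions = np.concatenate(
            [r.start + np.arange(len(r.bases)) for r in reads]
        )
        bases = np.concatenate([r.bases for r in reads])
        frag_starts = np.concatenate(
            [np.full(len(r.bases), r.fragment_start, dtype=np.int64) for r in reads]
        )
        keep = (bases != N) & _panel_mask(positions, regions)
        positions, bases, frag_starts = positions[keep], bases[keep], frag_starts[keep]
        if len(positions) == 0:
            continue
        uniq_pos, inverse = np.unique(positions, return_inverse=True)
        ref_codes = reference.codes_at(chrom, uniq_pos)
        n_codes = len(_ALPHABET)
        counts = np.bincount(
            inverse * n_codes + bases, minlength=len(uniq_pos) * n_codes
        ).reshape(len(uniq_pos), n_codes)
        for i, pos in enumerate(uniq_pos):
            pc = PileupCounts(chrom, int(pos), _ALPHABET[ref_codes[i]])
            for code in range(n_codes):
                if counts[i, code]:
                    pc.counts[_ALPHABET[code]] = int(counts[i, code])
            pileups[(chrom, int(pos))] = pc
        # distinct fragment start coordinates, only for non-reference alleles
        nonref = bases != ref_codes[inverse]
        for idx in np.nonzero(nonref)[0]:
            pc = pileups[(chrom, int(positions[idx]))]
            allele = _ALPHABET[bases[idx]]
            pc.supporting_coords.setdefault(allele, set()).add(int(frag_starts[idx]))
    return pileups


def compute_vaf(alt_count: int, depth: int) -> float | None:
    """alt_count / depth as a fraction; None (undefined) at zero depth."""
    if alt_count < 0 or depth < 0:
        raise ValueError("counts must be non-negative")
    if alt_count > depth:
        raise ValueError(f"alt_count {alt_count} exceeds depth {depth}")
    if depth == 0:
        return None
    return alt_count / depth


def _gene_label(panel: Sequence[PanelRegion], chrom: str, pos: int) -> str:
    for r in panel:
        if r.contains(chrom, pos):
            return r.label
    return ""


def call_candidates(
    pileups: Mapping[tuple[str, int], PileupCounts],
    min_alt_fragments: int = 1,
    panel: Sequence[PanelRegion] = (),
    sample_id: str = "",
) -> list[Variant]:
    """Emit one candidate per (site, non-reference allele) with enough
    supporting consensus fragments, in deterministic (chrom, pos, alt) order."""
    out: list[Variant] = []
    for (chrom, pos), pc in pileups.items():
        for allele, count in pc.counts.items():
            if allele == pc.ref or count < min_alt_fragments:
                continue
            out.append(
                Variant(
                    chrom=chrom,
                    pos=pos + 1,
                    ref=pc.ref,
                    alt=allele,
                    gene=_gene_label(panel, chrom, pos),
                    sample_id=sample_id,
                    vaf=compute_vaf(count, pc.depth),
                    var_class="indel" if allele == "*" else "substitution",
                )
            )
    out.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return out


def region_coverage_qc(
    pileups: Mapping[tuple[str, int], PileupCounts],
    panel: Sequence[PanelRegion],
    min_depth: int = 100,
    max_low_fraction: float = 0.10,
) -> tuple[pd.DataFrame, float]:
    """Flag regions where strictly more than max_low_fraction of bases sit
    below min_depth; also return the median per-base depth over the panel.

    Uncovered panel positions count as depth 0. The boundary is strict:
    a region with exactly 10% low bases passes.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rows = []
    all_depths: list[np.ndarray] = []
    for r in panel:
        depths = np.zeros(len(r), dtype=np.int64)
        for (chrom, pos), pc in pileups.items():
            if chrom == r.chrom and r.start <= pos < r.end:
                depths[pos - r.start] = pc.depth
        low_fraction = float((depths < min_depth).mean())
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "label": r.label,
                "low_fraction": low_fraction,
                "flagged_low": low_fraction > max_low_fraction,
            }
        )
        all_depths.append(depths)
    median_coverage = float(np.median(np.concatenate(all_depths)))
    return pd.DataFrame(rows), median_coverage
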