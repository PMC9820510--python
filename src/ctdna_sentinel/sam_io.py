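"""SAM dialect for UMI-tagged reads (pysam-backed).

Reads are gapless base vectors on the reference, so every record carries a
single-M CIGAR. The UMI travels in a configurable tag (RX by default);
fragment coordinates and orientation travel in XS/XE/XO, the mate label in
XM. Spiked indel-marker alleles (code "*") cannot be expressed in a SAM
SEQ field, so their read offsets are stashed in the XI tag and restored on
read-back.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .formats_io import PanelRegion
from .umi_consensus import ConsensusRead, INDEL_CODE, TaggedRead, encode_bases


def _header(panel: Sequence[PanelRegion]) -> pysam.AlignmentHeader:
    maxima: dict[str, int] = {}
    for r in panel:
        maxima[r.chrom] = max(maxima.get(r.chrom, 0), r.end)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": chrom, "LN": end + 1} for chrom, end in maxima.items()],
        }
    )


def write_reads_sam(
    reads: Iterable[TaggedRead], path: str | Path, panel: Sequence[PanelRegion],
    umi_tag: str = "RX",
) -> None:
    header = _header(panel)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(header)
            rec.query_name = read.read_id
            rec.reference_name = read.chrom
            rec.reference_start = read.start
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(read.bases))]
            seq = read.bases.copy()
            indel_offsets = np.nonzero(seq == INDEL_CODE)[0]
            seq[seq > 3] = 4  # anything unrepresentable becomes N in SEQ
            rec.query_sequence = "".join("ACGTN"[b] for b in seq)
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.quals)
            )
            rec.set_tag(umi_tag, read.umi)
            rec.set_tag("XS", read.fragment_start)
            rec.set_tag("XE", read.fragment_end)
            rec.set_tag("XO", read.strand_orientation)
            rec.set_tag("XM", read.mate)
            if len(indel_offsets):
                rec.set_tag("XI", ",".join(map(str, indel_offsets)))
            out.write(rec)


def write_consensus_sam(
    consensus: Iterable[ConsensusRead], path: str | Path,
    panel: Sequence[PanelRegion],
) -> None:
    """Consensus reads as SAM; family size in XF, family key in RX/XS/XE/XO."""
    header = _header(panel)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, cr in enumerate(consensus):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"consensus:{i}"
            rec.reference_name = cr.chrom
            rec.reference_start = cr.start
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(cr.bases))]
            seq = cr.bases.copy()
            indel_offsets = np.nonzero(seq == INDEL_CODE)[0]
            seq[seq > 3] = 4
            rec.query_sequence = "".join("ACGTN"[b] for b in seq)
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in cr.quals)
            )
            umi, _, fs, fe, orient = cr.key
            rec.set_tag("RX", umi)
            rec.set_tag("XS", fs)
            rec.set_tag("XE", fe)
            rec.set_tag("XO", orient)
            rec.set_tag("XF", cr.family_size)
            if len(indel_offsets):
                rec.set_tag("XI", ",".join(map(str, indel_offsets)))
            out.write(rec)


def read_consensus_sam(path: str | Path) -> list[ConsensusRead]:
    out: list[ConsensusRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            bases = encode_bases(rec.query_sequence)
            if rec.has_tag("XI"):
                for off in str(rec.get_tag("XI")).split(","):
                    bases[int(off)] = INDEL_CODE
            key = (
                str(rec.get_tag("RX")), rec.reference_name,
                int(rec.get_tag("XS")), int(rec.get_tag("XE")),
                str(rec.get_tag("XO")),
            )
            out.append(
                ConsensusRead(
                    key=key,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    bases=bases,
                    quals=np.asarray(rec.query_qualities, dtype=np.uint8),
                    family_size=int(rec.get_tag("XF")),
                )
            )
    return out


def read_tagged_reads_sam(
    path: str | Path, umi_tag: str = "RX"
) -> list[TaggedRead]:
    reads: list[TaggedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            bases = encode_bases(rec.query_sequence)
            if rec.has_tag("XI"):
                for off in str(rec.get_tag("XI")).split(","):
                    bases[int(off)] = INDEL_CODE
            reads.append(
                TaggedRead(
                    read_id=rec.query_name,
                    umi=str(rec.get_tag(umi_tag)),
                    chrom=rec.reference_name,
                    fragment_start=int(rec.get_tag("XS")),
                    fragment_end=int(rec.get_tag("XE")),
                    strand_orientation=str(rec.get_tag("XO")),
                    mate=str(rec.get_tag("XM")),
                    start=rec.reference_start,
                    bases=bases,
                    quals=np.asarray(rec.query_qualities, dtype=np.uint8),
                )
            )
    return reads
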