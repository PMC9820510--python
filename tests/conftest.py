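"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from ctdna_sentinel.formats_io import PanelRegion
from ctdna_sentinel.umi_consensus import TaggedRead, encode_bases


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """Brute-force one-sided Fisher p-value by hypergeometric enumeration.

    Exact rational arithmetic over all tables with the observed margins
    whose top-left cell is >= a. Independent of scipy.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    total = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        if 0 <= c1 - x <= r2:
            total += Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    return float(total)


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher by enumeration: sum of all table probabilities
    not exceeding the observed table's probability."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    observed = probs[a]
    # scipy counts tables with p <= p_obs * (1 + 1e-7) to absorb rounding
    return float(sum(p for p in probs.values() if p <= observed))


@pytest.fixture
def small_panel() -> list[PanelRegion]:
    return [PanelRegion("chr1", 0, 300, "GENE1")]


@pytest.fixture
def mk_read():
    """Factory for a TaggedRead from plain strings."""

    def _mk(
        umi: str = "ACGTACGTAC",
        start: int = 10,
        bases: str = "ACGT",
        quals=None,
        chrom: str = "chr1",
        fragment_start: int | None = None,
        fragment_end: int | None = None,
        orientation: str = "F1R2",
        mate: str = "read1",
        read_id: str = "r",
    ) -> TaggedRead:
        codes = encode_bases(bases)
        if quals is None:
            quals = np.full(len(codes), 37, dtype=np.uint8)
        else:
            quals = np.asarray(quals, dtype=np.uint8)
        fs = fragment_start if fragment_start is not None else start
        fe = fragment_end if fragment_end is not None else fs + len(codes)
        return TaggedRead(
            read_id=read_id, umi=umi, chrom=chrom, fragment_start=fs,
            fragment_end=fe, strand_orientation=orientation, mate=mate,
            start=start, bases=codes, quals=quals,
        )

    return _mk
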