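import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdna_sentinel.simulate import consensus_error_rate_by_family_size
from ctdna_sentinel.umi_consensus import (
    ReadFamily,
    call_consensus_batch,
    call_consensus_read,
    clip_overlap,
    decode_bases,
    filter_consensus_reads,
    group_reads_by_umi,
)


class TestGrouping:
    def test_identical_key_collapses(self, mk_read):
        reads = [mk_read(umi="ACGTAAGG", start=100, bases="ACGT", read_id=f"r{i}")
                 for i in range(2)]
        fams = group_reads_by_umi(reads)
        assert len(fams) == 1 and fams[0].size == 2

    def test_one_mismatch_umi_stays_separate(self, mk_read):
        # degenerate barcodes: identity matching, no edit-distance clustering
        reads = [mk_read(umi="ACGTAAGG", start=100),
                 mk_read(umi="ACGTAAGC", start=100)]
        assert len(group_reads_by_umi(reads)) == 2

    def test_fragment_coordinates_in_key(self, mk_read):
        reads = [mk_read(umi="ACGTAAGG", start=100),
                 mk_read(umi="ACGTAAGG", start=101)]
        assert len(group_reads_by_umi(reads)) == 2

    def test_empty_input(self):
        assert group_reads_by_umi([]) == []

    @given(
        st.lists(
            st.tuples(st.sampled_from(["AA", "AC", "CA"]),
                      st.integers(0, 2), st.sampled_from(["F1R2", "F2R1"])),
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_grouping_is_a_partition(self, keys):
        from ctdna_sentinel.umi_consensus import TaggedRead

        reads = [
            TaggedRead(
                read_id=f"r{i}", umi=u, chrom="chr1",
                fragment_start=100 + s, fragment_end=104 + s,
                strand_orientation=o, mate="read1", start=100 + s,
                bases=np.zeros(4, dtype=np.uint8),
                quals=np.full(4, 37, dtype=np.uint8),
            )
            for i, (u, s, o) in enumerate(keys)
        ]
        fams = group_reads_by_umi(reads)
        members = [m.read_id for f in fams for m in f.members]
        assert sorted(members) == sorted(r.read_id for r in reads)
        assert sum(f.size for f in fams) == len(reads)


class TestConsensus:
    def test_unanimous_family_reproduces_read(self, mk_read):
        fam = ReadFamily(("u", "chr1", 10, 14, "F1R2"),
                         [mk_read(bases="ACGT") for _ in range(3)])
        cons = call_consensus_read(fam)
        assert decode_bases(cons.bases) == "ACGT"
        assert cons.family_size == 3

    def test_equal_quality_tie_masks_to_n(self, mk_read):
        fam = ReadFamily(("u", "chr1", 10, 14, "F1R2"),
                         [mk_read(bases="ACGT"), mk_read(bases="AGGT")])
        cons = call_consensus_read(fam)
        assert decode_bases(cons.bases) == "ANGT"

    def test_majority_restores_true_base_all_two_vs_one_splits(self, mk_read):
        # enumeration oracle: for every (true base, error base, position),
        # two agreeing qualified reads must always outvote one dissenter
        for true, err, pos in itertools.product("ACGT", "ACGT", range(4)):
            if true == err:
                continue
            clean = ["ACGT"[(i + 1) % 4] for i in range(4)]
            clean[pos] = true
            errored = clean.copy()
            errored[pos] = err
            fam = ReadFamily(
                ("u", "chr1", 10, 14, "F1R2"),
                [mk_read(bases="".join(clean)), mk_read(bases="".join(clean)),
                 mk_read(bases="".join(errored))],
            )
            assert decode_bases(call_consensus_read(fam).bases)[pos] == true

    def test_low_quality_bases_do_not_vote(self, mk_read):
        fam = ReadFamily(
            ("u", "chr1", 10, 14, "F1R2"),
            [mk_read(bases="ACGT", quals=[37, 37, 37, 37]),
             mk_read(bases="AAGT", quals=[37, 20, 37, 37])],
        )
        # the disagreeing base at position 1 is below Q30: lone qualified C wins
        cons = call_consensus_read(fam)
        assert decode_bases(cons.bases)[1] == "C"

    def test_no_qualified_bases_masks_to_n(self, mk_read):
        fam = ReadFamily(("u", "chr1", 10, 14, "F1R2"),
                         [mk_read(bases="ACGT", quals=[10, 10, 10, 10])])
        assert decode_bases(call_consensus_read(fam).bases) == "NNNN"

    def test_ragged_members_rejected(self, mk_read):
        fam = ReadFamily(("u", "chr1", 10, 14, "F1R2"),
                         [mk_read(bases="ACGT"), mk_read(bases="ACG")])
        with pytest.raises(ValueError, match="aligned"):
            call_consensus_read(fam)

    def test_batch_matches_per_family_calls(self, mk_read):
        rng = np.random.default_rng(7)
        fams = []
        for i in range(60):
            k = int(rng.integers(1, 6))
            length = int(rng.integers(3, 8))
            bases = ["".join(rng.choice(list("ACGT"), length)) for _ in range(k)]
            fams.append(
                ReadFamily(
                    (f"u{i}", "chr1", 10, 10 + length, "F1R2"),
                    [mk_read(umi=f"u{i}", bases=b, start=10) for b in bases],
                )
            )
        singles = [call_consensus_read(f) for f in fams]
        batch = call_consensus_batch(fams)
        for s, b in zip(singles, batch):
            assert np.array_equal(s.bases, b.bases)
            assert np.array_equal(s.quals, b.quals)


class TestFilterAndClip:
    def test_family_size_threshold(self, mk_read):
        fams = [
            ReadFamily(("a", "chr1", 0, 4, "F1R2"), [mk_read(start=0)] * 2),
            ReadFamily(("b", "chr1", 0, 4, "F1R2"), [mk_read(start=0)] * 3),
        ]
        cons = call_consensus_batch(fams)
        assert [c.family_size for c in filter_consensus_reads(cons, 3)] == [3]
        assert filter_consensus_reads(cons, 1) == cons  # min 1 is the identity

    def test_min_family_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            filter_consensus_reads([], 0)

    def _cons(self, mk_read, start, length, qual=37):
        fam = ReadFamily(
            ("u", "chr1", start, start + length, "F1R2"),
            [mk_read(bases="A" * length, start=start,
                     quals=[qual] * length)],
        )
        return call_consensus_read(fam)

    def test_overlap_masked_on_exactly_one_mate(self, mk_read):
        c1 = self._cons(mk_read, 0, 30)
        c2 = self._cons(mk_read, 10, 30, qual=35)
        a, b = clip_overlap((c1, c2))
        # overlap is [10, 30): 20 bp; kept on the higher-quality mate (c1)
        assert decode_bases(a.bases) == "A" * 30
        assert decode_bases(b.bases) == "N" * 20 + "A" * 10

    def test_disjoint_mates_unchanged(self, mk_read):
        c1 = self._cons(mk_read, 0, 10)
        c2 = self._cons(mk_read, 50, 10)
        assert clip_overlap((c1, c2)) == (c1, c2)

    def test_nested_mate_fully_masked(self, mk_read):
        # position-set oracle: overlap = positions of the inner mate
        outer = self._cons(mk_read, 0, 40)
        inner = self._cons(mk_read, 10, 10, qual=35)
        a, b = clip_overlap((outer, inner))
        covered_once = set(range(0, 40))
        kept_a = {a.start + i for i, base in enumerate(a.bases) if base != 4}
        kept_b = {b.start + i for i, base in enumerate(b.bases) if base != 4}
        assert kept_a | kept_b == covered_once
        assert kept_a & kept_b == set()

    def test_cross_chromosome_mates_rejected(self, mk_read):
        c1 = self._cons(mk_read, 0, 10)
        fam = ReadFamily(("u", "chr2", 0, 10, "F1R2"),
                         [mk_read(bases="A" * 10, start=0, chrom="chr2")])
        c2 = call_consensus_read(fam)
        with pytest.raises(ValueError):
            clip_overlap((c1, c2))


def test_consensus_error_rate_non_increasing_in_family_size():
    """Error suppression: bigger families make fewer consensus errors."""
    rates = consensus_error_rate_by_family_size([1, 3, 5, 7], 20_000, 0.05, seed=11)
    values = [rates[k] for k in (1, 3, 5, 7)]
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert values[0] > values[-1]
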