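"""Read-level signature extraction: CIGAR scanning, split-read geometry,
and the additivity property behind streaming/offline equivalence."""
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from svstream.io_formats import AlignmentRecord, SupplementarySegment, parse_cigar
from svstream.signatures import (
    ExtractionParams,
    Segment,
    cigar_signatures,
    extract_batch_signatures,
    segments_from_record,
    split_read_signatures,
)

P = ExtractionParams()


def rec(cigar, ref_start=1000, read_id="r1", contig="chr1", strand="+",
        mapq=60, sa=()):
    return AlignmentRecord(read_id=read_id, contig=contig, ref_start=ref_start,
                           strand=strand, mapq=mapq, cigar=parse_cigar(cigar),
                           is_primary=True, is_supplementary=False,
                           sa_segments=tuple(sa))


class TestCigarSignatures:
    @pytest.mark.parametrize(
        "cigar, expected",
        [
            ("100M50D100M", [("DEL", 1100, 50)]),
            ("100M20D100M", []),  # below min_size
            ("100M40D10M40D100M", [("DEL", 1100, 80)]),  # merge across spacer
            ("100M120I100M", [("INS", 1100, 120)]),
            # two I ops 100 bp apart: length-weighted mean anchor, summed length
            ("100M30I100M30I100M", [("INS", 1150, 60)]),
            # unequal lengths: (1100*10 + 1200*50)/60 = 1183.33 -> 1183
            ("100M10I100M50I100M", [("INS", 1183, 60)]),
            ("300M", []),
            # merge happens before the size filter: 20+20 -> kept
            ("100M20D100M20D100M", [("DEL", 1100, 40)]),
            # beyond merge_dist: separate candidates, each filtered alone
            ("100M20D600M20D100M", []),
            ("100M40D600M40D100M", [("DEL", 1100, 40), ("DEL", 1740, 40)]),
        ],
    )
    def test_examples(self, cigar, expected):
        sigs = cigar_signatures(rec(cigar), P)
        assert [(s.svtype, s.start, s.length) for s in sigs] == expected

    def test_soft_clips_do_not_shift_reference(self):
        sigs = cigar_signatures(rec("50S100M50D100M50S"), P)
        assert [(s.svtype, s.start, s.length) for s in sigs] == [("DEL", 1100, 50)]


class TestSegments:
    def test_primary_only(self):
        (seg,) = segments_from_record(rec("100M"), P)
        assert (seg.query_start, seg.query_end) == (0, 100)
        assert (seg.ref_start, seg.ref_end) == (1000, 1100)

    def test_sa_pair_sorted_by_query(self):
        sa = SupplementarySegment("chr1", 16000, "+", parse_cigar("5000S5000M"), 60)
        r = rec("5000M5000S", ref_start=10000, sa=[sa])
        segs = segments_from_record(r, P)
        assert [(s.query_start, s.query_end) for s in segs] == [(0, 5000), (5000, 10000)]
        assert segs[1].ref_start == 16000

    def test_low_mapq_or_short_sa_dropped(self):
        short = SupplementarySegment("chr1", 16000, "+", parse_cigar("5000S100M4900S"), 60)
        lowq = SupplementarySegment("chr1", 16000, "+", parse_cigar("5000S5000M"), 5)
        r = rec("5000M5000S", ref_start=10000, sa=[short, lowq])
        assert len(segments_from_record(r, P)) == 1

    def test_reverse_strand_query_flipped(self):
        # reverse-strand segment: clips flip onto the forward-read axis
        sa = SupplementarySegment("chr1", 16000, "-", parse_cigar("5000M5000S"), 60)
        r = rec("5000M5000S", ref_start=10000, sa=[sa])
        segs = segments_from_record(r, P)
        # reverse alignment covering its own [0,5000) maps to forward [5000,10000)
        assert (segs[1].query_start, segs[1].query_end) == (5000, 10000)

    def test_hard_clipped_supplementary_reconstructed(self):
        sa = SupplementarySegment("chr1", 16000, "+", parse_cigar("5000H5000M"), 60)
        r = rec("5000M5000S", ref_start=10000, sa=[sa])
        segs = segments_from_record(r, P)
        assert (segs[1].query_start, segs[1].query_end) == (5000, 10000)


def seg(qs, qe, rs, re_, strand="+", contig="chr1"):
    return Segment(qs, qe, contig, rs, re_, strand, 60)


class TestSplitReadSignatures:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            # reference gap >> query gap: deletion
            (seg(0, 5000, 10000, 15000), seg(5000, 10000, 16000, 21000),
             [("DEL", "chr1", 15000, 1000)]),
            # query gap >> reference gap: insertion
            (seg(0, 5000, 10000, 15000), seg(5400, 10400, 15000, 20000),
             [("INS", "chr1", 15000, 400)]),
            # strand flip: inversion spanning both segments
            (seg(0, 5000, 10000, 15000), seg(5000, 10000, 15000, 20000, "-"),
             [("INV", "chr1", 10000, 10000)]),
            # reference rewind: tandem duplication
            (seg(0, 5000, 10000, 15000), seg(5000, 10000, 14000, 19000),
             [("DUP", "chr1", 14000, 1000)]),
            # contig change: breakend
            (seg(0, 5000, 10000, 15000), seg(5000, 10000, 500, 4500, contig="chr2"),
             [("BND", "chr1", 15000, 0)]),
            # small ref/query discrepancy: nothing
            (seg(0, 5000, 10000, 15000), seg(5000, 10000, 15010, 20010), []),
        ],
    )
    def test_pair_geometry(self, a, b, expected):
        sigs = split_read_signatures([a, b], "r1", P)
        assert [(s.svtype, s.contig, s.start, s.length) for s in sigs] == expected

    def test_bnd_carries_mate(self):
        sigs = split_read_signatures(
            [seg(0, 5000, 10000, 15000), seg(5000, 10000, 500, 4500, contig="chr2")],
            "r1", P)
        assert sigs[0].mate_contig == "chr2" and sigs[0].mate_pos == 500

    def test_only_consecutive_pairs(self):
        # three collinear segments -> two deletion signatures, not three
        segs = [seg(0, 3000, 10000, 13000), seg(3000, 6000, 14000, 17000),
                seg(6000, 9000, 18000, 21000)]
        sigs = split_read_signatures(segs, "r1", P)
        assert [(s.svtype, s.start, s.length) for s in sigs] == \
            [("DEL", 13000, 1000), ("DEL", 17000, 1000)]


class TestExtractBatch:
    def test_pure_match_batch_is_empty(self):
        records = [rec("1000M", read_id=f"r{i}") for i in range(5)]
        assert extract_batch_signatures(records, P) == []

    def test_duplicate_records_keep_duplicate_signatures(self):
        r = rec("100M50D100M")
        sigs = extract_batch_signatures([r, r], P)
        assert len(sigs) == 2  # deduplication is clustering's job via read_id

    def test_additivity_over_read_partitions(self, default_scenario):
        """Extracting per-batch and over the concatenation gives the same
        multiset — the property that makes streaming equal offline."""
        records = default_scenario.sim.records[:400]
        whole = Counter(extract_batch_signatures(records, P))
        # split keeping each read's records together
        cut = len(records) // 3
        while cut < len(records) and records[cut].read_id == records[cut - 1].read_id:
            cut += 1
        parts = Counter(extract_batch_signatures(records[:cut], P))
        parts += Counter(extract_batch_signatures(records[cut:], P))
        assert parts == whole

    def test_signature_positions_inside_contigs(self, default_scenario):
        sigs = extract_batch_signatures(default_scenario.sim.records, P)
        for s in sigs:
            assert 0 <= s.start < default_scenario.contigs.length(s.contig)


@st.composite
def cigar_with_big_gapped_dels(draw):
    """CIGARs whose D ops are all >= min_size and separated by > merge_dist."""
    n = draw(st.integers(1, 4))
    parts, dels = [], []
    for i in range(n):
        parts.append(("M", draw(st.integers(501, 800))))
        d = draw(st.integers(30, 400))
        dels.append(d)
        parts.append(("D", d))
    parts.append(("M", draw(st.integers(1, 500))))
    return tuple(parts), dels


@settings(max_examples=60, derandomize=True)
@given(cigar_with_big_gapped_dels())
def test_del_length_conservation(case):
    """With all D ops >= min_size and pairwise gaps > merge_dist, emitted DEL
    lengths equal the multiset of D lengths."""
    cigar, dels = case
    r = AlignmentRecord("r1", "chr1", 0, "+", 60, cigar, True, False)
    sigs = cigar_signatures(r, P)
    assert sorted(s.length for s in sigs if s.svtype == "DEL") == sorted(dels)
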