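"""Read-level SV signature extraction.

Two evidence classes are produced from long-read alignments:

* intra-alignment signatures — insertions (I) and deletions (D) inside a
  single alignment's CIGAR; nearby same-type events on one read are merged
  before the size filter, so a deletion interrupted by a short matched
  spacer still counts as one event;
* inter-alignment signatures — split reads, i.e. a primary alignment plus
  the supplementary alignments listed in its SA tag. The geometry of
  consecutive segments in read (query) order implies the SV class:
  a reference gap larger than the query gap is a deletion, the reverse an
  insertion, a strand flip an inversion, a reference rewind a tandem
  duplication, and a contig change a breakend.

Extraction is per-record/per-read only, which makes it additive over any
partition of a batch set that keeps a read's records together — the property
that lets a streaming run reproduce the offline callset exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._util import round_half_up
from .io_formats import AlignmentRecord, QUERY_OPS, REF_OPS

__all__ = [
    "Signature",
    "Segment",
    "ExtractionParams",
    "cigar_signatures",
    "segments_from_record",
    "split_read_signatures",
    "extract_batch_signatures",
]


@dataclass(frozen=True)
class Signature:
    """One read-level piece of SV evidence."""

    svtype: str  # DEL | INS | INV | DUP | BND
    contig: str
    start: int  # 0-based
    length: int  # 0 for BND
    read_id: str
    origin: str  # intra | inter
    mate_contig: Optional[str] = None  # BND only
    mate_pos: Optional[int] = None


@dataclass(frozen=True)
class Segment:
    """Split-read geometry: one alignment segment in forward-read coordinates."""

    query_start: int
    query_end: int
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int


@dataclass(frozen=True)
class ExtractionParams:
    min_size: int = 30  # smallest SV length reported
    merge_dist: int = 500  # bp; same-type CIGAR events closer than this merge
    min_mapq: int = 20
    min_segment_len: int = 300  # bp of reference a supplementary segment must span

    def __post_init__(self) -> None:
        for name in ("min_size", "merge_dist", "min_mapq", "min_segment_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sig_sort_key(s: Signature):
    return (
        s.contig,
        s.start,
        s.svtype,
        s.length,
        s.read_id,
        s.origin,
        s.mate_contig or "",
        -1 if s.mate_pos is None else s.mate_pos,
    )


def _merge_chain(cands: list[tuple[int, int]], merge_dist: int) -> list[list[tuple[int, int]]]:
    """Chain candidates (anchor, length) whose consecutive anchors are within
    merge_dist."""
    groups: list[list[tuple[int, int]]] = []
    for c in cands:
        if groups and c[0] - groups[-1][-1][0] <= merge_dist:
            groups[-1].append(c)
        else:
            groups.append([c])
    return groups


def cigar_signatures(
    rec: AlignmentRecord, params: ExtractionParams = ExtractionParams()
) -> list[Signature]:
    """Intra-alignment DEL/INS candidates from one record's CIGAR.

    Every D/I op is a candidate regardless of size; same-type candidates
    within merge_dist of each other (by anchor) merge first, and only then
    is the min_size filter applied — so e.g. 40D 10M 40D yields one 80 bp
    deletion. Merged deletions keep the first start and sum their D lengths;
    merged insertions anchor at the length-weighted mean position (rounded
    half-up) and sum their I lengths.
    """
    ref = rec.ref_start
    dels: list[tuple[int, int]] = []
    inss: list[tuple[int, int]] = []
    for op, n in rec.cigar:
        if op in ("M", "=", "X"):
            ref += n
        elif op == "D":
            dels.append((ref, n))
            ref += n
        elif op == "N":
            ref += n
        elif op == "I":
            inss.append((ref, n))
        # S, H, P consume no reference
    out: list[Signature] = []
    for group in _merge_chain(dels, params.merge_dist):
        total = sum(l for _, l in group)
        if total >= params.min_size:
            out.append(
                Signature("DEL", rec.contig, group[0][0], total, rec.read_id, "intra")
            )
    for group in _merge_chain(inss, params.merge_dist):
        total = sum(l for _, l in group)
        if total >= params.min_size:
            anchor = round_half_up(
                sum(a * l for a, l in group) / total
            )
            out.append(Signature("INS", rec.contig, anchor, total, rec.read_id, "intra"))
    out.sort(key=sig_sort_key)
    return out


def _clip_lengths(cigar: Sequence[tuple[str, int]]) -> tuple[int, int, int]:
    """(leading clip, trailing clip, aligned query length) counting S and H."""
    lead = trail = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in ("S", "H"):
        lead += cigar[i][1]
        i += 1
    j = len(cigar) - 1
    while j >= 0 and cigar[j][0] in ("S", "H"):
        trail += cigar[j][1]
        j -= 1
    aligned = sum(n for op, n in cigar if op in ("M", "I", "=", "X"))
    return lead, trail, aligned


def _segment(contig, ref_start, strand, cigar, mapq, read_len: int) -> Segment:
    lead, trail, aligned = _clip_lengths(cigar)
    qs, qe = lead, lead + aligned
    if strand == "-":  # express on the forward-strand read
        qs, qe = read_len - qe, read_len - qs
    ref_end = ref_start + sum(n for op, n in cigar if op in REF_OPS)
    return Segment(qs, qe, contig, ref_start, ref_end, strand, mapq)


def segments_from_record(
    rec: AlignmentRecord, params: ExtractionParams = ExtractionParams()
) -> list[Segment]:
    """Segments of one read: the primary plus its SA-tag supplementaries.

    Query coordinates are normalised to the forward-strand read so segments
    from both strands share one axis. Supplementary segments below min_mapq
    or spanning less reference than min_segment_len are dropped; the primary
    is always kept (its mapq was gated at batch reading).
    """
    lead, trail, aligned = _clip_lengths(rec.cigar)
    read_len = lead + aligned + trail
    segs = [_segment(rec.contig, rec.ref_start, rec.strand, rec.cigar, rec.mapq, read_len)]
    for sa in rec.sa_segments:
        if sa.mapq < params.min_mapq:
            continue
        seg = _segment(sa.contig, sa.ref_start, sa.strand, sa.cigar, sa.mapq, read_len)
        if seg.ref_end - seg.ref_start < params.min_segment_len:
            continue
        segs.append(seg)
    segs.sort(key=lambda s: (s.query_start, s.ref_start))
    return segs


def split_read_signatures(
    segments: Sequence[Segment],
    read_id: str,
    params: ExtractionParams = ExtractionParams(),
) -> list[Signature]:
    """Inter-alignment signatures from consecutive segment pairs (query order)."""
    out: list[Signature] = []
    for a, b in zip(segments, segments[1:]):
        if a.contig != b.contig:
            out.append(
                Signature(
                    "BND", a.contig, a.ref_end, 0, read_id, "inter",
                    mate_contig=b.contig, mate_pos=b.ref_start,
                )
            )
        elif a.strand != b.strand:
            start = min(a.ref_start, b.ref_start)
            span = max(a.ref_end, b.ref_end) - start
            if span >= params.min_size:
                out.append(Signature("INV", a.contig, start, span, read_id, "inter"))
        elif b.ref_start >= a.ref_end:
            ref_gap = b.ref_start - a.ref_end
            query_gap = b.query_start - a.query_end
            if ref_gap - query_gap >= params.min_size:
                out.append(
                    Signature("DEL", a.contig, a.ref_end, ref_gap - query_gap, read_id, "inter")
                )
            elif query_gap - ref_gap >= params.min_size:
                out.append(
                    Signature("INS", a.contig, a.ref_end, query_gap - ref_gap, read_id, "inter")
                )
        elif b.ref_start < a.ref_end - params.min_size:
            out.append(
                Signature("DUP", a.contig, b.ref_start, a.ref_end - b.ref_start, read_id, "inter")
            )
    return out


def extract_batch_signatures(
    records: Iterable[AlignmentRecord],
    params: ExtractionParams = ExtractionParams(),
) -> list[Signature]:
    """All signatures of one batch: CIGAR evidence from every mapped record
    plus split-read evidence from each primary's segment set. Output order is
    canonical (contig, start, svtype, read_id), so any batch partition that
    keeps a read's records together yields the same multiset union.
    """
    out: list[Signature] = []
    for rec in records:
        out.extend(cigar_signatures(rec, params))
        if rec.is_primary and rec.sa_segments:
            segs = segments_from_record(rec, params)
            out.extend(split_read_signatures(segs, rec.read_id, params))
    out.sort(key=sig_sort_key)
    return out
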