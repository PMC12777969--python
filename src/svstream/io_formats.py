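"""Alignment-batch and VCF I/O.

Coordinates are 0-based half-open everywhere inside the package; the single
conversion to the 1-based inclusive convention happens here, at the VCF
boundary. VCF output is rendered as text by this module (rather than through
a library writer) so that repeated runs over the same callset are
byte-identical: the header's date and source lines are injected from
configuration and default to fixed strings.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from ._util import atomic_write_text
from .feedback import TruthRecord

log = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "SupplementarySegment",
    "ContigTable",
    "TruthSet",
    "BatchReadError",
    "ContigMismatchError",
    "VcfStyle",
    "read_alignment_batch",
    "write_vcf",
    "read_truth_vcf",
]

# pysam cigar op codes 0..8 -> SAM characters
CIGAR_OPS = "MIDNSHP=X"
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class BatchReadError(RuntimeError):
    """A batch file could not be read (missing/truncated/garbled).

    Recoverable: the engine re-queues the batch up to its retry limit.
    """


class ContigMismatchError(ValueError):
    """A record names a contig absent from the run's contig table (hard error)."""


@dataclass(frozen=True)
class SupplementarySegment:
    """One entry of a primary record's SA tag."""

    contig: str
    ref_start: int  # 0-based
    strand: str  # '+' or '-'
    cigar: tuple[tuple[str, int], ...]
    mapq: int


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    contig: str
    ref_start: int  # 0-based
    strand: str
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    is_primary: bool
    is_supplementary: bool
    sa_segments: tuple[SupplementarySegment, ...] = ()

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_OPS)


class ContigTable:
    """Ordered (name, length) reference contigs; the order fixes sort order
    for every callset the run produces."""

    def __init__(self, pairs: Iterable[tuple[str, int]]):
        pairs = [(str(n), int(l)) for n, l in pairs]
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        if any(l <= 0 for _, l in pairs):
            raise ValueError("contig lengths must be positive")
        self._pairs = pairs
        self._index = {n: i for i, (n, _) in enumerate(pairs)}
        self._length = dict(pairs)

    @classmethod
    def from_fai(cls, path) -> "ContigTable":
        pairs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.split("\t")
                pairs.append((fields[0], int(fields[1])))
        return cls(pairs)

    @classmethod
    def from_sam_header(cls, path) -> "ContigTable":
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            return cls(zip(af.references, af.lengths))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._pairs]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self._pairs)

    def __len__(self):
        return len(self._pairs)

    def __eq__(self, other):
        return isinstance(other, ContigTable) and self._pairs == other._pairs

    def length(self, name: str) -> int:
        return self._length[name]

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self._pairs)


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text))
    if not ops or "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"malformed CIGAR: {text!r}")
    return ops


def cigar_to_str(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def parse_sa_tag(tag: str) -> tuple[SupplementarySegment, ...]:
    """Parse the standard SA tag (`rname,pos,strand,CIGAR,mapQ,NM;` entries)."""
    out = []
    for entry in tag.strip().split(";"):
        if not entry:
            continue
        rname, pos, strand, cig, mapq, _nm = entry.split(",")
        out.append(
            SupplementarySegment(
                contig=rname,
                ref_start=int(pos) - 1,
                strand=strand,
                cigar=parse_cigar(cig),
                mapq=int(mapq),
            )
        )
    return tuple(out)


def read_alignment_batch(
    path, min_mapq: int = 20, contigs: Optional[ContigTable] = None
) -> list[AlignmentRecord]:
    """Read one batch (SAM or BAM), keeping mapped records with
    mapq >= min_mapq; secondary alignments are dropped, supplementaries kept.
    File order is preserved.
    """
    records: list[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for a in af:
                if a.is_unmapped or a.is_secondary:
                    continue
                if a.mapping_quality < min_mapq:
                    continue
                contig = a.reference_name
                if contigs is not None and contig not in contigs:
                    raise ContigMismatchError(
                        f"contig {contig!r} in {path} absent from contig table"
                    )
                sa: tuple[SupplementarySegment, ...] = ()
                if not a.is_supplementary and a.has_tag("SA"):
                    sa = parse_sa_tag(a.get_tag("SA"))
                records.append(
                    AlignmentRecord(
                        read_id=a.query_name,
                        contig=contig,
                        ref_start=a.reference_start,
                        strand="-" if a.is_reverse else "+",
                        mapq=a.mapping_quality,
                        cigar=tuple((CIGAR_OPS[op], n) for op, n in a.cigartuples),
                        is_primary=not a.is_supplementary,
                        is_supplementary=a.is_supplementary,
                        sa_segments=sa,
                    )
                )
    except ContigMismatchError:
        raise
    except Exception as exc:  # truncated/garbled batch -> recoverable
        raise BatchReadError(f"failed to read batch {path}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# VCF output


@dataclass(frozen=True)
class VcfStyle:
    """Injectable header metadata; fixed defaults keep output byte-stable."""

    file_date: str = "20250101"
    source: str = "svstream"
    sample: str = "SAMPLE"


_ALT_DEFS = {
    "DEL": "Deletion",
    "INS": "Insertion",
    "DUP": "Duplication",
    "INV": "Inversion",
    "BND": "Breakend",
}


def vcf_header_lines(
    contigs: ContigTable, style: VcfStyle = VcfStyle(), with_af: bool = False
) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        f"##fileDate={style.file_date}",
        f"##source={style.source}",
    ]
    lines += [f"##contig=<ID={n},length={l}>" for n, l in contigs]
    lines += [f'##ALT=<ID={k},Description="{v}">' for k, v in _ALT_DEFS.items()]
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of distinct supporting reads">',
    ]
    if with_af:
        lines.append(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">'
        )
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference-supporting reads">',
        '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + style.sample,
    ]
    return lines


def _vcf_end(svtype: str, pos0: int, length: int) -> int:
    # 1-based inclusive END; point events (INS, BND) end at POS
    if svtype in ("DEL", "INV", "DUP"):
        return pos0 + length
    return pos0 + 1


def write_vcf(
    calls: Sequence,
    contigs: ContigTable,
    path,
    style: VcfStyle = VcfStyle(),
) -> None:
    """Write a callset as VCF 4.2, atomically (temp file + rename).

    Calls must be sorted by (contig-table order, position); unsorted input is
    a hard error. Output is byte-identical across repeated runs.
    """
    keys = [(contigs.index(c.contig), c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (contig order, position)")

    lines = vcf_header_lines(contigs, style)
    counters: dict[str, int] = {}
    for c in calls:
        k = counters.get(c.svtype, 0)
        counters[c.svtype] = k + 1
        pos1 = c.pos + 1
        svlen = -c.length if c.svtype == "DEL" else c.length
        end = _vcf_end(c.svtype, c.pos, c.length)
        if c.svtype == "BND":
            alt = f"N[{c.mate_contig}:{c.mate_pos + 1}["
        else:
            alt = f"<{c.svtype}>"
        info = f"SVTYPE={c.svtype};SVLEN={svlen};END={end};SUPPORT={c.dv}"
        lines.append(
            "\t".join(
                [
                    c.contig,
                    str(pos1),
                    f"SV.{c.svtype}.{k}",
                    "N",
                    alt,
                    str(c.qual),
                    "PASS",
                    info,
                    "GT:DR:DV",
                    f"{c.gt}:{c.dr}:{c.dv}",
                ]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Truth VCF input


class TruthSet(list):
    """List of TruthRecord with a count of skipped (unresolvable) records."""

    n_skipped: int = 0


def _record_svtype(rec) -> Optional[str]:
    svtype = rec.info.get("SVTYPE")
    if svtype:
        return str(svtype)
    for alt in rec.alts or ():
        m = re.fullmatch(r"<(\w+)(?::[\w:]+)?>", alt)
        if m:
            return m.group(1)
        if "[" in alt or "]" in alt:
            return "BND"
    return None


def _record_af(rec) -> Optional[float]:
    try:
        af = rec.info.get("AF")
    except (KeyError, ValueError):  # AF not declared in this file's header
        af = None
    if af is not None:
        if isinstance(af, (tuple, list)):
            af = af[0]
        return float(af)
    # fall back to allele counts over sample genotypes
    alt = called = 0
    for sample in rec.samples.values():
        gt = sample.get("GT")
        if gt is None:
            continue
        for allele in gt:
            if allele is None:
                continue
            called += 1
            if allele > 0:
                alt += 1
    if called:
        return alt / called
    return None


def read_truth_vcf(path) -> TruthSet:
    """Read a truth/population SV callset.

    Length comes from SVLEN, falling back to END - POS; BND records get
    length 0. Records whose type or length cannot be resolved are skipped
    with a logged warning and counted on the returned list's ``n_skipped``.
    """
    out = TruthSet()
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = _record_svtype(rec)
            if svtype is None:
                log.warning("skipping truth record without resolvable SVTYPE at %s:%s",
                            rec.chrom, rec.pos)
                skipped += 1
                continue
            if svtype == "BND":
                length = 0
            else:
                svlen = rec.info.get("SVLEN")
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                if svlen is not None:
                    length = abs(int(svlen))
                elif rec.stop is not None and rec.stop > rec.start:
                    length = rec.stop - rec.start
                else:
                    log.warning("skipping truth record without resolvable length at %s:%s",
                                rec.chrom, rec.pos)
                    skipped += 1
                    continue
            out.append(
                TruthRecord(
                    contig=rec.chrom,
                    pos=rec.start,  # pysam .start is 0-based
                    svtype=svtype,
                    length=length,
                    af=_record_af(rec),
                )
            )
    out.n_skipped = skipped
    return out
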