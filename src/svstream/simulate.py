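"""Synthetic sequencer-output fixtures.

Generates, with no external tools or downloads, everything needed to
exercise the streaming caller end to end: a random reference, a set of
implanted SVs with population-style allele frequencies, alignment records
carrying the corresponding evidence, and equal-size SAM batches materialised
into a directory the way a sequencer drips output files.

Alignments are constructed directly rather than produced by an aligner: a
read overlapping a deletion (on the variant allele) carries a D op of the
SV's length in its CIGAR, an insertion an I op, and inversions,
duplications and breakends are emitted as a primary + supplementary record
pair whose SA tags and query intervals follow exactly the split-read
geometry the signature extractor expects. Noise comes from breakpoint
jitter, per-read evidence dropout (the read is drawn from the reference
allele), and background 1-10 bp indels that sit strictly below the
extractor's size threshold.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    ContigTable,
    SupplementarySegment,
    VcfStyle,
    cigar_to_str,
    vcf_header_lines,
)
from ._util import atomic_write_text

__all__ = [
    "SvSpec",
    "SimParams",
    "TruthSV",
    "SimResult",
    "Scenario",
    "make_reference",
    "sample_sv_set",
    "write_truth_vcf",
    "simulate_alignments",
    "write_batches",
    "generate_scenario",
]

SV_TYPES = ("DEL", "INS", "INV", "DUP", "BND")


@dataclass(frozen=True)
class SvSpec:
    """What to implant. Inversions and duplications default to larger sizes
    than indels because split-read detection needs each segment of the pair
    to span a few hundred bases of reference."""

    n_del: int = 12
    n_ins: int = 12
    n_inv: int = 6
    n_dup: int = 6
    n_bnd: int = 4
    size_range: dict = field(
        default_factory=lambda: {
            "DEL": (50, 500),
            "INS": (50, 500),
            "INV": (800, 2000),
            "DUP": (800, 2000),
            "BND": (0, 0),
        }
    )
    min_spacing: int = 2000
    het_fraction: float = 0.5
    af_range: tuple[float, float] = (0.02, 0.6)
    seed: int = 42

    def counts(self) -> dict[str, int]:
        return {
            "DEL": self.n_del, "INS": self.n_ins, "INV": self.n_inv,
            "DUP": self.n_dup, "BND": self.n_bnd,
        }


@dataclass(frozen=True)
class SimParams:
    coverage: float = 20.0
    read_length_mean: float = 8000.0
    read_length_sd: float = 2000.0
    read_length_floor: int = 500
    breakpoint_jitter_sd: float = 10.0
    dropout: float = 0.1  # per read per SV: evidence omitted (reference allele)
    background_indel_per_kb: float = 0.2
    background_size_range: tuple[int, int] = (1, 10)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TruthSV:
    svid: int
    contig: str
    pos: int  # 0-based
    svtype: str
    length: int
    zygosity: str  # het | hom
    af: float
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None


@dataclass
class SimResult:
    records: list[AlignmentRecord]
    implanted_support: dict[int, int]  # svid -> evidence-carrying reads


def make_reference(
    n_contigs: int, length_each: int, seed: int, out_fasta=None
) -> ContigTable:
    """Uniform-random A/C/G/T contigs, deterministic under seed. Writes the
    FASTA (plus a .fai index) when a path is given; the downstream pipeline
    itself consumes only the contig table."""
    if length_each < 10_000:
        raise ValueError("contigs must be at least 10 kb")
    rng = np.random.default_rng(seed)
    contigs = ContigTable((f"ctg{i + 1}", length_each) for i in range(n_contigs))
    if out_fasta is not None:
        width = 80
        parts = []
        offsets = []
        offset = 0
        for name, length in contigs:
            seq = "".join(rng.choice(list("ACGT"), size=length))
            header = f">{name}\n"
            offset += len(header)
            offsets.append((name, length, offset, width, width + 1))
            body = "\n".join(seq[i:i + width] for i in range(0, length, width)) + "\n"
            offset += len(body)
            parts.append(header + body)
        atomic_write_text(out_fasta, "".join(parts))
        fai = "".join(
            f"{n}\t{l}\t{o}\t{lb}\t{lw}\n" for n, l, o, lb, lw in offsets
        )
        atomic_write_text(str(out_fasta) + ".fai", fai)
    return contigs


def _far_enough(placed: list[tuple[int, int]], start: int, end: int, spacing: int) -> bool:
    return all(start - e >= spacing or s - end >= spacing for s, e in placed)


def sample_sv_set(contigs: ContigTable, spec: SvSpec = SvSpec()) -> list[TruthSV]:
    """Place the requested SVs uniformly, subject to a minimum pairwise
    spacing; zygosity and allele frequency are drawn independently (AF plays
    the role of a population frequency for the feedback filter)."""
    rng = np.random.default_rng(spec.seed)
    names = contigs.names
    weights = np.array([contigs.length(n) for n in names], dtype=float)
    weights /= weights.sum()
    margin = 2500
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    raw: list[dict] = []
    if spec.n_bnd > 0 and len(names) < 2:
        raise ValueError("breakends need at least two contigs")
    for svtype in SV_TYPES:
        lo, hi = spec.size_range[svtype]
        for _ in range(spec.counts()[svtype]):
            for attempt in range(500):
                contig = names[int(rng.choice(len(names), p=weights))]
                clen = contigs.length(contig)
                length = 0 if svtype == "BND" else int(rng.integers(lo, hi + 1))
                span = max(length, 1)
                if clen - span - 2 * margin <= 0:
                    continue
                pos = int(rng.integers(margin, clen - span - margin))
                if not _far_enough(placed[contig], pos, pos + span, spec.min_spacing):
                    continue
                entry = {"contig": contig, "pos": pos, "svtype": svtype, "length": length}
                if svtype == "BND":
                    others = [n for n in names if n != contig]
                    mate_c = others[int(rng.integers(len(others)))]
                    mlen = contigs.length(mate_c)
                    for _ in range(100):
                        mpos = int(rng.integers(margin, mlen - margin))
                        if _far_enough(placed[mate_c], mpos, mpos + 1, spec.min_spacing):
                            break
                    else:
                        continue
                    entry["mate_contig"] = mate_c
                    entry["mate_pos"] = mpos
                    placed[mate_c].append((mpos, mpos + 1))
                placed[contig].append((pos, pos + span))
                entry["zygosity"] = "het" if rng.random() < spec.het_fraction else "hom"
                entry["af"] = float(rng.uniform(*spec.af_range))
                raw.append(entry)
                break
            else:
                raise RuntimeError(
                    f"could not place a {svtype} given spacing {spec.min_spacing}"
                )
    raw.sort(key=lambda e: (contigs.index(e["contig"]), e["pos"]))
    return [
        TruthSV(svid=i, contig=e["contig"], pos=e["pos"], svtype=e["svtype"],
                length=e["length"], zygosity=e["zygosity"], af=e["af"],
                mate_contig=e.get("mate_contig"), mate_pos=e.get("mate_pos"))
        for i, e in enumerate(raw)
    ]


def write_truth_vcf(
    svs: Sequence[TruthSV], contigs: ContigTable, path, style: VcfStyle = VcfStyle()
) -> None:
    lines = vcf_header_lines(contigs, style, with_af=True)
    for sv in svs:
        pos1 = sv.pos + 1
        if sv.svtype == "BND":
            alt = f"N[{sv.mate_contig}:{sv.mate_pos + 1}["
            end = pos1
            svlen = 0
        else:
            alt = f"<{sv.svtype}>"
            end = sv.pos + sv.length if sv.svtype in ("DEL", "INV", "DUP") else pos1
            svlen = -sv.length if sv.svtype == "DEL" else sv.length
        gt = "0/1" if sv.zygosity == "het" else "1/1"
        lines.append(
            "\t".join(
                [
                    sv.contig, str(pos1), f"truth.{sv.svid}", "N", alt, ".", "PASS",
                    f"SVTYPE={sv.svtype};SVLEN={svlen};END={end};AF={sv.af:.4f}",
                    "GT", gt,
                ]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignment construction


def _jitter(rng, sd: float, clamp: int = 50) -> int:
    if sd <= 0:
        return 0
    return int(np.clip(round(rng.normal(0.0, sd)), -clamp, clamp))


def _carries(rng, zygosity: str, dropout: float) -> bool:
    p = (1.0 if zygosity == "hom" else 0.5) * (1.0 - dropout)
    return bool(rng.random() < p)


def _build_linear_read(
    rng, read_id, contig, clen, start, qlen, events, p: SimParams
):
    """CIGAR for a single-segment read: M runs interleaved with the ordered
    (ref_pos, kind, length, svid) events it carries. Returns (record, emitted
    svids) or None when geometry fails (event at the read edge)."""
    events = sorted(events, key=lambda e: e[0])
    ops: list[tuple[str, int]] = []
    cur = start
    m_used = 0
    ins_total = 0
    emitted = []
    for ref_pos, kind, length, svid in events:
        gap = ref_pos - cur
        if gap <= 0:
            continue
        ops.append(("M", gap))
        m_used += gap
        if kind == "D":
            ops.append(("D", length))
            cur = ref_pos + length
        else:
            ops.append(("I", length))
            ins_total += length
            cur = ref_pos
        if svid is not None:
            emitted.append(svid)
    tail_m = (qlen - ins_total) - m_used
    overflow = (cur + tail_m) - clen
    if overflow > 0:
        tail_m -= overflow
    if tail_m < 1:
        return None
    ops.append(("M", tail_m))
    rec = AlignmentRecord(
        read_id=read_id, contig=contig, ref_start=start,
        strand="+" if rng.random() < 0.5 else "-", mapq=60,
        cigar=tuple(ops), is_primary=True, is_supplementary=False,
    )
    return rec, emitted


def _split_pair(read_id, contig_a, a_start, a_len, strand_b, contig_b, b_start, b_len):
    """Primary + supplementary pair for one split read. Query layout: the
    primary occupies [0, a_len), the supplementary [a_len, a_len + b_len) of
    the forward-strand read."""
    a_cig = (("M", a_len), ("S", b_len))
    if strand_b == "+":
        b_cig = (("S", a_len), ("M", b_len))
    else:
        # reverse segment covering forward-read [a_len, a_len+b_len)
        b_cig = (("M", b_len), ("S", a_len))
    sa = SupplementarySegment(contig_b, b_start, strand_b, b_cig, 60)
    primary = AlignmentRecord(
        read_id=read_id, contig=contig_a, ref_start=a_start, strand="+",
        mapq=60, cigar=a_cig, is_primary=True, is_supplementary=False,
        sa_segments=(sa,),
    )
    suppl = AlignmentRecord(
        read_id=read_id, contig=contig_b, ref_start=b_start, strand=strand_b,
        mapq=60, cigar=b_cig, is_primary=False, is_supplementary=True,
    )
    return [primary, suppl]


def simulate_alignments(
    contigs: ContigTable, svs: Sequence[TruthSV], p: SimParams = SimParams()
) -> SimResult:
    """Construct the alignment records a long-read aligner would produce over
    the implanted SV set, at the requested coverage. Deterministic under
    ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    names = contigs.names
    lengths = np.array([contigs.length(n) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    total_len = contigs.total_length
    margin = 150

    simple = {n: [s for s in svs if s.contig == n and s.svtype in ("DEL", "INS")]
              for n in names}
    support: dict[int, int] = {s.svid: 0 for s in svs}
    records: list[AlignmentRecord] = []
    read_no = 0

    n_reads = int(round(p.coverage * total_len / p.read_length_mean))
    for _ in range(n_reads):
        contig = names[int(rng.choice(len(names), p=weights))]
        clen = contigs.length(contig)
        qlen = int(np.clip(rng.normal(p.read_length_mean, p.read_length_sd),
                           p.read_length_floor, clen - 1))
        start = int(rng.integers(0, clen - qlen + 1))
        events = []
        for sv in simple[contig]:
            if start + margin <= sv.pos <= start + qlen - margin:
                if not _carries(rng, sv.zygosity, p.dropout):
                    continue
                length = max(1, sv.length + _jitter(rng, p.breakpoint_jitter_sd))
                pos = sv.pos + _jitter(rng, p.breakpoint_jitter_sd)
                events.append((pos, "D" if sv.svtype == "DEL" else "I", length, sv.svid))
        lam = p.background_indel_per_kb * qlen / 1000.0
        for _ in range(int(rng.poisson(lam))):
            off = int(rng.integers(margin, qlen - margin))
            ref_pos = start + off
            if any(abs(ref_pos - e[0]) < 100 for e in events):
                continue
            size = int(rng.integers(p.background_size_range[0],
                                    p.background_size_range[1] + 1))
            kind = "D" if rng.random() < 0.5 else "I"
            events.append((ref_pos, kind, size, None))
        built = _build_linear_read(
            rng, f"r{read_no:06d}", contig, clen, start, qlen, events, p
        )
        read_no += 1
        if built is None:
            continue
        rec, emitted = built
        records.append(rec)
        for svid in emitted:
            support[svid] += 1

    # split-read support for balanced/complex events
    for sv in svs:
        if sv.svtype in ("DEL", "INS"):
            continue
        n_span = int(rng.poisson(p.coverage))
        n_carry = int(rng.binomial(n_span, (1.0 if sv.zygosity == "hom" else 0.5)
                                   * (1.0 - p.dropout)))
        clen = contigs.length(sv.contig)
        for _ in range(n_carry):
            rid = f"r{read_no:06d}"
            read_no += 1
            j1, j2 = _jitter(rng, p.breakpoint_jitter_sd), _jitter(rng, p.breakpoint_jitter_sd)
            if sv.svtype == "INV":
                s = sv.pos + sv.length // 2
                a_start = max(0, sv.pos + j1)
                b_end = min(clen, sv.pos + sv.length + j2)
                a_len, b_len = s - a_start, b_end - s
                if a_len < 301 or b_len < 301:
                    continue
                pair = _split_pair(rid, sv.contig, a_start, a_len, "-", sv.contig, s, b_len)
            elif sv.svtype == "DUP":
                j3, j4 = _jitter(rng, p.breakpoint_jitter_sd), _jitter(rng, p.breakpoint_jitter_sd)
                a_start = max(0, sv.pos + j1)
                a_len = min(clen, sv.pos + sv.length + j2) - a_start
                b_start = max(0, sv.pos + j3)
                b_len = min(clen, sv.pos + sv.length + j4) - b_start
                if a_len < 301 or b_len < 301:
                    continue
                pair = _split_pair(rid, sv.contig, a_start, a_len, "+", sv.contig, b_start, b_len)
            else:  # BND
                mlen = contigs.length(sv.mate_contig)
                a_len = int(rng.integers(500, 2000))
                b_len = int(rng.integers(500, 2000))
                p1 = max(400, sv.pos + j1)
                p2 = min(mlen - 400, max(0, sv.mate_pos + j2))
                a_len = min(a_len, p1)
                b_len = min(b_len, mlen - p2)
                if a_len < 301 or b_len < 301:
                    continue
                pair = _split_pair(rid, sv.contig, p1 - a_len, a_len, "+",
                                   sv.mate_contig, p2, b_len)
            records.extend(pair)
            support[sv.svid] += 1

    # shuffle whole reads so batches interleave loci like a real run
    groups: list[list[AlignmentRecord]] = []
    last = None
    for rec in records:
        if rec.read_id != last:
            groups.append([])
            last = rec.read_id
        groups[-1].append(rec)
    order = rng.permutation(len(groups))
    shuffled = [rec for i in order for rec in groups[i]]
    return SimResult(records=shuffled, implanted_support=support)


# ---------------------------------------------------------------------------
# Batch materialisation


def _sam_text(records: Sequence[AlignmentRecord], contigs: ContigTable) -> str:
    lines = ["@HD\tVN:1.6"]
    lines += [f"@SQ\tSN:{n}\tLN:{l}" for n, l in contigs]
    for rec in records:
        flag = 0
        if rec.strand == "-":
            flag |= 16
        if rec.is_supplementary:
            flag |= 2048
        fields = [
            rec.read_id, str(flag), rec.contig, str(rec.ref_start + 1),
            str(rec.mapq), cigar_to_str(rec.cigar), "*", "0", "0", "*", "*",
        ]
        if rec.sa_segments:
            sa = "".join(
                f"{s.contig},{s.ref_start + 1},{s.strand},{cigar_to_str(s.cigar)},{s.mapq},0;"
                for s in rec.sa_segments
            )
            fields.append(f"SA:Z:{sa}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def write_batches(
    records: Sequence[AlignmentRecord],
    batch_size: int,
    out_dir,
    contigs: ContigTable,
    interval: float = 0.0,
    jitter: float = 0.0,
    prefix: str = "batch_",
) -> list[Path]:
    """Split records in order into equal-size SAM batch files, keeping all
    records of one read in the same batch, and materialise them into out_dir
    (complete files only: temp name, then rename). interval > 0 sleeps
    between files to emulate a sequencer's cadence."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    batches: list[list[AlignmentRecord]] = [[]]
    last = None
    for rec in records:
        new_read = rec.read_id != last
        last = rec.read_id
        if new_read and len(batches[-1]) >= batch_size:
            batches.append([])
        batches[-1].append(rec)
    if batches == [[]]:
        batches = []
    rng = np.random.default_rng(0)
    paths = []
    for i, batch in enumerate(batches):
        if interval > 0 and i > 0:
            delay = interval + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)
            time.sleep(max(0.0, delay))
        path = out_dir / f"{prefix}{i:04d}.sam"
        atomic_write_text(path, _sam_text(batch, contigs))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# One-call scenario builder


@dataclass
class Scenario:
    root: Path
    contigs: ContigTable
    svs: list[TruthSV]
    truth_path: Path
    batch_dir: Path
    batch_paths: list[Path]
    sim: SimResult


def generate_scenario(
    out_dir,
    n_contigs: int = 2,
    contig_length: int = 500_000,
    spec: Optional[SvSpec] = None,
    sim_params: Optional[SimParams] = None,
    n_batches: int = 10,
    interval: float = 0.0,
    jitter: float = 0.0,
    write_fasta: bool = False,
    seed: Optional[int] = None,
) -> Scenario:
    """Build the full default study fixture in one call: reference, implanted
    truth set, simulated alignments, and equal-size batches dripped (or
    dropped at once) into ``out_dir/batches``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        spec = spec or SvSpec(seed=seed)
        sim_params = sim_params or SimParams(seed=seed)
    spec = spec or SvSpec()
    sim_params = sim_params or SimParams()
    contigs = make_reference(
        n_contigs, contig_length, spec.seed,
        out_fasta=(out_dir / "ref.fasta") if write_fasta else None,
    )
    svs = sample_sv_set(contigs, spec)
    truth_path = out_dir / "truth.vcf"
    write_truth_vcf(svs, contigs, truth_path)
    sim = simulate_alignments(contigs, svs, sim_params)
    batch_size = max(1, -(-len(sim.records) // n_batches))
    batch_dir = out_dir / "batches"
    paths = write_batches(sim.records, batch_size, batch_dir, contigs,
                          interval=interval, jitter=jitter)
    return Scenario(out_dir, contigs, svs, truth_path, batch_dir, paths, sim)
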