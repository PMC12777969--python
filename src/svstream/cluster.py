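"""Signature clustering, depth-adaptive support filtering and genotyping.

The accumulated signature store is re-clustered from scratch every cycle:
``call_variants`` is a pure function of (store, depth, params), which is what
makes interim callsets reproducible and the streaming run equal to an
offline single pass over the same batches.

The minimum number of distinct supporting reads a cluster needs scales with
run-level mean depth (a fixed fraction, clamped to a floor and cap), so
thresholds step upward as sequencing accumulates — low-support calls that
were reportable at shallow depth may transiently drop out when the threshold
increments.

Genotypes come from binomial likelihoods of the variant-read count among
variant+reference reads, with allele-sampling probabilities eps (hom-ref,
sequencing/assignment error), 0.5 (het) and 1-eps (hom-alt), a uniform
prior, and a Phred-scaled posterior quality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._util import round_half_up
from .depth import DepthTrack
from .signatures import Signature, sig_sort_key

__all__ = [
    "ClusterParams",
    "SVCall",
    "SignatureStore",
    "partition",
    "resolve_cluster",
    "min_support",
    "genotype",
    "call_variants",
]

DEFAULT_MAX_BIAS = {"DEL": 200, "INS": 100, "INV": 500, "DUP": 500, "BND": 50}


@dataclass(frozen=True)
class ClusterParams:
    max_bias: dict = field(default_factory=lambda: dict(DEFAULT_MAX_BIAS))
    support_ratio: float = 0.1  # fraction of mean depth required as support
    min_support_floor: int = 2
    min_support_cap: int = 10
    genotype_error: float = 0.1  # eps: alt-read probability under hom-ref

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.max_bias.values()):
            raise ValueError("max_bias values must be positive")
        if not (0 < self.genotype_error < 0.5):
            raise ValueError("genotype_error must be in (0, 0.5)")

    def to_jsonable(self) -> dict:
        return {
            "max_bias": dict(self.max_bias),
            "support_ratio": self.support_ratio,
            "min_support_floor": self.min_support_floor,
            "min_support_cap": self.min_support_cap,
            "genotype_error": self.genotype_error,
        }


@dataclass(frozen=True)
class SVCall:
    contig: str
    pos: int  # 0-based
    svtype: str
    length: int
    end: int
    dv: int  # distinct supporting reads
    dr: int  # inferred reference-supporting reads
    gt: str
    qual: int
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None

    @property
    def af(self) -> float:
        return self.dv / (self.dv + self.dr) if self.dv + self.dr else 0.0


class SignatureStore:
    """Append-only accumulator of signatures keyed by (contig, svtype).

    Content equals the union of all processed batches' extractions;
    iteration is canonical (contig-table order, svtype lexicographic,
    then start/read), independent of arrival order.
    """

    def __init__(self, contig_order: Sequence[str]):
        self.contig_order = list(contig_order)
        self._by_key: dict[tuple[str, str], list[Signature]] = {}
        self.total = 0

    def add(self, sigs: Sequence[Signature]) -> None:
        for s in sigs:
            self._by_key.setdefault((s.contig, s.svtype), []).append(s)
        self.total += len(sigs)

    def items(self):
        order = {n: i for i, n in enumerate(self.contig_order)}
        for key in sorted(self._by_key, key=lambda k: (order[k[0]], k[1])):
            yield key, sorted(self._by_key[key], key=sig_sort_key)

    def all_signatures(self) -> list[Signature]:
        return [s for _, sigs in self.items() for s in sigs]

    def __eq__(self, other):
        return (
            isinstance(other, SignatureStore)
            and self.contig_order == other.contig_order
            and {k: sorted(v, key=sig_sort_key) for k, v in self._by_key.items()}
            == {k: sorted(v, key=sig_sort_key) for k, v in other._by_key.items()}
        )

    def to_jsonable(self) -> list:
        return [
            [s.svtype, s.contig, s.start, s.length, s.read_id, s.origin,
             s.mate_contig, s.mate_pos]
            for s in self.all_signatures()
        ]

    @classmethod
    def from_jsonable(cls, data: list, contig_order: Sequence[str]) -> "SignatureStore":
        store = cls(contig_order)
        store.add(
            [
                Signature(svtype=t, contig=c, start=int(st), length=int(ln),
                          read_id=r, origin=o, mate_contig=mc,
                          mate_pos=None if mp is None else int(mp))
                for t, c, st, ln, r, o, mc, mp in data
            ]
        )
        return store


def partition(sigs: Sequence[Signature], max_bias: int) -> list[list[Signature]]:
    """Greedy linear scan over start-sorted signatures: a gap between
    consecutive starts larger than max_bias opens a new cluster (gaps chain,
    so a cluster may span more than max_bias end to end)."""
    clusters: list[list[Signature]] = []
    for s in sigs:
        if clusters and s.start - clusters[-1][-1].start <= max_bias:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return clusters


def _lower_median(values: Sequence[int]) -> int:
    v = sorted(values)
    return v[(len(v) - 1) // 2]


@dataclass(frozen=True)
class Candidate:
    pos: int
    length: int
    dv: int
    read_ids: frozenset
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None


def resolve_cluster(cluster: Sequence[Signature]) -> Candidate:
    """Summarise one cluster: lower-median position and length; support is
    the number of distinct reads (a chimeric read contributing several
    signatures counts once). Breakend mates take the majority mate contig
    and the median mate position within it."""
    if not cluster:
        raise ValueError("empty cluster")
    pos = _lower_median([s.start for s in cluster])
    length = _lower_median([s.length for s in cluster])
    reads = frozenset(s.read_id for s in cluster)
    mate_contig = mate_pos = None
    if cluster[0].svtype == "BND":
        counts: dict[str, int] = {}
        for s in cluster:
            counts[s.mate_contig] = counts.get(s.mate_contig, 0) + 1
        mate_contig = max(sorted(counts), key=counts.get)
        mate_pos = _lower_median(
            [s.mate_pos for s in cluster if s.mate_contig == mate_contig]
        )
    return Candidate(pos, length, len(reads), reads, mate_contig, mate_pos)


def min_support(mean_depth: float, params: ClusterParams = ClusterParams()) -> int:
    """Depth-adaptive support threshold: round(ratio * depth) clamped to
    [floor, cap]. Piecewise-constant in depth — the threshold steps up as
    the run accumulates coverage."""
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    return max(
        params.min_support_floor,
        min(params.min_support_cap, round_half_up(params.support_ratio * mean_depth)),
    )


def genotype(dv: int, dr: int, eps: float = 0.1) -> tuple[str, int]:
    """Genotype from supporting-read counts via binomial likelihoods.

    Alt reads ~ Binomial(dv+dr, p) with p = eps, 0.5, 1-eps for 0/0, 0/1,
    1/1; uniform prior; ties break toward the lower-alt genotype. Quality is
    the Phred-scaled posterior error, capped at 100.
    """
    n = dv + dr
    if n == 0:
        return "./.", 0
    loglik = [
        dv * math.log(eps) + dr * math.log(1 - eps),
        n * math.log(0.5),
        dv * math.log(1 - eps) + dr * math.log(eps),
    ]
    m = max(loglik)
    weights = [math.exp(l - m) for l in loglik]
    total = sum(weights)
    best = 0
    for i in (1, 2):
        if weights[i] > weights[best]:
            best = i
    post = weights[best] / total
    err = max(1.0 - post, 1e-10)
    qual = min(100, round_half_up(-10.0 * math.log10(err)))
    return ("0/0", "0/1", "1/1")[best], qual


def call_variants(
    store: SignatureStore,
    depth: DepthTrack,
    params: ClusterParams = ClusterParams(),
) -> list[SVCall]:
    """Cluster the whole store and emit genotyped calls.

    Pure in (store, depth, params): per (contig, svtype) group, partition ->
    resolve -> keep candidates with dv >= the depth-adaptive threshold; DR is
    inferred from the local binned depth (total reads at the locus minus
    supporters, floored at 0); output sorted by (contig order, pos, svtype).
    """
    ms = min_support(depth.mean_depth, params)
    order = {n: i for i, n in enumerate(store.contig_order)}
    calls: list[SVCall] = []
    for (contig, svtype), sigs in store.items():
        bias = params.max_bias[svtype]
        for cluster in partition(sigs, bias):
            cand = resolve_cluster(cluster)
            if cand.dv < ms:
                continue
            local = depth.local_depth(contig, cand.pos)
            dr = max(0, round_half_up(local) - cand.dv)
            gt, qual = genotype(cand.dv, dr, params.genotype_error)
            end = cand.pos + cand.length if svtype in ("DEL", "INV", "DUP") else cand.pos
            calls.append(
                SVCall(
                    contig=contig, pos=cand.pos, svtype=svtype, length=cand.length,
                    end=end, dv=cand.dv, dr=dr, gt=gt, qual=qual,
                    mate_contig=cand.mate_contig, mate_pos=cand.mate_pos,
                )
            )
    calls.sort(key=lambda c: (order[c.contig], c.pos, c.svtype))
    return calls
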