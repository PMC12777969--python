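"""Detection-rate feedback against a frequency-filtered truth set.

The feedback statistic is truth-side coverage: the fraction of a
population/truth SV set (restricted to common variants, allele frequency
above a cutoff) that the current callset recovers. It rises quickly at low
sequencing depth and plateaus, which makes it a usable signal for deciding
when enough data has been produced and sequencing can be stopped early.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "TruthRecord",
    "MatchCriteria",
    "FeedbackReport",
    "filter_truth",
    "match",
    "detection_rate",
    "should_stop",
    "benchmark",
]

_LENGTH_BEARING = {"DEL", "INS", "INV", "DUP"}


@dataclass(frozen=True)
class TruthRecord:
    """One truth-set SV with (optional) population allele frequency."""

    contig: str
    pos: int  # 0-based
    svtype: str
    length: int
    af: Optional[float] = None


@dataclass(frozen=True)
class MatchCriteria:
    """Breakpoint-distance / size-ratio matching rule.

    A call matches a truth record when the types agree (if ``type_strict``),
    breakpoints are within ``max_dist`` bp, and for length-bearing types the
    smaller/larger size ratio is at least ``min_size_ratio``. Breakends are
    matched on contig and position only.
    """

    max_dist: int = 1000
    min_size_ratio: float = 0.7
    type_strict: bool = True

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if not (0 < self.min_size_ratio <= 1):
            raise ValueError("min_size_ratio must be in (0, 1]")


@dataclass
class FeedbackReport:
    """Per-cycle feedback: detection rate and the early-stop recommendation."""

    cycle_index: int
    mean_depth: float
    n_truth: int
    n_matched: int
    detection_rate: float
    stop_recommended: bool
    min_support: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "cycle_index": self.cycle_index,
            "mean_depth": round(self.mean_depth, 4),
            "n_truth": self.n_truth,
            "n_matched": self.n_matched,
            "detection_rate": round(self.detection_rate, 6),
            "stop_recommended": self.stop_recommended,
        }
        if self.min_support is not None:
            d["min_support"] = self.min_support
        d.update(self.extra)
        return json.dumps(d, sort_keys=True)


def filter_truth(records: Sequence[TruthRecord], af_min: float = 0.1) -> list[TruthRecord]:
    """Keep truth records whose allele frequency is known and strictly > af_min.

    Records with missing AF fail the filter: an SV of unknown population
    frequency cannot be certified as common.
    """
    return [r for r in records if r.af is not None and r.af > af_min]


def match(call, truth: TruthRecord, c: MatchCriteria = MatchCriteria()) -> bool:
    """Does one call match one truth record under the criteria?"""
    if call.contig != truth.contig:
        return False
    if c.type_strict and call.svtype != truth.svtype:
        return False
    if abs(call.pos - truth.pos) > c.max_dist:
        return False
    if call.svtype in _LENGTH_BEARING and truth.svtype in _LENGTH_BEARING:
        lo, hi = sorted((abs(call.length), abs(truth.length)))
        if hi == 0:
            return lo == 0
        if lo / hi < c.min_size_ratio:
            return False
    return True


def detection_rate(
    calls: Sequence, truth: Sequence[TruthRecord], c: MatchCriteria = MatchCriteria()
) -> tuple[int, float]:
    """Truth-side coverage: (n_matched, n_matched / n_truth).

    Each truth record counts at most once however many calls hit it; one call
    may cover several truth records. Raises on an empty truth set (the
    statistic is undefined).
    """
    if not truth:
        raise ValueError("detection rate undefined for an empty truth set")
    n_matched = sum(1 for t in truth if any(match(call, t, c) for call in calls))
    return n_matched, n_matched / len(truth)


def should_stop(rate_history: Sequence[float], threshold: float, patience: int) -> bool:
    """Recommend stopping iff the last `patience` rates all reached `threshold`."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if len(rate_history) < patience:
        return False
    return all(r >= threshold for r in rate_history[-patience:])


def benchmark(
    calls: Sequence, truth: Sequence[TruthRecord], c: MatchCriteria = MatchCriteria()
) -> dict:
    """Offline precision/recall/F1 of a callset against a same-sample truth set."""
    n_truth_matched = sum(1 for t in truth if any(match(call, t, c) for call in calls))
    n_call_matched = sum(1 for call in calls if any(match(call, t, c) for t in truth))
    recall = n_truth_matched / len(truth) if truth else 0.0
    precision = n_call_matched / len(calls) if calls else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "n_calls": len(calls),
        "n_truth": len(truth),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
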