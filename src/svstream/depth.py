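"""Binned per-contig depth accumulation.

Aligned (reference-consuming) bases are summed into fixed-width bins as
batches arrive; mean depth over the whole genome drives the adaptive
support threshold and the per-bin sums give a local depth estimate for
reference-read (DR) inference without random access to spent batches.
"""
from __future__ import annotations

import numpy as np

from .io_formats import ContigTable

__all__ = ["DepthTrack"]


class DepthTrack:
    def __init__(self, contigs: ContigTable, bin_size: int = 1000):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = bin_size
        self.contigs = contigs
        self.genome_length = contigs.total_length
        self._bins = {
            name: np.zeros(-(-length // bin_size), dtype=np.int64)
            for name, length in contigs
        }

    def add_interval(self, contig: str, start: int, end: int) -> None:
        """Credit the aligned bases of [start, end) to the bins it overlaps."""
        if end <= start:
            return
        bs = self.bin_size
        bins = self._bins[contig]
        b0, b1 = start // bs, (end - 1) // bs
        if b0 == b1:
            bins[b0] += end - start
            return
        for b in range(b0, b1 + 1):
            lo = max(start, b * bs)
            hi = min(end, (b + 1) * bs)
            bins[b] += hi - lo

    @property
    def total_bases(self) -> int:
        return int(sum(int(b.sum()) for b in self._bins.values()))

    @property
    def mean_depth(self) -> float:
        return self.total_bases / self.genome_length

    def local_depth(self, contig: str, pos: int) -> float:
        return float(self._bins[contig][pos // self.bin_size]) / self.bin_size

    def __eq__(self, other):
        return (
            isinstance(other, DepthTrack)
            and self.bin_size == other.bin_size
            and self.contigs == other.contigs
            and all(np.array_equal(self._bins[n], other._bins[n]) for n in self._bins)
        )

    def to_jsonable(self) -> dict:
        return {
            "bin_size": self.bin_size,
            "bins": {n: [int(x) for x in b] for n, b in self._bins.items()},
        }

    @classmethod
    def from_jsonable(cls, data: dict, contigs: ContigTable) -> "DepthTrack":
        track = cls(contigs, bin_size=int(data["bin_size"]))
        for name, counts in data["bins"].items():
            arr = np.asarray(counts, dtype=np.int64)
            if arr.shape != track._bins[name].shape:
                raise ValueError(f"depth bins for {name} do not match contig table")
            track._bins[name] = arr
        return track
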