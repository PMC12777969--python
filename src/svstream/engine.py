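"""The real-time orchestration loop.

A directory of batch alignment files stands in for a sequencer's output
stream. The engine polls the directory, treats a file as ready only when its
size and modification time are unchanged across two polls (the stability
window), processes ready batches sequentially — appending their signatures
to the store and their aligned bases to the depth track — and, whenever new
batches have landed, runs a clustering cycle that writes an interim VCF and
(if a truth set is configured) a detection-rate feedback report.

State is checkpointed after every batch and every cycle by atomic replace,
so a crash at any point loses at most the batch in flight; ``recover``
reloads the last good checkpoint, verifies the processed ledger's content
checksums against the files on disk, deletes any partial interim output and
re-queues whatever the ledger has not seen. Because clustering is a pure
function of the accumulated state, the resumed run's final callset is
byte-identical to an uninterrupted run's — and to an offline single pass.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from ._util import content_checksum
from .cluster import ClusterParams, SignatureStore, call_variants, min_support
from .depth import DepthTrack
from .feedback import (
    FeedbackReport,
    MatchCriteria,
    TruthRecord,
    detection_rate,
    filter_truth,
    should_stop,
)
from .io_formats import (
    BatchReadError,
    ContigTable,
    VcfStyle,
    read_alignment_batch,
    read_truth_vcf,
    write_vcf,
)
from .signatures import ExtractionParams, extract_batch_signatures

log = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "svstream-checkpoint"
CHECKPOINT_VERSION = 1

__all__ = [
    "BatchEvent",
    "EngineState",
    "FeedbackConfig",
    "CorruptCheckpointError",
    "ChecksumMismatchError",
    "detect_stable_files",
    "process_batch",
    "save_checkpoint",
    "load_checkpoint",
    "recover",
    "StreamEngine",
    "call_offline",
]


class CorruptCheckpointError(RuntimeError):
    """Checkpoint file is unreadable, truncated, or of an unknown version."""


class ChecksumMismatchError(RuntimeError):
    """A ledger entry's checksum no longer matches the file on disk."""


@dataclass(frozen=True)
class BatchEvent:
    path: Path
    size_bytes: int
    first_seen: float
    stable_since: Optional[float] = None


@dataclass(frozen=True)
class LedgerEntry:
    name: str  # basename within the watch dir
    checksum: str
    n_signatures: int


@dataclass
class EngineState:
    """Complete resumable state: exactly the accumulation over the ledger."""

    contigs: ContigTable
    processed: list[LedgerEntry]
    store: SignatureStore
    depth: DepthTrack
    cycle_index: int
    extraction: ExtractionParams
    clustering: ClusterParams
    rate_history: list[float] = field(default_factory=list)

    @classmethod
    def fresh(
        cls,
        contigs: ContigTable,
        extraction: ExtractionParams = ExtractionParams(),
        clustering: ClusterParams = ClusterParams(),
        bin_size: int = 1000,
    ) -> "EngineState":
        return cls(
            contigs=contigs,
            processed=[],
            store=SignatureStore(contigs.names),
            depth=DepthTrack(contigs, bin_size=bin_size),
            cycle_index=0,
            extraction=extraction,
            clustering=clustering,
        )

    def processed_names(self) -> set[str]:
        return {e.name for e in self.processed}

    def __eq__(self, other):
        return (
            isinstance(other, EngineState)
            and self.contigs == other.contigs
            and self.processed == other.processed
            and self.store == other.store
            and self.depth == other.depth
            and self.cycle_index == other.cycle_index
            and self.extraction == other.extraction
            and self.clustering == other.clustering
            and self.rate_history == other.rate_history
        )


@dataclass(frozen=True)
class FeedbackConfig:
    truth: tuple[TruthRecord, ...]
    af_min: float = 0.1
    criteria: MatchCriteria = MatchCriteria()
    stop_threshold: float = 0.9
    patience: int = 2

    @classmethod
    def from_vcf(cls, path, **kwargs) -> "FeedbackConfig":
        return cls(truth=tuple(read_truth_vcf(path)), **kwargs)

    def filtered_truth(self) -> list[TruthRecord]:
        return filter_truth(self.truth, self.af_min)


# ---------------------------------------------------------------------------
# File watching

_IGNORED_SUFFIXES = (".tmp", ".part", ".lock", ".json")


def detect_stable_files(
    watch_dir,
    known: set[str],
    stability_window: float = 5.0,
    _sleep: Callable[[float], None] = time.sleep,
) -> list[BatchEvent]:
    """Two-poll readiness: a file is ready iff its size and mtime are
    unchanged across two polls separated by the stability window and its
    name is not already known (processed, queued or quarantined).

    Readiness is defined solely by this rule; `_sleep` is injectable so the
    window can be exercised deterministically.
    """

    def snapshot() -> dict[str, tuple[int, float]]:
        snap = {}
        for entry in os.scandir(watch_dir):
            name = entry.name
            if name.startswith(".") or name.endswith(_IGNORED_SUFFIXES):
                continue
            if not entry.is_file():
                continue
            try:
                st = entry.stat()
            except FileNotFoundError:  # vanished between scandir and stat
                log.info("file %s vanished during poll", name)
                continue
            snap[name] = (st.st_size, st.st_mtime)
        return snap

    first = snapshot()
    _sleep(stability_window)
    second = snapshot()
    now = time.time()
    ready = [
        BatchEvent(Path(watch_dir) / name, second[name][0], now, stable_since=now)
        for name in second
        if name not in known and first.get(name) == second[name]
    ]
    ready.sort(key=lambda e: (os.path.getmtime(e.path), e.path.name))
    return ready


# ---------------------------------------------------------------------------
# Batch processing and checkpointing


def process_batch(path, state: EngineState) -> EngineState:
    """Fold one batch into the state (in place): extract signatures, credit
    aligned bases to the depth track, append to the ledger. Raises
    BatchReadError without touching the state if the file cannot be read."""
    name = os.path.basename(path)
    if name in state.processed_names():
        raise ValueError(f"batch {name} already processed")
    checksum = content_checksum(path)
    t0 = time.monotonic()
    records = read_alignment_batch(path, state.extraction.min_mapq, state.contigs)
    sigs = extract_batch_signatures(records, state.extraction)
    state.store.add(sigs)
    for rec in records:
        state.depth.add_interval(rec.contig, rec.ref_start, rec.ref_end)
    state.processed.append(LedgerEntry(name, checksum, len(sigs)))
    log.info(
        "batch=%s records=%d signatures=%d depth=%.2f elapsed=%.3fs",
        name, len(records), len(sigs), state.depth.mean_depth,
        time.monotonic() - t0,
    )
    return state


def save_checkpoint(state: EngineState, path) -> None:
    """Serialize the complete state as versioned JSON; write-temp-then-rename
    so a kill mid-save leaves the previous complete checkpoint in place."""
    payload = {
        "format": CHECKPOINT_FORMAT,
        "version": CHECKPOINT_VERSION,
        "contigs": [[n, l] for n, l in state.contigs],
        "cycle_index": state.cycle_index,
        "processed": [
            {"name": e.name, "checksum": e.checksum, "n_signatures": e.n_signatures}
            for e in state.processed
        ],
        "signatures": state.store.to_jsonable(),
        "depth": state.depth.to_jsonable(),
        "extraction": {
            "min_size": state.extraction.min_size,
            "merge_dist": state.extraction.merge_dist,
            "min_mapq": state.extraction.min_mapq,
            "min_segment_len": state.extraction.min_segment_len,
        },
        "clustering": state.clustering.to_jsonable(),
        "rate_history": state.rate_history,
    }
    path = os.fspath(path)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh)
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp, path)


def load_checkpoint(path) -> EngineState:
    try:
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise CorruptCheckpointError(f"{path} is not a checkpoint file")
        if payload.get("version") != CHECKPOINT_VERSION:
            raise CorruptCheckpointError(
                f"unknown checkpoint version {payload.get('version')!r}"
            )
        contigs = ContigTable(payload["contigs"])
        state = EngineState(
            contigs=contigs,
            processed=[
                LedgerEntry(e["name"], e["checksum"], e["n_signatures"])
                for e in payload["processed"]
            ],
            store=SignatureStore.from_jsonable(payload["signatures"], contigs.names),
            depth=DepthTrack.from_jsonable(payload["depth"], contigs),
            cycle_index=int(payload["cycle_index"]),
            extraction=ExtractionParams(**payload["extraction"]),
            clustering=ClusterParams(**payload["clustering"]),
            rate_history=[float(r) for r in payload["rate_history"]],
        )
    except CorruptCheckpointError:
        raise
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise CorruptCheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
    # internal consistency: store must equal the ledger's accounting
    if state.store.total != sum(e.n_signatures for e in state.processed):
        raise CorruptCheckpointError(
            f"checkpoint {path}: store/ledger signature counts disagree"
        )
    return state


# ---------------------------------------------------------------------------
# Cycles


def cycle_vcf_name(cycle_index: int) -> str:
    return f"cycle_{cycle_index:04d}.vcf"


def run_cycle(
    state: EngineState,
    out_dir,
    feedback: Optional[FeedbackConfig] = None,
    style: VcfStyle = VcfStyle(),
    checkpoint_path=None,
) -> tuple[Path, Optional[FeedbackReport]]:
    """One clustering cycle: call variants over the whole store, write the
    interim VCF for this cycle, evaluate feedback, advance the cycle counter
    and checkpoint."""
    out_dir = Path(out_dir)
    calls = call_variants(state.store, state.depth, state.clustering)
    vcf_path = out_dir / cycle_vcf_name(state.cycle_index)
    write_vcf(calls, state.contigs, vcf_path, style)
    report = None
    ms = min_support(state.depth.mean_depth, state.clustering)
    if feedback is not None:
        truth = feedback.filtered_truth()
        n_matched, rate = detection_rate(calls, truth, feedback.criteria)
        state.rate_history.append(rate)
        report = FeedbackReport(
            cycle_index=state.cycle_index,
            mean_depth=state.depth.mean_depth,
            n_truth=len(truth),
            n_matched=n_matched,
            detection_rate=rate,
            stop_recommended=should_stop(
                state.rate_history, feedback.stop_threshold, feedback.patience
            ),
            min_support=ms,
            extra={"n_calls": len(calls)},
        )
        log.info("feedback %s", report.to_json())
    else:
        report = FeedbackReport(
            cycle_index=state.cycle_index,
            mean_depth=state.depth.mean_depth,
            n_truth=0,
            n_matched=0,
            detection_rate=0.0,
            stop_recommended=False,
            min_support=ms,
            extra={"truth_absent": True, "n_calls": len(calls)},
        )
    state.cycle_index += 1
    if checkpoint_path is not None:
        save_checkpoint(state, checkpoint_path)
    return vcf_path, report


# ---------------------------------------------------------------------------
# Recovery


def recover(
    watch_dir,
    out_dir,
    contigs: ContigTable,
    extraction: ExtractionParams = ExtractionParams(),
    clustering: ClusterParams = ClusterParams(),
    stability_window: float = 0.05,
    _sleep: Callable[[float], None] = time.sleep,
) -> tuple[EngineState, list[Path]]:
    """Restore after a fault (or start fresh if no checkpoint exists).

    Verifies every ledger entry's checksum against the file on disk (a
    mismatch means the input mutated mid-run: hard error), deletes partial
    interim output for cycles the checkpoint has not sealed, and queues
    every stabilized file the ledger has not seen.
    """
    out_dir = Path(out_dir)
    ckpt = out_dir / "checkpoint.json"
    state: Optional[EngineState] = None
    if ckpt.exists():
        try:
            state = load_checkpoint(ckpt)
        except CorruptCheckpointError as exc:
            log.warning("checkpoint unusable (%s); rebuilding from scratch", exc)
            state = None
    if state is None:
        state = EngineState.fresh(contigs, extraction, clustering)
    elif state.contigs != contigs:
        raise ValueError("checkpoint contig table does not match the run's")

    for entry in state.processed:
        path = Path(watch_dir) / entry.name
        if not path.exists() or content_checksum(path) != entry.checksum:
            raise ChecksumMismatchError(
                f"processed batch {entry.name} changed on disk since it was ingested"
            )

    # drop partial interim output: stray temp files and any cycle VCF the
    # checkpoint does not yet account for (it will be regenerated)
    for stray in out_dir.glob("*.tmp"):
        stray.unlink()
    for vcf in out_dir.glob("cycle_*.vcf"):
        try:
            idx = int(vcf.stem.split("_")[1])
        except (IndexError, ValueError):
            continue
        if idx >= state.cycle_index:
            vcf.unlink()

    events = detect_stable_files(
        watch_dir, state.processed_names(), stability_window, _sleep=_sleep
    )
    return state, [e.path for e in events]


# ---------------------------------------------------------------------------
# Engine


class StreamEngine:
    """Single-writer engine owning one watch directory and one output
    directory (lock file). Drive it with :meth:`run` or step it manually
    with :meth:`poll_once` / :meth:`run_cycle`."""

    MAX_RETRIES = 3

    def __init__(
        self,
        watch_dir,
        out_dir,
        contigs: ContigTable,
        extraction: ExtractionParams = ExtractionParams(),
        clustering: ClusterParams = ClusterParams(),
        feedback: Optional[FeedbackConfig] = None,
        stability_window: float = 0.05,
        poll_interval: float = 0.05,
        style: VcfStyle = VcfStyle(),
        _resume_state: Optional[EngineState] = None,
        _initial_queue: Optional[list[Path]] = None,
    ):
        self.watch_dir = Path(watch_dir)
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.feedback = feedback
        self.stability_window = stability_window
        self.poll_interval = poll_interval
        self.style = style
        self.checkpoint_path = self.out_dir / "checkpoint.json"
        self._lock_path = self.out_dir / "engine.lock"
        self.queue: list[Path] = list(_initial_queue or [])
        self.retries: dict[str, int] = {}
        self.quarantined: set[str] = set()
        self.reports: list[FeedbackReport] = []
        self.stop_recommended = False
        if _resume_state is not None:
            self.state = _resume_state
            self._lock_path.write_text(str(os.getpid()))
        else:
            if self._lock_path.exists():
                raise RuntimeError(
                    f"{self._lock_path} exists: another engine owns this output "
                    "directory (use resume after a crash)"
                )
            self._lock_path.write_text(str(os.getpid()))
            self.state = EngineState.fresh(contigs, extraction, clustering)
            save_checkpoint(self.state, self.checkpoint_path)

    @classmethod
    def resume(
        cls,
        watch_dir,
        out_dir,
        contigs: ContigTable,
        extraction: ExtractionParams = ExtractionParams(),
        clustering: ClusterParams = ClusterParams(),
        feedback: Optional[FeedbackConfig] = None,
        stability_window: float = 0.05,
        poll_interval: float = 0.05,
        style: VcfStyle = VcfStyle(),
    ) -> "StreamEngine":
        state, queue = recover(
            watch_dir, out_dir, contigs, extraction, clustering, stability_window
        )
        return cls(
            watch_dir, out_dir, contigs, extraction, clustering, feedback,
            stability_window, poll_interval, style,
            _resume_state=state, _initial_queue=queue,
        )

    # -- stepping ----------------------------------------------------------

    def _known(self) -> set[str]:
        return (
            self.state.processed_names()
            | self.quarantined
            | {p.name for p in self.queue}
        )

    def poll_once(self) -> int:
        """One poll of the watch directory; returns how many files queued."""
        events = detect_stable_files(
            self.watch_dir, self._known(), self.stability_window
        )
        self.queue.extend(e.path for e in events)
        return len(events)

    def process_queue(self) -> int:
        """Process every queued batch (checkpoint after each); returns how
        many were ingested. Unreadable batches are re-queued up to
        MAX_RETRIES, then quarantined."""
        n = 0
        pending, self.queue = self.queue, []
        for path in pending:
            try:
                process_batch(path, self.state)
            except BatchReadError as exc:
                attempts = self.retries.get(path.name, 0) + 1
                self.retries[path.name] = attempts
                if attempts >= self.MAX_RETRIES:
                    self.quarantined.add(path.name)
                    log.error("quarantined %s after %d attempts: %s",
                              path.name, attempts, exc)
                else:
                    self.queue.append(path)
                    log.warning("re-queued %s (attempt %d): %s", path.name, attempts, exc)
                continue
            save_checkpoint(self.state, self.checkpoint_path)
            n += 1
        return n

    def run_cycle(self) -> FeedbackReport:
        vcf_path, report = run_cycle(
            self.state, self.out_dir, self.feedback, self.style, self.checkpoint_path
        )
        self.reports.append(report)
        if report.stop_recommended:
            self.stop_recommended = True
        return report

    # -- main loop ---------------------------------------------------------

    def run(
        self,
        expected_batches: Optional[int] = None,
        max_polls: Optional[int] = None,
    ) -> Path:
        """Poll/process/cycle until `expected_batches` are ingested (or
        `max_polls` idle polls elapse), then write the final callset."""
        polls = 0
        while True:
            queued = self.poll_once()
            processed = self.process_queue() if (queued or self.queue) else 0
            if processed:
                self.run_cycle()
            n_done = len(self.state.processed)
            if expected_batches is not None and n_done >= expected_batches:
                break
            if queued == 0 and processed == 0:
                polls += 1
                if max_polls is not None and polls >= max_polls:
                    break
                time.sleep(self.poll_interval)
            else:
                polls = 0
        return self.write_final()

    def write_final(self) -> Path:
        calls = call_variants(self.state.store, self.state.depth, self.state.clustering)
        path = self.out_dir / "variants.vcf"
        write_vcf(calls, self.state.contigs, path, self.style)
        return path

    def close(self) -> None:
        if self._lock_path.exists():
            self._lock_path.unlink()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def call_offline(
    batch_paths: Sequence,
    contigs: ContigTable,
    out_path,
    extraction: ExtractionParams = ExtractionParams(),
    clustering: ClusterParams = ClusterParams(),
    style: VcfStyle = VcfStyle(),
) -> Path:
    """Offline single pass: ingest all batches, cluster once, write one VCF.

    The reference the streaming run is held to — for the same batch set the
    output is byte-identical to the engine's final callset.
    """
    state = EngineState.fresh(contigs, extraction, clustering)
    for path in batch_paths:
        process_batch(path, state)
    calls = call_variants(state.store, state.depth, state.clustering)
    write_vcf(calls, contigs, out_path, style)
    return Path(out_path)
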