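"""Stream engine: stabilization, depth accounting, checkpoint/recovery."""
from pathlib import Path

import pytest

from svstream.depth import DepthTrack
from svstream.engine import (
    ChecksumMismatchError,
    CorruptCheckpointError,
    EngineState,
    StreamEngine,
    cycle_vcf_name,
    detect_stable_files,
    load_checkpoint,
    process_batch,
    recover,
    save_checkpoint,
)
from svstream.io_formats import ContigTable

from conftest import TEST_CONTIGS, sam_line, write_sam


def make_batch(dir_path: Path, name="b1.sam", pos=1001, n=3):
    lines = [sam_line(f"{name}.r{i}", 0, "chr1", pos + 200 * i, 60, "100M50D100M")
             for i in range(n)]
    return write_sam(dir_path / name, lines)


class TestDepthTrack:
    def test_mean_depth_is_bases_over_genome(self):
        contigs = ContigTable([("chr1", 1_000_000)])
        track = DepthTrack(contigs, bin_size=1000)
        for i in range(10):
            track.add_interval("chr1", i * 2000, i * 2000 + 1000)
        assert track.mean_depth == pytest.approx(0.01)

    def test_local_depth_binned(self):
        track = DepthTrack(ContigTable([("chr1", 10_000)]), bin_size=1000)
        track.add_interval("chr1", 500, 2500)  # bins 0,1,2 get 500,1000,500
        assert track.local_depth("chr1", 0) == 0.5
        assert track.local_depth("chr1", 1999) == 1.0
        assert track.local_depth("chr1", 3500) == 0.0

    def test_roundtrip(self):
        contigs = ContigTable([("chr1", 10_000)])
        track = DepthTrack(contigs, bin_size=1000)
        track.add_interval("chr1", 100, 900)
        assert DepthTrack.from_jsonable(track.to_jsonable(), contigs) == track


class TestDetectStableFiles:
    def test_file_growing_during_window_not_ready(self, tmp_path):
        f = tmp_path / "b1.sam"
        f.write_text("x")

        def grow(_seconds):
            f.write_text("xx")

        assert detect_stable_files(tmp_path, set(), 0.01, _sleep=grow) == []

    def test_stable_file_ready(self, tmp_path):
        (tmp_path / "b1.sam").write_text("x")
        events = detect_stable_files(tmp_path, set(), 0.0)
        assert [e.path.name for e in events] == ["b1.sam"]

    def test_known_names_ignored(self, tmp_path):
        (tmp_path / "b1.sam").write_text("x")
        assert detect_stable_files(tmp_path, {"b1.sam"}, 0.0) == []

    def test_temp_files_ignored(self, tmp_path):
        (tmp_path / "b1.sam.tmp").write_text("x")
        (tmp_path / ".hidden").write_text("x")
        assert detect_stable_files(tmp_path, set(), 0.0) == []


class TestProcessBatch:
    def test_accumulates_signatures_and_depth(self, tmp_path):
        state = EngineState.fresh(TEST_CONTIGS)
        process_batch(make_batch(tmp_path), state)
        assert state.store.total == 3
        assert len(state.processed) == 1
        # 3 reads x 250 reference bases (100M 50D 100M)
        assert state.depth.total_bases == 3 * 250

    def test_duplicate_batch_rejected(self, tmp_path):
        state = EngineState.fresh(TEST_CONTIGS)
        batch = make_batch(tmp_path)
        process_batch(batch, state)
        with pytest.raises(ValueError):
            process_batch(batch, state)


class TestCheckpoint:
    def _state(self, tmp_path):
        state = EngineState.fresh(TEST_CONTIGS)
        process_batch(make_batch(tmp_path), state)
        state.cycle_index = 3
        state.rate_history = [0.5, 0.75]
        return state

    def test_roundtrip_field_by_field(self, tmp_path):
        state = self._state(tmp_path)
        ckpt = tmp_path / "checkpoint.json"
        save_checkpoint(state, ckpt)
        assert load_checkpoint(ckpt) == state

    def test_truncated_checkpoint_is_distinguishable(self, tmp_path):
        state = self._state(tmp_path)
        ckpt = tmp_path / "checkpoint.json"
        save_checkpoint(state, ckpt)
        ckpt.write_text(ckpt.read_text()[: ckpt.stat().st_size // 2])
        with pytest.raises(CorruptCheckpointError):
            load_checkpoint(ckpt)

    def test_unknown_version_refused(self, tmp_path):
        ckpt = tmp_path / "checkpoint.json"
        ckpt.write_text('{"format": "svstream-checkpoint", "version": 99}')
        with pytest.raises(CorruptCheckpointError):
            load_checkpoint(ckpt)

    def test_kill_between_temp_write_and_rename(self, tmp_path):
        """A stray temp file from an interrupted save must not shadow the
        older complete checkpoint."""
        state = self._state(tmp_path)
        ckpt = tmp_path / "checkpoint.json"
        save_checkpoint(state, ckpt)
        (tmp_path / "checkpoint.json.tmp").write_text('{"partial": ')
        assert load_checkpoint(ckpt) == state


class TestRecover:
    def test_ledger_and_stray_vcf_rules(self, tmp_path):
        watch = tmp_path / "watch"; watch.mkdir()
        out = tmp_path / "out"; out.mkdir()
        batches = [make_batch(watch, f"b{i}.sam", pos=1001 + 10_000 * i)
                   for i in range(4)]
        state = EngineState.fresh(TEST_CONTIGS)
        process_batch(batches[0], state)
        process_batch(batches[1], state)
        state.cycle_index = 2
        save_checkpoint(state, out / "checkpoint.json")
        (out / "cycle_0002.vcf").write_text("partial")  # unsealed cycle
        (out / "stale.vcf.tmp").write_text("partial")
        (out / cycle_vcf_name(1)).write_text("sealed")

        recovered, queue = recover(watch, out, TEST_CONTIGS, stability_window=0.0)
        assert recovered == state
        assert sorted(p.name for p in queue) == ["b2.sam", "b3.sam"]
        assert not (out / "cycle_0002.vcf").exists()
        assert not (out / "stale.vcf.tmp").exists()
        assert (out / cycle_vcf_name(1)).exists()  # sealed output untouched

    def test_no_checkpoint_queues_everything(self, tmp_path):
        watch = tmp_path / "watch"; watch.mkdir()
        out = tmp_path / "out"; out.mkdir()
        for i in range(4):
            make_batch(watch, f"b{i}.sam", pos=1001 + 10_000 * i)
        state, queue = recover(watch, out, TEST_CONTIGS, stability_window=0.0)
        assert state.processed == [] and len(queue) == 4

    def test_mutated_input_is_hard_error(self, tmp_path):
        watch = tmp_path / "watch"; watch.mkdir()
        out = tmp_path / "out"; out.mkdir()
        batch = make_batch(watch)
        state = EngineState.fresh(TEST_CONTIGS)
        process_batch(batch, state)
        save_checkpoint(state, out / "checkpoint.json")
        batch.write_text(batch.read_text() + "\n")
        with pytest.raises(ChecksumMismatchError):
            recover(watch, out, TEST_CONTIGS, stability_window=0.0)


class TestEngineLoop:
    def test_unreadable_batch_quarantined_after_retries(self, tmp_path):
        watch = tmp_path / "watch"; watch.mkdir()
        out = tmp_path / "out"
        bad = watch / "bad.sam"
        bad.write_text("definitely\tnot\ta sam file\n")
        with StreamEngine(watch, out, TEST_CONTIGS, stability_window=0.0,
                          poll_interval=0.0) as eng:
            for _ in range(StreamEngine.MAX_RETRIES + 1):
                eng.poll_once()
                eng.process_queue()
            assert "bad.sam" in eng.quarantined
            assert eng.state.processed == []  # state untouched

    def test_second_engine_refused_while_locked(self, tmp_path):
        watch = tmp_path / "watch"; watch.mkdir()
        out = tmp_path / "out"
        with StreamEngine(watch, out, TEST_CONTIGS):
            with pytest.raises(RuntimeError):
                StreamEngine(watch, out, TEST_CONTIGS)

    def test_interim_vcf_reproducible_without_new_batches(self, tmp_path):
        watch = tmp_path / "watch"; watch.mkdir()
        out = tmp_path / "out"
        make_batch(watch, n=5)
        with StreamEngine(watch, out, TEST_CONTIGS, stability_window=0.0,
                          poll_interval=0.0) as eng:
            eng.poll_once(); eng.process_queue()
            eng.run_cycle()
            first = (out / cycle_vcf_name(0)).read_bytes()
            eng.run_cycle()
            second = (out / cycle_vcf_name(1)).read_bytes()
        assert first == second
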