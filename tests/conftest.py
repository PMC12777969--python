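from pathlib import Path

import pytest

from svstream.engine import StreamEngine
from svstream.io_formats import ContigTable
from svstream.simulate import generate_scenario

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000000\n@SQ\tSN:chr2\tLN:1000000\n"
TEST_CONTIGS = ContigTable([("chr1", 1_000_000), ("chr2", 1_000_000)])


def write_sam(path: Path, body_lines, header: str = SAM_HEADER) -> Path:
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return path


def sam_line(qname, flag, rname, pos1, mapq, cigar, tags=()):
    fields = [qname, str(flag), rname, str(pos1), str(mapq), cigar,
              "*", "0", "0", "*", "*", *tags]
    return "\t".join(fields)


def drive_per_batch(engine: StreamEngine, batch_paths):
    """Feed batches one per cycle (emulates a one-file-per-interval drip)."""
    for p in batch_paths:
        engine.queue = [Path(p)]
        engine.process_queue()
        engine.run_cycle()
    return engine.write_final()


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """The default study fixture: 2 x 500 kb contigs, 40 implanted SVs,
    20x coverage, seed 42, ten equal batches."""
    return generate_scenario(tmp_path_factory.mktemp("scenario"), seed=42)
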