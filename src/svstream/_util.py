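"""Small shared helpers."""
from __future__ import annotations

import hashlib
import math
import os

_CHUNK = 64 * 1024


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def content_checksum(path: str | os.PathLike) -> str:
    """Cheap content fingerprint: sha256 over first + last 64 KiB + length.

    Detects truncation and in-place mutation of batch files without
    re-reading whole files on recovery.
    """
    size = os.path.getsize(path)
    h = hashlib.sha256()
    h.update(size.to_bytes(8, "little"))
    with open(path, "rb") as fh:
        h.update(fh.read(_CHUNK))
        if size > _CHUNK:
            fh.seek(max(_CHUNK, size - _CHUNK))
            h.update(fh.read(_CHUNK))
    return h.hexdigest()


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text to a temp file in the same directory, then rename into place."""
    path = os.fspath(path)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp, path)
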