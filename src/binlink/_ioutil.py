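"""Text I/O that treats ``.gz`` transparently.

Gzip writes pin mtime to 0 so identical content yields identical bytes —
re-runs with a fixed seed reproduce artifacts exactly.
"""

from __future__ import annotations

import gzip
import io
from contextlib import contextmanager
from pathlib import Path


@contextmanager
def open_text(path, mode: str):
    """Context manager for 'r'/'w' text streams; gzip when path ends .gz."""
    if mode not in ("r", "w"):
        raise ValueError(f"mode must be 'r' or 'w', got {mode!r}")
    gzipped = str(path).endswith(".gz")
    if mode == "r":
        fh = (gzip.open(path, "rt", encoding="utf-8", newline="")
              if gzipped else open(path, "r", encoding="utf-8", newline=""))
        try:
            yield fh
        finally:
            fh.close()
        return
    if gzipped:
        buf = io.StringIO()
        yield buf
        Path(path).write_bytes(
            gzip.compress(buf.getvalue().encode("utf-8"), mtime=0))
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            yield fh
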