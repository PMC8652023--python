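"""Shared helpers: build logging, deterministic serialization, digests."""

from __future__ import annotations

import gzip
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("cellbundle")


@dataclass
class BuildLog:
    """Collects warnings and drop counts during a build.

    Every cell/row dropped anywhere in the pipeline is recorded here so the
    numbers can be audited afterwards: counts per (stage, reason) must sum to
    (source size - canonical size) for each source.
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def warn(self, message: str) -> None:
        self.records.append(("warning", message))
        logger.warning(message)

    def info(self, message: str) -> None:
        self.records.append(("info", message))
        logger.info(message)

    def count(self, key: str, n: int = 1) -> None:
        if n:
            self.counts[key] = self.counts.get(key, 0) + n

    def warnings(self) -> list[str]:
        return [m for level, m in self.records if level == "warning"]


def sha256_text_list(items: list[str]) -> str:
    """Digest of an ordered identifier list (canonical cell order fingerprint)."""
    h = hashlib.sha256()
    for item in items:
        h.update(item.encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_json(obj, path: Path | str) -> None:
    """Write JSON deterministically: fixed separators, no timestamps, LF."""
    text = json.dumps(obj, indent=2, ensure_ascii=True)
    Path(path).write_text(text + "\n", encoding="utf-8", newline="\n")


def load_json(path: Path | str):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_gzip_text(path: Path | str, text: str) -> None:
    """Gzip with mtime pinned to 0 and no embedded filename, so identical
    content always yields identical bytes (build determinism)."""
    buf = io.BytesIO()
    with gzip.GzipFile(filename="", mode="wb", fileobj=buf, mtime=0) as gz:
        gz.write(text.encode("utf-8"))
    Path(path).write_bytes(buf.getvalue())


def open_maybe_gzip(path: Path | str, mode: str = "rt"):
    """Open plain or .gz text/binary transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    if "t" in mode:
        return open(path, mode, encoding="utf-8")
    return open(path, mode)


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance; gene lists are small enough for the O(len*len) DP."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def closest_ids(target: str, candidates, k: int = 3) -> list[str]:
    """The k candidate identifiers closest to target by edit distance."""
    scored = sorted(candidates, key=lambda c: (levenshtein(target, c), c))
    return scored[:k]
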