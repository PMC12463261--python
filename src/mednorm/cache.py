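"""Multi-tier persistent result cache.

One append-only JSON-lines file per processing stage (``preprocess``,
``match``, ``enrich``) under a cache directory.  Keys are the exact raw
input strings — never normalized first — so a change in preprocessing
rules cannot silently alias two different inputs; instead, every record
carries a pipeline-version tag and a record written under a different
version is treated as a miss.

Negative results (e.g. UNMATCHED) are cached like any other value, so a
name that failed once is never re-queried.  Appended records are only
durable after :meth:`CacheSet.flush`; a process killed mid-write leaves
at most one truncated final line, which the loader ignores, giving
resume-after-interruption semantics.
"""

from __future__ import annotations

import json
import os
import time
from pathlib import Path
from typing import Any

__all__ = ["CacheSet", "CacheError", "TIERS"]

TIERS = ("preprocess", "match", "enrich")


class CacheError(RuntimeError):
    """A corrupted cache store; the message names the tier."""


class CacheSet:
    """Key-value stores for each pipeline stage, persisted as JSONL."""

    def __init__(self, directory: str | Path, version: str = "1"):
        self.directory = Path(directory)
        self.version = version
        self.directory.mkdir(parents=True, exist_ok=True)
        self._data: dict[str, dict[str, Any]] = {t: {} for t in TIERS}
        self._pending: dict[str, list[tuple[str, Any]]] = {
            t: [] for t in TIERS
        }
        self.hits = 0
        self.misses = 0
        for tier in TIERS:
            self._load(tier)

    def _path(self, tier: str) -> Path:
        return self.directory / f"{tier}.jsonl"

    def _load(self, tier: str) -> None:
        path = self._path(tier)
        if not path.exists():
            return
        raw = path.read_text(encoding="utf-8")
        lines = raw.split("\n")
        # a trailing fragment without newline is an interrupted write
        complete, tail = lines[:-1], lines[-1]
        for line in complete:
            if not line:
                continue
            try:
                rec = json.loads(line)
                key, value, ver = rec["k"], rec["v"], rec["ver"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CacheError(
                    f"corrupted cache store for tier {tier!r}: {exc}"
                ) from exc
            if ver == self.version:
                self._data[tier][key] = value  # last write wins
        if tail.strip():
            try:
                rec = json.loads(tail)
                if rec.get("ver") == self.version:
                    self._data[tier][rec["k"]] = rec["v"]
            except (json.JSONDecodeError, KeyError, TypeError):
                pass  # truncated interrupted write: ignored

    def _check_tier(self, tier: str) -> None:
        if tier not in self._data:
            raise KeyError(f"unknown cache tier: {tier}")

    def get(self, tier: str, key: str) -> Any | None:
        """Exact-raw-string lookup; ``None`` on miss or version mismatch."""
        self._check_tier(tier)
        value = self._data[tier].get(key)
        if value is None:
            self.misses += 1
        else:
            self.hits += 1
        return value

    def put(self, tier: str, key: str, value: Any) -> None:
        """Record *key* -> *value*; durable only after :meth:`flush`."""
        self._check_tier(tier)
        self._data[tier][key] = value
        self._pending[tier].append((key, value))

    def flush(self) -> None:
        """Append pending records and fsync, so a new process sees them."""
        now = time.time()
        for tier, pending in self._pending.items():
            if not pending:
                continue
            with open(self._path(tier), "a", encoding="utf-8") as fh:
                for key, value in pending:
                    fh.write(
                        json.dumps(
                            {"k": key, "v": value, "ts": now,
                             "ver": self.version},
                            ensure_ascii=False,
                        )
                        + "\n"
                    )
                fh.flush()
                os.fsync(fh.fileno())
            self._pending[tier] = []

    def __len__(self) -> int:
        return sum(len(d) for d in self._data.values())


def cache_get(cache: CacheSet, tier: str, key: str) -> Any | None:
    return cache.get(tier, key)


def cache_put(cache: CacheSet, tier: str, key: str, value: Any) -> None:
    cache.put(tier, key, value)
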