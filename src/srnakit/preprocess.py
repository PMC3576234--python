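"""Adapter clipping and size-class selection for small-RNA read pools.

The 3' adapter is removed by exact substring matching: the longest read
suffix of length >= ``min_adapter_match`` that equals a prefix of the 3'
adapter is clipped off; a read with no such suffix is discarded outright.
A configured 5' adapter is clipped the same way (longest read prefix equal
to an adapter suffix) but its absence never discards. Reads are then kept
only if the clipped insert falls inside the pool's size window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import PipelineConfig
from .io import SequenceRecord

__all__ = ["SmallRNARead", "DiscardTally", "clip_adapters", "size_filter", "preprocess_pool"]


@dataclass(frozen=True)
class SmallRNARead:
    """A clipped read assigned to one small-RNA pool."""

    id: str
    seq: str
    pool: str
    clipped3: int = 0
    clipped5: int = 0


@dataclass
class DiscardTally:
    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    discarded_no_adapter: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.too_short + self.too_long + self.discarded_no_adapter

    def as_rows(self) -> list[dict]:
        return [
            {"category": "kept", "count": self.kept},
            {"category": "too_short", "count": self.too_short},
            {"category": "too_long", "count": self.too_long},
            {"category": "discarded_no_adapter", "count": self.discarded_no_adapter},
        ]


def _longest_suffix_matching_prefix(seq: str, adapter: str, min_len: int) -> int:
    """Length of the longest suffix of seq equal to a prefix of adapter (>= min_len), else 0."""
    limit = min(len(seq), len(adapter))
    for n in range(limit, min_len - 1, -1):
        if seq.endswith(adapter[:n]):
            return n
    return 0


def _longest_prefix_matching_suffix(seq: str, adapter: str, min_len: int) -> int:
    limit = min(len(seq), len(adapter))
    for n in range(limit, min_len - 1, -1):
        if seq.startswith(adapter[-n:]):
            return n
    return 0


def clip_adapters(read: SequenceRecord, cfg: PipelineConfig,
                  pool: str = "mirna") -> SmallRNARead | None:
    """Clip 3' (mandatory) and 5' (optional) adapters; None means DISCARD."""
    n3 = _longest_suffix_matching_prefix(read.seq, cfg.adapter3, cfg.min_adapter_match)
    if n3 == 0:
        return None
    seq = read.seq[: len(read.seq) - n3]
    n5 = 0
    if cfg.adapter5:
        n5 = _longest_prefix_matching_suffix(seq, cfg.adapter5, cfg.min_adapter_match)
        seq = seq[n5:]
    if not seq:
        return None
    return SmallRNARead(id=read.id, seq=seq, pool=pool, clipped3=n3, clipped5=n5)


def size_filter(reads: Iterable[SmallRNARead], pool: str, cfg: PipelineConfig,
                tally: DiscardTally | None = None) -> tuple[list[SmallRNARead], DiscardTally]:
    """Keep reads whose length lies in the pool's inclusive size window."""
    if pool not in cfg.size_ranges:
        raise ValueError(f"no size range configured for pool {pool!r}")
    lo, hi = cfg.size_ranges[pool]
    tally = tally or DiscardTally()
    kept: list[SmallRNARead] = []
    for read in reads:
        n = len(read.seq)
        if n < lo:
            tally.too_short += 1
        elif n > hi:
            tally.too_long += 1
        else:
            tally.kept += 1
            kept.append(read)
    return kept, tally


def preprocess_pool(records: Iterable[SequenceRecord], pool: str,
                    cfg: PipelineConfig) -> tuple[list[SmallRNARead], DiscardTally]:
    """Clip then size-filter one pool; the tally conserves the input count."""
    tally = DiscardTally()
    clipped: list[SmallRNARead] = []
    for rec in records:
        out = clip_adapters(rec, cfg, pool=pool)
        if out is None:
            tally.discarded_no_adapter += 1
        else:
            clipped.append(out)
    kept, tally = size_filter(clipped, pool, cfg, tally)
    return kept, tally
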