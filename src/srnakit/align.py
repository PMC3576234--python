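"""All-hits ungapped read mapping with a bounded mismatch count.

Enumerates every placement of a read on both strands of the genome with
Hamming distance <= ``max_mismatches`` (no indels), the all-alignments
one-mismatch regime used throughout the pipeline. Exactness comes from
pigeonhole seeding: a read is split into ``max_mismatches + 1`` contiguous
parts, and any qualifying placement must match at least one part exactly;
each exact part occurrence found through a k-mer index nominates one
candidate placement, which is then fully verified. ``brute_force_map`` is
the quadratic ground-truth scan used by the test suite.

Coordinates always refer to the forward genome; for minus-strand hits the
read equals the reverse complement of the genome window (BED/SAM
convention). N in read or genome never matches and always counts as a
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .config import PipelineConfig
from .io import SequenceRecord, revcomp

__all__ = ["AlignmentHit", "GenomeIndex", "build_index", "map_read", "brute_force_map"]


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One ungapped placement of a read on a genome contig."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __len__(self) -> int:
        return self.end - self.start


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            n += 1
            if limit is not None and n > limit:
                return n
    return n


class GenomeIndex:
    """Contig sequences plus an exact k-mer -> positions table.

    k-mers containing N are not indexed: N never matches, so no N-containing
    window can be an exact seed occurrence.
    """

    def __init__(self, contigs: dict[str, str], k: int):
        self.contigs = contigs
        self.k = k
        self._table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in contigs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" not in kmer:
                    self._table.setdefault(kmer, []).append((name, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (contig, position) occurrences of an exact k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"index built for k={self.k}, queried with {len(kmer)}-mer")
        return self._table.get(kmer, [])


def build_index(genome: Sequence[SequenceRecord], k: int) -> GenomeIndex:
    if k < 1:
        raise ValueError("k must be >= 1")
    contigs: dict[str, str] = {}
    for rec in genome:
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = rec.seq
    return GenomeIndex(contigs, k)


def _partitions(length: int, n_parts: int) -> list[tuple[int, int]]:
    """Split [0, length) into n_parts contiguous, near-equal pieces."""
    base, extra = divmod(length, n_parts)
    bounds, pos = [], 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


def _exact_occurrences(part: str, index: GenomeIndex) -> Iterator[tuple[str, int]]:
    """All exact occurrences of ``part`` (len >= k) via the seed table."""
    if "N" in part:
        return  # N never matches: no exact occurrence possible
    seed = part[: index.k]
    for contig, pos in index.lookup(seed):
        if index.contigs[contig].startswith(part, pos):
            yield contig, pos


def map_read(read, index: GenomeIndex, cfg: PipelineConfig) -> list[AlignmentHit]:
    """Exactly the set of placements with <= cfg.max_mismatches mismatches.

    Falls back to a full window scan for reads too short to carry
    ``max_mismatches + 1`` parts of at least k bases each.
    """
    mm = cfg.max_mismatches
    seq = read.seq
    n_parts = mm + 1
    if len(seq) < n_parts * index.k:
        genome = [SequenceRecord(id=c, seq=s) for c, s in index.contigs.items()]
        return brute_force_map(read, genome, cfg)

    results: dict[tuple[str, int, str], int] = {}
    for strand in ("+", "-"):
        query = seq if strand == "+" else revcomp(seq)
        for p_start, p_end in _partitions(len(query), n_parts):
            part = query[p_start:p_end]
            for contig, occ in _exact_occurrences(part, index):
                start = occ - p_start
                cseq = index.contigs[contig]
                if start < 0 or start + len(query) > len(cseq):
                    continue
                key = (contig, start, strand)
                if key in results:
                    continue
                d = hamming(query, cseq[start : start + len(query)], limit=mm)
                if d <= mm:
                    results[key] = d
    return sorted(
        AlignmentHit(
            read_id=read.id, contig=contig, start=start, end=start + len(seq),
            strand=strand, mismatches=d,
        )
        for (contig, start, strand), d in results.items()
    )


def brute_force_map(read, genome: Iterable[SequenceRecord],
                    cfg: PipelineConfig) -> list[AlignmentHit]:
    """Direct O(genome x readlen) scan over every window on both strands."""
    mm = cfg.max_mismatches
    seq = read.seq
    rc = revcomp(seq)
    out: list[AlignmentHit] = []
    for rec in genome:
        cseq = rec.seq
        for start in range(len(cseq) - len(seq) + 1):
            window = cseq[start : start + len(seq)]
            for strand, query in (("+", seq), ("-", rc)):
                d = hamming(query, window, limit=mm)
                if d <= mm:
                    out.append(
                        AlignmentHit(
                            read_id=read.id, contig=rec.id, start=start,
                            end=start + len(seq), strand=strand, mismatches=d,
                        )
                    )
    return sorted(out)
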