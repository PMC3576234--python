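"""Hairpin-based miRNA gene calling.

Each genomic placement of a read is inspected by folding the alignment
plus 50 bp of flank on either side and testing three structural criteria
on the best stem-loop overlapping the read:

* an unpaired terminal loop is present,
* at least 75% of the bases in the stem (both arms, bulges included in the
  denominator) are paired,
* the read itself lies on the stem, not in the loop.

A read is a bona fide miRNA if at least one of its placements passes;
passing windows overlapping on the same strand merge into loci. Candidate
locus hairpins are then compared against a reference hairpin/mature
collection: a candidate is considered against every reference hairpin
sharing an exact seed of at least 15 nt (either candidate strand), the
mature is slid ungapped along the reference hairpin, and a hit needs 95%
mature identity; the best identity wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .align import AlignmentHit
from .config import PipelineConfig
from .fold import FoldResult, StemLoop, fold, parse_stemloops
from .io import FeatureInterval, SequenceRecord, revcomp

__all__ = [
    "HairpinCall",
    "MirnaLocus",
    "ReferenceHit",
    "extract_window",
    "validate_hairpin",
    "call_mirna_loci",
    "compare_to_reference",
    "classify_locus",
]


@dataclass(frozen=True)
class HairpinCall:
    """Verdicts for one folded window around one alignment."""

    hit: AlignmentHit
    window_start: int  # genomic, forward-strand coordinates
    window_end: int
    truncated: bool
    fold: FoldResult
    stemloop: StemLoop | None
    read_offset: tuple[int, int]  # window-relative, on the folded strand
    has_loop: bool
    stem_frac_ok: bool
    read_in_stem: bool

    @property
    def passed(self) -> bool:
        return (
            self.stemloop is not None
            and self.has_loop
            and self.stem_frac_ok
            and self.read_in_stem
        )


@dataclass
class MirnaLocus:
    """Merged genomic interval supported by passing hairpin windows."""

    contig: str
    start: int
    end: int
    strand: str
    read_ids: set[str] = field(default_factory=set)
    calls: list[HairpinCall] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def representative(self) -> HairpinCall:
        """Deterministic exemplar: best stem, then leftmost window."""
        return min(
            self.calls,
            key=lambda c: (-(c.stemloop.n_pairs if c.stemloop else 0),
                           c.window_start, c.hit.read_id),
        )

    @property
    def hairpin_seq(self) -> str:
        return self.representative.fold.window_seq


@dataclass(frozen=True)
class ReferenceHit:
    ref_id: str
    identity: float
    seed_len: int
    mature_offset: int


def extract_window(hit: AlignmentHit, genome: Mapping[str, str],
                   flank: int = 50) -> tuple[str, tuple[int, int], bool]:
    """Window = alignment ± flank on the hit's strand.

    Returns (window_seq, read_offset, truncated): for minus-strand hits the
    window is reverse-complemented so the read lies on the folded strand,
    and the offsets are recomputed accordingly. ``truncated`` flags a
    window clipped at a contig edge.
    """
    contig = genome[hit.contig]
    w_start = max(0, hit.start - flank)
    w_end = min(len(contig), hit.end + flank)
    truncated = w_start > hit.start - flank or w_end < hit.end + flank
    window = contig[w_start:w_end]
    off = (hit.start - w_start, hit.end - w_start)
    if hit.strand == "-":
        window = revcomp(window)
        off = (len(window) - off[1], len(window) - off[0])
    return window, off, truncated


def validate_hairpin(hit: AlignmentHit, fold_result: FoldResult,
                     read_offset: tuple[int, int], window_span: tuple[int, int],
                     truncated: bool, cfg: PipelineConfig) -> HairpinCall:
    """Apply the three structural criteria to a folded window.

    Among stem-loops whose arms overlap the read interval, the one with the
    most pairs (tie: 5'-most) is selected; verdicts are computed on it.
    """
    stemloops = parse_stemloops(fold_result)
    r0, r1 = read_offset
    # candidate stem-loops: full span (arms plus terminal loop) touches the
    # read, so a read sitting in the loop still selects its hairpin and then
    # fails the read-in-stem verdict rather than being silently unjudged
    overlapping = [
        sl for sl in stemloops if r0 <= sl.outer3 and r1 - 1 >= sl.outer5
    ]
    chosen: StemLoop | None = None
    if overlapping:
        chosen = max(overlapping, key=lambda sl: (sl.n_pairs, -sl.outer5))
    has_loop = stem_frac_ok = read_in_stem = False
    if chosen is not None:
        has_loop = chosen.loop_len >= 1
        stem_frac_ok = chosen.stem_paired_frac >= cfg.min_stem_paired_frac
        in_loop = sum(1 for p in range(r0, r1) if chosen.in_loop(p))
        outside = sum(
            1 for p in range(r0, r1)
            if not chosen.contains(p) and not chosen.in_loop(p)
        )
        read_in_stem = outside == 0 and in_loop <= cfg.loop_overhang
    return HairpinCall(
        hit=hit, window_start=window_span[0], window_end=window_span[1],
        truncated=truncated, fold=fold_result, stemloop=chosen,
        read_offset=read_offset, has_loop=has_loop,
        stem_frac_ok=stem_frac_ok, read_in_stem=read_in_stem,
    )


def evaluate_hit(hit: AlignmentHit, genome: Mapping[str, str], cfg: PipelineConfig,
                 fold_fn: Callable[[str, PipelineConfig], FoldResult] = fold,
                 _cache: dict | None = None) -> HairpinCall:
    """Fold and validate one alignment window (folds cached by sequence)."""
    contig = genome[hit.contig]
    w_start = max(0, hit.start - cfg.hairpin_flank)
    w_end = min(len(contig), hit.end + cfg.hairpin_flank)
    window, off, truncated = extract_window(hit, genome, cfg.hairpin_flank)
    if _cache is not None and window in _cache:
        fr = _cache[window]
    else:
        fr = fold_fn(window, cfg)
        if _cache is not None:
            _cache[window] = fr
    return validate_hairpin(hit, fr, off, (w_start, w_end), truncated, cfg)


def call_mirna_loci(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                    genome: Mapping[str, str], cfg: PipelineConfig,
                    fold_fn: Callable[[str, PipelineConfig], FoldResult] = fold,
                    ) -> tuple[set[str], list[MirnaLocus], dict[str, list[HairpinCall]]]:
    """Bona fide reads and merged hairpin loci.

    A read is bona fide iff at least one of its placements yields a passing
    window; passing windows overlapping by >= 1 bp on the same contig and
    strand merge into one locus. Non-bona-fide reads are returned via the
    calls map so the caller can route them to target calling.
    """
    cache: dict[str, FoldResult] = {}
    calls: dict[str, list[HairpinCall]] = {}
    for read_id, hits in hits_by_read.items():
        calls[read_id] = [
            evaluate_hit(h, genome, cfg, fold_fn=fold_fn, _cache=cache) for h in hits
        ]
    bona_fide = {rid for rid, cs in calls.items() if any(c.passed for c in cs)}

    passing = sorted(
        (c for cs in calls.values() for c in cs if c.passed),
        key=lambda c: (c.hit.contig, c.hit.strand, c.window_start, c.window_end),
    )
    loci: list[MirnaLocus] = []
    for call in passing:
        last = loci[-1] if loci else None
        if (
            last is not None
            and last.contig == call.hit.contig
            and last.strand == call.hit.strand
            and call.window_start < last.end
        ):
            last.end = max(last.end, call.window_end)
            last.read_ids.add(call.hit.read_id)
            last.calls.append(call)
        else:
            loci.append(
                MirnaLocus(
                    contig=call.hit.contig, start=call.window_start,
                    end=call.window_end, strand=call.hit.strand,
                    read_ids={call.hit.read_id}, calls=[call],
                )
            )
    return bona_fide, loci, calls


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact substring shared by a and b (O(|a||b|))."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1] and ai != "N":
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _slide_identity(mature: str, ref_hairpin: str) -> tuple[float, int]:
    """Best ungapped identity of mature against any window of the hairpin."""
    m = len(mature)
    best, best_off = 0.0, -1
    for off in range(0, len(ref_hairpin) - m + 1):
        window = ref_hairpin[off : off + m]
        matches = sum(1 for x, y in zip(mature, window) if x == y and x != "N")
        ident = matches / m
        if ident > best:
            best, best_off = ident, off
    return best, best_off


def compare_to_reference(candidate_hairpin: str, mature: str,
                         reference: Sequence[tuple[SequenceRecord, SequenceRecord]],
                         cfg: PipelineConfig) -> ReferenceHit | None:
    """Best reference match for a candidate hairpin, or None.

    ``reference`` pairs each reference hairpin with its mature sequence;
    matching is keyed on the reference hairpin id. A reference is
    considered when it shares an exact seed of >= ``ref_min_seed`` nt with
    the candidate hairpin on either strand; the candidate's mature is then
    slid ungapped across the reference hairpin and must reach
    ``ref_min_identity``. Best identity wins; ties break on longer seed,
    then lexicographic reference id.
    """
    if len(mature) == 0:
        return None
    cand_rc = revcomp(candidate_hairpin)
    best: ReferenceHit | None = None
    for ref_hairpin, _ref_mature in reference:
        seed = max(
            _longest_common_substring(candidate_hairpin, ref_hairpin.seq),
            _longest_common_substring(cand_rc, ref_hairpin.seq),
        )
        if seed < cfg.ref_min_seed:
            continue
        if len(ref_hairpin.seq) < len(mature):
            continue
        ident, off = _slide_identity(mature, ref_hairpin.seq)
        if ident < cfg.ref_min_identity:
            continue
        hit = ReferenceHit(ref_id=ref_hairpin.id, identity=ident,
                           seed_len=seed, mature_offset=off)
        if (
            best is None
            or (hit.identity, hit.seed_len) > (best.identity, best.seed_len)
            or ((hit.identity, hit.seed_len) == (best.identity, best.seed_len)
                and hit.ref_id < best.ref_id)
        ):
            best = hit
    return best


_CLASS_PRECEDENCE = ("known_mirna_gene", "protein_coding_overlap", "pseudogene_overlap")


def classify_locus(locus: MirnaLocus, annotations: Sequence[FeatureInterval]) -> str:
    """Classify a locus by >= 1 bp overlap with gene annotations.

    Gene features carry their biotype in ``class_label`` ("miRNA",
    "protein_coding", "pseudogene"); precedence is known miRNA gene >
    protein coding > pseudogene > intergenic.
    """
    found: set[str] = set()
    span = FeatureInterval(contig=locus.contig, start=locus.start, end=locus.end,
                           strand=locus.strand, kind="other", name="locus")
    for feat in annotations:
        if feat.kind != "gene" or not feat.overlaps(span):
            continue
        label = feat.class_label.lower()
        if label == "mirna":
            found.add("known_mirna_gene")
        elif label == "pseudogene":
            found.add("pseudogene_overlap")
        else:
            found.add("protein_coding_overlap")
    for cls in _CLASS_PRECEDENCE:
        if cls in found:
            return cls
    return "intergenic"
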