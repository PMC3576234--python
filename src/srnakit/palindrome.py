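"""Discontiguous-palindrome (mirror) motif statistic for crasiRNA loci.

For every alignment of a crasiRNA, the alignment plus 50 bases up- and
downstream is extracted (on the strand the read mapped to). Windows cut
short by a contig edge are ignored, as are windows failing a complexity
gate of at least five distinct 3-mers. The mirror score of a window W of
length L is the number of positions i where W[i] equals the complement of
W[L-1-i] — i.e. position-wise agreement between W and its reverse
complement; matches come in symmetric pairs, so the score is always even.
Significance is empirical: the window is permuted (composition-preserving
Fisher-Yates) ``n_shuffles`` times and the p-value is the fraction of
permutations scoring at least the original. A locus belongs to the motif
cohort when at least one third of its window bases carry a complementary
match.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import AlignmentHit
from .config import PipelineConfig
from .io import revcomp

__all__ = [
    "MotifWindow",
    "PalindromeResult",
    "extract_motif_window",
    "count_distinct_3mers",
    "mirror_score",
    "empirical_p",
    "score_locus",
    "cohort_summary",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}  # N intentionally absent


@dataclass(frozen=True)
class MotifWindow:
    hit: AlignmentHit
    window_seq: str
    skipped: str | None = None  # None, "edge", or "low_complexity"


@dataclass(frozen=True)
class PalindromeResult:
    window: MotifWindow
    score: int
    match_frac: float
    n_shuffles: int
    n_ge: int
    p_value: float
    share_member: bool


def extract_motif_window(hit: AlignmentHit, genome: Mapping[str, str],
                         cfg: PipelineConfig) -> MotifWindow:
    """±flank window on the hit's strand; skip edge-clipped or trivial windows."""
    contig = genome[hit.contig]
    flank = cfg.motif_flank
    if hit.start - flank < 0 or hit.end + flank > len(contig):
        return MotifWindow(hit=hit, window_seq="", skipped="edge")
    window = contig[hit.start - flank : hit.end + flank]
    if hit.strand == "-":
        window = revcomp(window)
    n_frac = window.count("N") / len(window)
    if n_frac > 0.10 or count_distinct_3mers(window) < cfg.motif_min_distinct_3mers:
        return MotifWindow(hit=hit, window_seq=window, skipped="low_complexity")
    return MotifWindow(hit=hit, window_seq=window)


def count_distinct_3mers(seq: str) -> int:
    """Distinct overlapping 3-mers; 3-mers containing N are excluded."""
    if len(seq) < 3:
        raise ValueError("need at least 3 bases to count 3-mers")
    return len(
        {seq[i : i + 3] for i in range(len(seq) - 2) if "N" not in seq[i : i + 3]}
    )


def mirror_score(window_seq: str) -> int:
    """Positions where the base complements its mirror-image base.

    score = |{i : W[i] == revcomp(W)[i]}|; N never matches. Always even:
    no base is self-complementary, so matches occur in symmetric pairs.
    """
    if not window_seq:
        raise ValueError("empty window")
    L = len(window_seq)
    score = 0
    for i in range(L):
        partner = window_seq[L - 1 - i]
        if _COMP.get(partner) == window_seq[i]:
            score += 1
    return score


def _mirror_score_array(arr: np.ndarray) -> int:
    """mirror_score on a uint8 code array (A,C,G,T,N -> 0,1,2,3,4)."""
    comp = np.array([3, 2, 1, 0, 9], dtype=np.uint8)  # N -> sentinel, never matches
    return int(np.count_nonzero(arr == comp[arr[::-1]]))


_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def window_seed(cfg: PipelineConfig, hit: AlignmentHit) -> int:
    """Deterministic per-window child seed from (contig, start, strand).

    Results are independent of processing order and stable across runs with
    one global seed.
    """
    key = f"{cfg.rng_seed}:{hit.contig}:{hit.start}:{hit.strand}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def empirical_p(window_seq: str, cfg: PipelineConfig,
                rng: np.random.Generator) -> tuple[int, int, float]:
    """Composition-preserving permutation p-value for the mirror score.

    Returns (score, n_ge, p_value) with p = n_ge / n_shuffles, the fraction
    of shuffled windows scoring at least the original.
    """
    arr = _encode(window_seq)
    score = _mirror_score_array(arr)
    n_ge = 0
    for _ in range(cfg.motif_n_shuffles):
        if _mirror_score_array(rng.permutation(arr)) >= score:
            n_ge += 1
    return score, n_ge, n_ge / cfg.motif_n_shuffles


def score_locus(window: MotifWindow, cfg: PipelineConfig) -> PalindromeResult | None:
    """Full per-locus result; None for skipped windows."""
    if window.skipped is not None:
        return None
    rng = np.random.default_rng(window_seed(cfg, window.hit))
    score, n_ge, p = empirical_p(window.window_seq, cfg, rng)
    frac = score / len(window.window_seq)
    return PalindromeResult(
        window=window, score=score, match_frac=frac,
        n_shuffles=cfg.motif_n_shuffles, n_ge=n_ge, p_value=p,
        share_member=frac >= cfg.motif_share_threshold,
    )


def cohort_summary(results: Sequence[PalindromeResult | None],
                   cfg: PipelineConfig) -> dict:
    """Cohort share of mirror-motif loci and the p-value histogram.

    ``share`` is the fraction of non-skipped loci at or above the share
    threshold; ``share_all_loci`` uses every locus (skipped included) as
    the denominator. The histogram bins p-values in steps of 0.01.
    """
    scored = [r for r in results if r is not None]
    if not scored:
        raise ValueError("no scoreable loci in cohort")
    n_members = sum(1 for r in scored if r.share_member)
    edges = np.round(np.arange(0.0, 1.01 + 1e-9, 0.01), 2)
    hist, _ = np.histogram([r.p_value for r in scored], bins=edges)
    return {
        "n_loci": len(results),
        "n_scored": len(scored),
        "n_share_members": n_members,
        "share": n_members / len(scored),
        "share_all_loci": n_members / len(results),
        "p_hist_edges": edges.tolist(),
        "p_hist_counts": hist.tolist(),
    }
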