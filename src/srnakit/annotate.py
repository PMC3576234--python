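"""Downstream annotation of mapped small-RNA pools.

Covers gene-model expansion (±1000 bp to approximate missing UTRs), miRNA
target calling on non-hairpin alignments, repeat association for the
piRNA/crasiRNA pools (>= 1 bp overlap; multi-mapping reads may take several
repeat classes), cross-pool locus comparison, read-peak clustering, and
overlap counting against ChIP-enrichment intervals.

All overlap logic is half-open: an alignment abutting a feature end-to-
start shares no base and does not associate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .align import AlignmentHit
from .config import PipelineConfig
from .io import FeatureInterval

__all__ = [
    "GeneModel",
    "TargetRecord",
    "RepeatAssociation",
    "Peak",
    "build_gene_models",
    "expand_gene_model",
    "call_targets",
    "target_matrix",
    "associate_repeats",
    "compare_pools",
    "cluster_peaks",
    "overlap_peaks",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene annotation plus flags for which UTR ends are annotated."""

    gene: FeatureInterval
    has_utr5: bool = False
    has_utr3: bool = False
    children: tuple[FeatureInterval, ...] = ()


@dataclass
class TargetRecord:
    gene_name: str
    pool: str
    unique_read_count: int
    read_ids: set[str]


@dataclass
class RepeatAssociation:
    read_id: str
    class_labels: set[str]


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    n_reads: int


def build_gene_models(features: Sequence[FeatureInterval]) -> list[GeneModel]:
    """Assemble GeneModels from a mixed feature list (e.g. one GFF3 file).

    UTR/exon features are attached to the gene whose span contains them on
    the same contig; a gene has an annotated UTR end only when a matching
    utr5/utr3 child exists.
    """
    genes = [f for f in features if f.kind == "gene"]
    others = [f for f in features if f.kind in ("exon", "utr5", "utr3")]
    models = []
    for gene in genes:
        children = tuple(
            c for c in others
            if c.contig == gene.contig and c.start >= gene.start and c.end <= gene.end
        )
        models.append(GeneModel(
            gene=gene,
            has_utr5=any(c.kind == "utr5" for c in children),
            has_utr3=any(c.kind == "utr3" for c in children),
            children=children,
        ))
    return models


def expand_gene_model(gm: GeneModel, contig_len: int,
                      flank: int = 1000) -> FeatureInterval:
    """Expand the transcriptional ends lacking an annotated UTR by ``flank``.

    Strand-aware: on a minus-strand gene the 5' side is the genomic right.
    Coordinates clamp to [0, contig_len].
    """
    g = gm.gene
    start, end = g.start, g.end
    minus = g.strand == "-"
    grow_left = (gm.has_utr3 if minus else gm.has_utr5) is False
    grow_right = (gm.has_utr5 if minus else gm.has_utr3) is False
    if grow_left:
        start = max(0, start - flank)
    if grow_right:
        end = min(contig_len, end + flank)
    return FeatureInterval(contig=g.contig, start=start, end=end, strand=g.strand,
                           kind=g.kind, name=g.name, class_label=g.class_label)


def _feature_trees(features: Iterable[FeatureInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)
    return trees


def call_targets(hits: Sequence[AlignmentHit], genes: Sequence[FeatureInterval],
                 pool: str, read_seqs: Mapping[str, str]) -> list[TargetRecord]:
    """Genes supported by >= 1 bp overlapping alignments, with unique counts.

    ``hits`` must already exclude bona fide hairpin reads. The unique read
    count collapses identical read sequences, so sequencing duplicates do
    not inflate target support; ``read_seqs`` maps read id to insert
    sequence.
    """
    trees = _feature_trees(genes)
    support: dict[str, dict[str, set[str]]] = {}
    for hit in hits:
        tree = trees.get(hit.contig)
        if tree is None:
            continue
        for iv in tree.overlap(hit.start, hit.end):
            gene: FeatureInterval = iv.data
            per_gene = support.setdefault(gene.name, {"seqs": set(), "ids": set()})
            per_gene["seqs"].add(read_seqs[hit.read_id])
            per_gene["ids"].add(hit.read_id)
    return [
        TargetRecord(gene_name=name, pool=pool,
                     unique_read_count=len(d["seqs"]), read_ids=d["ids"])
        for name, d in sorted(support.items())
    ]


def target_matrix(records_by_pool: Mapping[str, Sequence[TargetRecord]],
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x pool unique-read-count matrix and its row-max-normalized copy."""
    if not records_by_pool:
        raise ValueError("need at least one pool")
    counts: dict[str, dict[str, int]] = {}
    for pool, records in records_by_pool.items():
        for rec in records:
            counts.setdefault(rec.gene_name, {})[pool] = rec.unique_read_count
    matrix = (
        pd.DataFrame.from_dict(counts, orient="index",
                               columns=list(records_by_pool))
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    row_max = matrix.max(axis=1)
    normalized = matrix.div(row_max.where(row_max > 0, 1), axis=0)
    return matrix, normalized


def associate_repeats(hits: Sequence[AlignmentHit],
                      repeats: Sequence[FeatureInterval],
                      ) -> tuple[list[RepeatAssociation], pd.DataFrame]:
    """Per-read repeat classes plus the class distribution table.

    A read associates with every repeat class any of its alignments
    overlaps by >= 1 bp. The distribution counts one assignment per
    (read, class); percentages are over total assignments, so multi-class
    reads contribute to several classes and the column still sums to 100.
    """
    trees = _feature_trees(f for f in repeats if f.kind == "repeat")
    classes: dict[str, set[str]] = {}
    for hit in hits:
        tree = trees.get(hit.contig)
        if tree is None:
            continue
        for iv in tree.overlap(hit.start, hit.end):
            classes.setdefault(hit.read_id, set()).add(iv.data.class_label)
    associations = [
        RepeatAssociation(read_id=rid, class_labels=labels)
        for rid, labels in sorted(classes.items())
    ]
    tally: dict[str, int] = {}
    for assoc in associations:
        for label in assoc.class_labels:
            tally[label] = tally.get(label, 0) + 1
    total = sum(tally.values())
    table = pd.DataFrame(
        {
            "class_label": sorted(tally),
            "n_reads": [tally[c] for c in sorted(tally)],
        }
    )
    table["percent"] = 100.0 * table["n_reads"] / total if total else 0.0
    return associations, table


def compare_pools(hits_a: Sequence[AlignmentHit], hits_b: Sequence[AlignmentHit],
                  ) -> tuple[set[tuple[str, str]], int, int]:
    """Read pairs from two pools whose alignments share >= 1 bp, same strand.

    Returns (pairs, distinct A reads in any pair, distinct B reads in any
    pair) — the overlap census used to show two pools are disjoint.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for hit in hits_b:
        trees.setdefault((hit.contig, hit.strand), IntervalTree()).addi(
            hit.start, hit.end, hit.read_id
        )
    pairs: set[tuple[str, str]] = set()
    for hit in hits_a:
        tree = trees.get((hit.contig, hit.strand))
        if tree is None:
            continue
        for iv in tree.overlap(hit.start, hit.end):
            pairs.add((hit.read_id, iv.data))
    return pairs, len({a for a, _ in pairs}), len({b for _, b in pairs})


def cluster_peaks(hits: Sequence[AlignmentHit], cfg: PipelineConfig) -> list[Peak]:
    """Single-linkage clustering of alignments into read peaks.

    Alignments on one contig chain while the gap between them is at most
    ``peak_max_gap``; clusters with fewer than ``peak_min_reads`` members
    are dropped. Strand is ignored: a peak is a pile-up of coverage.
    """
    by_contig: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        by_contig.setdefault(hit.contig, []).append(hit)
    peaks: list[Peak] = []
    for contig in sorted(by_contig):
        chunk = sorted(by_contig[contig], key=lambda h: (h.start, h.end))
        cur_start, cur_end, n = None, None, 0
        for hit in chunk:
            if cur_end is not None and hit.start <= cur_end + cfg.peak_max_gap:
                cur_end = max(cur_end, hit.end)
                n += 1
            else:
                if n >= cfg.peak_min_reads:
                    peaks.append(Peak(contig, cur_start, cur_end, n))
                cur_start, cur_end, n = hit.start, hit.end, 1
        if n >= cfg.peak_min_reads:
            peaks.append(Peak(contig, cur_start, cur_end, n))
    return peaks


def overlap_peaks(peaks: Sequence[Peak], enrichment: Sequence[FeatureInterval],
                  ) -> tuple[int, int, list[bool]]:
    """Count peaks overlapping >= 1 enrichment interval by >= 1 bp."""
    trees = _feature_trees(enrichment)
    flags: list[bool] = []
    for peak in peaks:
        tree = trees.get(peak.contig)
        flags.append(bool(tree is not None and tree.overlap(peak.start, peak.end)))
    return sum(flags), len(peaks), flags
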