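"""Deterministic synthetic data: genome, annotations, reads, truth ledger.

The generator emulates the study inputs at desk scale: a random background
genome carrying planted miRNA hairpin loci (arm + loop + reverse-
complemented arm), shuffled decoy loci, class-labelled repeat intervals
derived from per-class consensus sequences, gene models with known planted
target-read counts, and crasiRNA loci whose read-plus-flank window is
constructed with an exact designed fraction of mirror-matching positions.
Reads are sampled from the planted loci, 3' adapter-ligated (a configurable
fraction receives a sub-minimum adapter to exercise the discard rule), and
optionally perturbed with substitution errors. Every read is traceable to
one ledger entry, and identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import GeneModel
from .config import PipelineConfig
from .io import FeatureInterval, SequenceRecord, revcomp
from .preprocess import _longest_suffix_matching_prefix

__all__ = ["SimParams", "TruthLedger", "simulate_genome", "simulate_reads"]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimParams:
    """Study-scale knobs for the synthetic genome and read sets."""

    length: int = 60000
    n_contigs: int = 2
    gc: float = 0.5
    n_hairpins: int = 20
    stem_len: int = 25
    loop_len: int = 6
    n_decoys: int = 20
    repeat_counts: dict[str, int] = field(
        default_factory=lambda: {"LINE/L1": 6, "SINE/MIR": 6, "DNA/hAT": 3, "LTR/ERVL": 2}
    )
    repeat_len: int = 300
    repeat_divergence: float = 0.02
    n_genes: int = 5
    gene_len: int = 1200
    target_read_counts: tuple[int, ...] = (3, 0, 7, 1, 2)
    n_palindromes: int = 12
    palindrome_match_frac: float = 0.5
    n_crasi_random: int = 8
    enrich_frac: float = 0.6
    margin: int = 80
    seed: int = 17


@dataclass
class _ReadTruth:
    id: str
    pool: str
    locus_id: str
    contig: str
    start: int
    end: int
    strand: str
    insert: str
    adapter_len: int
    n_errors: int
    discard_expected: bool


@dataclass
class TruthLedger:
    """Machine-readable record of everything planted in the simulation."""

    contigs: dict[str, int] = field(default_factory=dict)
    hairpins: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    palindromes: list[dict] = field(default_factory=list)
    enrichment: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    # -- annotation views -------------------------------------------------
    def repeat_features(self) -> list[FeatureInterval]:
        return [
            FeatureInterval(contig=r["contig"], start=r["start"], end=r["end"],
                            strand=r["strand"], kind="repeat", name=r["id"],
                            class_label=r["class_label"])
            for r in self.repeats
        ]

    def enrichment_features(self) -> list[FeatureInterval]:
        return [
            FeatureInterval(contig=e["contig"], start=e["start"], end=e["end"],
                            strand=".", kind="peak", name=e["id"])
            for e in self.enrichment
        ]

    def gene_models(self) -> list[GeneModel]:
        return [
            GeneModel(
                gene=FeatureInterval(
                    contig=g["contig"], start=g["start"], end=g["end"],
                    strand=g["strand"], kind="gene", name=g["name"],
                    class_label="protein_coding",
                ),
                has_utr5=g["has_utr5"], has_utr3=g["has_utr3"],
            )
            for g in self.genes
        ]


class _Placer:
    """Non-overlapping placement with a safety margin, by rejection."""

    def __init__(self, contig_lens: Mapping[str, int], margin: int,
                 rng: np.random.Generator):
        self.contig_lens = dict(contig_lens)
        self.margin = margin
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lens}

    def place(self, length: int, tries: int = 2000) -> tuple[str, int]:
        names = sorted(self.contig_lens)
        for _ in range(tries):
            contig = names[int(self.rng.integers(len(names)))]
            clen = self.contig_lens[contig]
            if clen < length + 2 * self.margin:
                continue
            start = int(self.rng.integers(self.margin, clen - length - self.margin + 1))
            end = start + length
            if all(
                end + self.margin <= s or start - self.margin >= e
                for s, e in self.occupied[contig]
            ):
                self.occupied[contig].append((start, end))
                return contig, start
        raise RuntimeError("could not place feature: genome too crowded")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def _mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    if n_sub == 0:
        return seq
    positions = rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _mirror_window(length: int, match_frac: float, rng: np.random.Generator) -> str:
    """A window whose mirror-matching position count is exactly as designed.

    Pairs (i, L-1-i) are matched (right base set to the complement of the
    left) or deliberately mismatched; an odd-length middle base never
    matches, matching the scoring rule.
    """
    n_pairs = length // 2
    # an odd-length middle base can never match, so full coverage means
    # every symmetric pair; clamp the half-count rounding accordingly
    n_matched = min(int(round(match_frac * length / 2)), n_pairs)
    left = _random_seq(rng, n_pairs)
    middle = _random_seq(rng, 1) if length % 2 else ""
    matched = set(rng.choice(n_pairs, size=n_matched, replace=False).tolist())
    right = []
    for i in range(n_pairs - 1, -1, -1):  # build right half left-to-right
        comp = _COMP[left[i]]
        if i in matched:
            right.append(comp)
        else:
            alternatives = [b for b in _BASES if b != comp]
            right.append(alternatives[int(rng.integers(3))])
    return left + middle + "".join(right)


def simulate_genome(params: SimParams,
                    cfg: PipelineConfig | None = None,
                    ) -> tuple[list[SequenceRecord], TruthLedger]:
    """Build the genome and plant every feature class; fully seeded."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(params.seed)
    per = params.length // params.n_contigs
    contig_lens = {f"contig{i + 1}": per for i in range(params.n_contigs)}
    seqs = {c: list(_random_seq(rng, n, params.gc)) for c, n in contig_lens.items()}
    placer = _Placer(contig_lens, params.margin, rng)
    ledger = TruthLedger(contigs=dict(contig_lens))

    def plant(seq: str) -> tuple[str, int, int]:
        contig, start = placer.place(len(seq))
        seqs[contig][start : start + len(seq)] = list(seq)
        return contig, start, start + len(seq)

    flank = cfg.motif_flank
    crasi_lo, crasi_hi = cfg.size_ranges["crasirna"]

    for i in range(params.n_hairpins):
        # loop and loop-adjacent arm bases come from {A, C}: neither A.A,
        # A.C nor C.C can pair, so the designed stem is the unique optimum
        # and the fold cannot nibble into the loop on a pair-count tie
        arm = (_random_seq(rng, params.stem_len - 2, params.gc)
               + "".join("AC"[int(rng.integers(2))] for _ in range(2)))
        loop = "".join("AC"[int(rng.integers(2))] for _ in range(params.loop_len))
        locus = arm + loop + revcomp(arm)
        contig, start, end = plant(locus)
        ledger.hairpins.append({
            "id": f"hp{i + 1}", "contig": contig, "start": start, "end": end,
            "strand": "+", "stem_len": params.stem_len, "loop_len": params.loop_len,
            "arm5": [start, start + params.stem_len],
            "arm3": [end - params.stem_len, end],
        })

    for i in range(params.n_decoys):
        arm = _random_seq(rng, params.stem_len, params.gc)
        loop = _random_seq(rng, params.loop_len, params.gc)
        locus = "".join(rng.permutation(list(arm + loop + revcomp(arm))))
        contig, start, end = plant(locus)
        ledger.decoys.append({
            "id": f"decoy{i + 1}", "contig": contig, "start": start, "end": end,
        })

    rep_idx = 0
    for class_label in sorted(params.repeat_counts):
        consensus = _random_seq(rng, params.repeat_len, params.gc)
        for _ in range(params.repeat_counts[class_label]):
            rep_idx += 1
            n_sub = int(round(params.repeat_divergence * params.repeat_len))
            contig, start, end = plant(_mutate(consensus, n_sub, rng))
            ledger.repeats.append({
                "id": f"rep{rep_idx}", "contig": contig, "start": start,
                "end": end, "strand": "+", "class_label": class_label,
            })

    for i in range(params.n_genes):
        contig, start, end = plant(_random_seq(rng, params.gene_len, params.gc))
        planted = (params.target_read_counts[i % len(params.target_read_counts)]
                   if params.target_read_counts else 0)
        ledger.genes.append({
            "name": f"gene{i + 1}", "contig": contig, "start": start, "end": end,
            "strand": "+" if i % 2 == 0 else "-",
            "has_utr5": bool(i % 2), "has_utr3": False,
            "planted_target_reads": planted,
        })

    pal_idx = 0
    for planted_flag, count, frac in (
        (True, params.n_palindromes, params.palindrome_match_frac),
        (False, params.n_crasi_random, None),
    ):
        for _ in range(count):
            pal_idx += 1
            read_len = int(rng.integers(crasi_lo, crasi_hi + 1))
            window_len = read_len + 2 * flank
            if frac is None:
                window = _random_seq(rng, window_len, params.gc)
            else:
                window = _mirror_window(window_len, frac, rng)
            contig, start, end = plant(window)
            ledger.palindromes.append({
                "id": f"pal{pal_idx}", "contig": contig, "start": start, "end": end,
                "read_start": start + flank, "read_end": start + flank + read_len,
                "designed_match_frac": frac, "planted": frac is not None,
            })

    # ChIP-style enrichment intervals over a known fraction of crasiRNA loci
    for i, pal in enumerate(ledger.palindromes):
        if rng.random() < params.enrich_frac:
            ledger.enrichment.append({
                "id": f"enr{i + 1}", "contig": pal["contig"],
                "start": max(0, pal["read_start"] - 10),
                "end": pal["read_end"] + 10,
                "covers": pal["id"],
            })

    genome = [SequenceRecord(id=c, seq="".join(seqs[c])) for c in sorted(seqs)]
    return genome, ledger


def _emit_read(ledger: TruthLedger, rng: np.random.Generator, *, pool: str,
               locus_id: str, contig: str, start: int, end: int,
               genome: Mapping[str, str], adapter3: str, error_rate: float,
               short_adapter_frac: float, counter: list[int],
               strand: str | None = None) -> SequenceRecord:
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    insert = genome[contig][start:end]
    if strand == "-":
        insert = revcomp(insert)
    n_errors = int(rng.binomial(len(insert), error_rate))
    insert = _mutate(insert, n_errors, rng)
    # keep clipping unambiguous: an insert that happens to end in a >=5 nt
    # adapter prefix would clip short; its opposite strand almost never does
    if (_longest_suffix_matching_prefix(insert, adapter3, 5) > 0
            and _longest_suffix_matching_prefix(revcomp(insert), adapter3, 5) == 0):
        strand = "-" if strand == "+" else "+"
        insert = revcomp(insert)
    if rng.random() < short_adapter_frac:
        adapter_len = int(rng.integers(0, 5))
    else:
        adapter_len = int(rng.integers(5, len(adapter3) + 1))
    counter[0] += 1
    rid = f"{pool}_{counter[0]:05d}"
    ledger.reads.append(asdict(_ReadTruth(
        id=rid, pool=pool, locus_id=locus_id, contig=contig, start=start,
        end=end, strand=strand, insert=insert, adapter_len=adapter_len,
        n_errors=n_errors, discard_expected=adapter_len < 5,
    )))
    seq = insert + adapter3[:adapter_len]
    return SequenceRecord(id=rid, seq=seq, qual="I" * len(seq))


def simulate_reads(ledger: TruthLedger, genome_records: Sequence[SequenceRecord],
                   pool: str, cfg: PipelineConfig | None = None, *,
                   depth: int = 2, error_rate: float = 0.0,
                   short_adapter_frac: float = 0.1,
                   seed: int = 17) -> list[SequenceRecord]:
    """Sample adapter-ligated reads for one pool from the planted loci.

    miRNA reads come from hairpin arms (and, pool-matched in length, from
    decoy loci and planted gene-target positions); piRNA reads from repeat
    bodies; crasiRNA reads are the exact planted window centers plus
    repeat-derived reads. The ledger gains one entry per emitted read.
    """
    cfg = cfg or PipelineConfig()
    pool_offsets = {"mirna": 0, "pirna": 1, "crasirna": 2}
    if pool not in pool_offsets:
        raise ValueError(f"unknown pool {pool!r}")
    rng = np.random.default_rng(seed + pool_offsets[pool])
    genome = {r.id: r.seq for r in genome_records}
    lo, hi = cfg.size_ranges[pool]
    adapter3 = cfg.adapter3
    counter = [0]
    reads: list[SequenceRecord] = []

    def emit(locus_id: str, contig: str, start: int, end: int,
             strand: str | None = None) -> None:
        reads.append(_emit_read(
            ledger, rng, pool=pool, locus_id=locus_id, contig=contig,
            start=start, end=end, genome=genome, adapter3=adapter3,
            error_rate=error_rate, short_adapter_frac=short_adapter_frac,
            counter=counter, strand=strand,
        ))

    if pool == "mirna":
        for hp in ledger.hairpins:
            for _ in range(depth):
                arm = "arm5" if rng.random() < 0.5 else "arm3"
                a_start, a_end = hp[arm]
                rlen = int(rng.integers(lo, min(hi, a_end - a_start) + 1))
                start = int(rng.integers(a_start, a_end - rlen + 1))
                emit(hp["id"], hp["contig"], start, start + rlen)
        for decoy in ledger.decoys:
            for _ in range(depth):
                rlen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(decoy["start"], decoy["end"] - rlen + 1))
                emit(decoy["id"], decoy["contig"], start, start + rlen)
        for gene in ledger.genes:
            n_targets = gene["planted_target_reads"]
            if not n_targets:
                continue
            # distinct start positions -> distinct insert sequences; copies
            # share strand so uniqueness collapses them back to n_targets
            rlen = hi
            positions = rng.choice(
                gene["end"] - gene["start"] - rlen, size=n_targets, replace=False
            )
            for offset in sorted(int(p) for p in positions):
                start = gene["start"] + offset
                strand = "+" if rng.random() < 0.5 else "-"
                for _copy in range(int(rng.integers(1, 3))):
                    emit(gene["name"], gene["contig"], start, start + rlen, strand)
    elif pool == "pirna":
        for rep in ledger.repeats:
            for _ in range(depth):
                rlen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(rep["start"], rep["end"] - rlen + 1))
                emit(rep["id"], rep["contig"], start, start + rlen)
    elif pool == "crasirna":
        for pal in ledger.palindromes:
            for _ in range(depth):
                emit(pal["id"], pal["contig"], pal["read_start"], pal["read_end"])
        for rep in ledger.repeats:
            rlen = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(rep["start"], rep["end"] - rlen + 1))
            emit(rep["id"], rep["contig"], start, start + rlen)
    else:
        raise ValueError(f"unknown pool {pool!r}")
    return reads
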