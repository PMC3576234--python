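"""Gene expansion, target calling, repeat association, pools, peaks."""

import random

import pytest

from oracles import quadratic_cluster, quadratic_overlaps
from srnakit.align import AlignmentHit
from srnakit.annotate import (
    GeneModel, Peak, associate_repeats, build_gene_models, call_targets,
    cluster_peaks, compare_pools, expand_gene_model, overlap_peaks,
    target_matrix, TargetRecord,
)
from srnakit.config import PipelineConfig
from srnakit.io import FeatureInterval


def _hit(start, end, rid="r", contig="c1", strand="+"):
    return AlignmentHit(read_id=rid, contig=contig, start=start, end=end,
                        strand=strand, mismatches=0)


def _feat(start, end, contig="c1", strand="+", kind="repeat", name="f",
          class_label=""):
    return FeatureInterval(contig=contig, start=start, end=end, strand=strand,
                           kind=kind, name=name, class_label=class_label)


class TestExpandGeneModel:
    def _gm(self, start, end, strand="+", utr5=False, utr3=False):
        gene = _feat(start, end, strand=strand, kind="gene", name="g")
        return GeneModel(gene=gene, has_utr5=utr5, has_utr3=utr3)

    def test_both_ends_expanded(self):
        out = expand_gene_model(self._gm(5000, 8000), 100000, flank=1000)
        assert (out.start, out.end) == (4000, 9000)

    def test_clamped_at_contig_bounds(self):
        out = expand_gene_model(self._gm(300, 900), 1000, flank=1000)
        assert (out.start, out.end) == (0, 1000)

    def test_minus_strand_missing_utr3_expands_genomic_left(self):
        out = expand_gene_model(self._gm(5000, 8000, strand="-", utr5=True),
                                100000, flank=1000)
        assert (out.start, out.end) == (4000, 8000)

    def test_annotated_utrs_suppress_expansion(self):
        out = expand_gene_model(self._gm(5000, 8000, utr5=True, utr3=True),
                                100000, flank=1000)
        assert (out.start, out.end) == (5000, 8000)

    def test_idempotent_once_utrs_flagged(self):
        first = expand_gene_model(self._gm(5000, 8000), 100000, flank=1000)
        again = expand_gene_model(
            GeneModel(gene=first, has_utr5=True, has_utr3=True), 100000, 1000
        )
        assert (again.start, again.end) == (first.start, first.end)
        assert first.start >= 0


class TestCallTargets:
    def test_hit_in_expanded_flank_supports_gene(self):
        genes = [_feat(1000, 3000, kind="gene", name="g1")]
        hits = [_hit(1010, 1030, rid="r1")]
        out = call_targets(hits, genes, "mirna", {"r1": "ACGT"})
        assert len(out) == 1 and out[0].unique_read_count == 1

    def test_identical_sequences_collapse(self):
        genes = [_feat(0, 1000, kind="gene", name="g1")]
        hits = [_hit(10, 30, rid="a"), _hit(10, 30, rid="b")]
        out = call_targets(hits, genes, "mirna", {"a": "ACGTACGT", "b": "ACGTACGT"})
        assert out[0].unique_read_count == 1
        assert out[0].read_ids == {"a", "b"}

    def test_abutting_hit_does_not_support(self):
        genes = [_feat(100, 200, kind="gene", name="g1")]
        assert call_targets([_hit(80, 100)], genes, "mirna", {"r": "A"}) == []


class TestTargetMatrix:
    def test_row_normalized_by_max(self):
        records = {
            "tammar": [TargetRecord("Lrtm1", "tammar", 69, set())],
            "mouse": [TargetRecord("Lrtm1", "mouse", 49, set())],
            "human": [TargetRecord("Lrtm1", "human", 3, set())],
        }
        matrix, normalized = target_matrix(records)
        assert matrix.loc["Lrtm1"].tolist() == [69, 49, 3]
        assert normalized.loc["Lrtm1"].tolist() == pytest.approx(
            [1.0, 49 / 69, 3 / 69]
        )

    def test_single_pool_gives_zero_one(self):
        records = {"p": [TargetRecord("g1", "p", 5, set()),
                         TargetRecord("g2", "p", 0, set())]}
        _, normalized = target_matrix(records)
        assert set(normalized["p"]) <= {0.0, 1.0}

    def test_all_zero_row_stays_zero(self):
        records = {"a": [TargetRecord("g", "a", 0, set())],
                   "b": [TargetRecord("g", "b", 0, set())]}
        _, normalized = target_matrix(records)
        assert normalized.loc["g"].tolist() == [0.0, 0.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            target_matrix({})


class TestAssociateRepeats:
    def test_multi_class_union(self):
        repeats = [_feat(110, 200, class_label="LINE/L1", name="L"),
                   _feat(50, 105, class_label="SINE/MIR", name="S")]
        assoc, table = associate_repeats([_hit(100, 120)], repeats)
        assert assoc[0].class_labels == {"LINE/L1", "SINE/MIR"}
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_abutting_repeat_not_associated(self):
        repeats = [_feat(120, 200, class_label="LINE/L1")]
        assoc, table = associate_repeats([_hit(100, 120)], repeats)
        assert assoc == [] and table.empty

    def test_percentages_sum_to_100_on_random_fixture(self):
        rng = random.Random(7)
        repeats = [
            _feat(s, s + rng.randint(50, 200),
                  class_label=rng.choice(["LINE", "SINE", "DNA"]))
            for s in rng.sample(range(0, 20000, 40), 100)
        ]
        hits = [_hit(s, s + 30, rid=f"r{i}")
                for i, s in enumerate(rng.sample(range(0, 20000), 300))]
        _, table = associate_repeats(hits, repeats)
        assert table["percent"].sum() == pytest.approx(100.0)


class TestComparePools:
    def test_single_shared_locus(self):
        pairs, na, nb = compare_pools([_hit(100, 136, rid="a")],
                                      [_hit(120, 150, rid="b")])
        assert pairs == {("a", "b")} and (na, nb) == (1, 1)

    def test_disjoint_pools(self):
        pairs, na, nb = compare_pools([_hit(0, 30)], [_hit(100, 130)])
        assert pairs == set() and (na, nb) == (0, 0)

    def test_strand_must_match(self):
        pairs, _, _ = compare_pools([_hit(100, 130, strand="+")],
                                    [_hit(100, 130, strand="-")])
        assert pairs == set()

    def test_three_over_two_fixture(self):
        crasi = [_hit(100, 140, rid=f"c{i}") for i in range(3)]
        pi = [_hit(110, 140, rid="p1"), _hit(120, 150, rid="p2")]
        pairs, na, nb = compare_pools(crasi, pi)
        assert (na, nb) == (3, 2) and len(pairs) == 6


class TestClusterPeaks:
    def _cfg(self, min_reads=1, gap=0):
        return PipelineConfig(peak_min_reads=min_reads, peak_max_gap=gap)

    def test_two_clusters(self):
        hits = [_hit(0, 36), _hit(10, 46), _hit(100, 140)]
        peaks = cluster_peaks(hits, self._cfg(min_reads=1))
        assert [(p.start, p.end, p.n_reads) for p in peaks] == [
            (0, 46, 2), (100, 140, 1),
        ]

    def test_min_reads_threshold(self):
        hits = [_hit(0, 36), _hit(10, 46), _hit(100, 140)]
        peaks = cluster_peaks(hits, self._cfg(min_reads=2))
        assert [(p.start, p.end, p.n_reads) for p in peaks] == [(0, 46, 2)]

    def test_matches_quadratic_union_find(self):
        rng = random.Random(13)
        for gap in (0, 5):
            hits = [
                _hit(s, s + rng.randint(20, 60), rid=f"r{i}",
                     contig=rng.choice(["c1", "c2"]))
                for i, s in enumerate(rng.choices(range(0, 3000), k=120))
            ]
            expected = quadratic_cluster(
                [(h.contig, h.start, h.end) for h in hits], max_gap=gap
            )
            got = sorted(
                (p.contig, p.start, p.end, p.n_reads)
                for p in cluster_peaks(hits, self._cfg(min_reads=1, gap=gap))
            )
            assert got == expected


class TestOverlapPeaks:
    def test_constructed_six_of_ten(self):
        peaks = [Peak("c1", i * 100, i * 100 + 40, 3) for i in range(10)]
        enrichment = [_feat(i * 100 + 20, i * 100 + 60, kind="peak")
                      for i in range(6)]
        n_over, n_total, flags = overlap_peaks(peaks, enrichment)
        assert (n_over, n_total) == (6, 10)
        assert flags == [True] * 6 + [False] * 4

    def test_different_contig_never_overlaps(self):
        peaks = [Peak("c1", 0, 100, 3)]
        n_over, _, _ = overlap_peaks(peaks, [_feat(0, 100, contig="c2", kind="peak")])
        assert n_over == 0

    def test_matches_quadratic_oracle(self):
        rng = random.Random(17)
        peaks = [Peak("c1", s, s + 50, 2)
                 for s in rng.sample(range(0, 10000, 10), 150)]
        enrichment = [_feat(s, s + 80, kind="peak")
                      for s in rng.sample(range(0, 10000, 10), 150)]
        expected_idx = {i for i, _ in quadratic_overlaps(
            [("c1", p.start, p.end) for p in peaks],
            [("c1", f.start, f.end) for f in enrichment],
        )}
        _, _, flags = overlap_peaks(peaks, enrichment)
        assert {i for i, f in enumerate(flags) if f} == expected_idx


class TestBuildGeneModels:
    def test_utr_children_set_flags(self):
        feats = [
            _feat(1000, 5000, kind="gene", name="g1"),
            _feat(1000, 1200, kind="utr5", name="g1.utr5"),
            _feat(6000, 9000, kind="gene", name="g2"),
        ]
        models = {m.gene.name: m for m in build_gene_models(feats)}
        assert models["g1"].has_utr5 and not models["g1"].has_utr3
        assert not models["g2"].has_utr5 and not models["g2"].has_utr3
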