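import numpy as np
import pytest

from svcna.catalog import (
    Breakend,
    GeneModel,
    Rearrangement,
    SvCluster,
    classify_simple,
    cn_boundaries_from_segments,
    detect_kinase_fusions,
    group_clusters,
    merge_consensus,
    orientation_counts,
    read_bedpe,
    write_bedpe,
)
from svcna.cna import CnSegment
from svcna.genome import GenomeLayout, Interval


def rearr(id_, c1, p1, o1, c2, p2, o2, sample="S0", **kw):
    return Rearrangement(id_, sample, Breakend(c1, p1, o1), Breakend(c2, p2, o2),
                         **kw)


def deletion(id_, chrom, start, end, **kw):
    return rearr(id_, chrom, start, "+", chrom, end, "-", **kw)


class TestRearrangement:
    def test_canonical_ordering(self):
        r = rearr("a", "chr2", 100, "-", "chr1", 50, "+")
        assert (r.bnd1.chrom, r.bnd1.pos) == ("chr1", 50)

    def test_orientation_class_swap_invariant(self):
        a = rearr("a", "chr1", 100, "+", "chr1", 500, "-")
        b = Rearrangement("b", "S0", Breakend("chr1", 500, "-"),
                          Breakend("chr1", 100, "+"))
        assert a.orientation_class == b.orientation_class == "del_like"

    def test_length(self):
        assert deletion("a", "chr1", 100, 400).length == 300
        assert rearr("a", "chr1", 1, "+", "chr2", 2, "-").length is None


class TestMergeConsensus:
    @pytest.fixture
    def layout(self):
        return GenomeLayout(["chr1", "chr2"], {"chr1": 10_000_000,
                                               "chr2": 10_000_000})

    def test_two_caller_merge(self, layout):
        callsets = {
            "manta": [deletion("m1", "chr1", 100_000, 200_000)],
            "delly": [deletion("d1", "chr1", 100_150, 200_150)],
        }
        merged = merge_consensus(callsets, layout=layout)
        assert len(merged) == 1
        assert merged[0].callers == {"manta", "delly"}

    def test_single_caller_rescued_by_cn_boundary(self, layout):
        callsets = {"manta": [deletion("m1", "chr1", 100_000, 200_000)]}
        boundaries = {"chr1": np.array([102_000])}
        assert len(merge_consensus(callsets, boundaries, layout=layout)) == 1

    def test_single_caller_no_boundary_dropped(self, layout):
        callsets = {"manta": [deletion("m1", "chr1", 100_000, 200_000)]}
        boundaries = {"chr1": np.array([110_000])}
        assert merge_consensus(callsets, boundaries, layout=layout) == []

    def test_prefilters(self, layout):
        callsets = {
            "manta": [
                deletion("normal", "chr1", 100_000, 200_000, normal_support=2),
                deletion("lowvaf", "chr1", 300_000, 400_000,
                         tumour_support_frac=0.01),
                deletion("offref", "chrUn", 1_000, 2_000),
            ],
            "delly": [
                deletion("normal2", "chr1", 100_100, 200_100, normal_support=1),
                deletion("lowvaf2", "chr1", 300_100, 400_100,
                         tumour_support_frac=0.01),
            ],
        }
        assert merge_consensus(callsets, layout=layout) == []

    def test_orientation_mismatch_not_merged(self, layout):
        callsets = {
            "manta": [deletion("m1", "chr1", 100_000, 200_000)],
            "delly": [rearr("d1", "chr1", 100_000, "-", "chr1", 200_000, "+")],
        }
        assert merge_consensus(callsets, layout=layout) == []

    def test_order_invariance(self, layout):
        a = deletion("a", "chr1", 100_000, 200_000)
        b = deletion("b", "chr1", 100_100, 200_100)
        c = deletion("c", "chr2", 500_000, 600_000)
        m1 = merge_consensus({"x": [a, c], "y": [b]}, layout=layout)
        m2 = merge_consensus({"y": [b], "x": [c, a]}, layout=layout)
        key = lambda r: (r.bnd1.chrom, r.bnd1.pos)
        assert [key(r) for r in m1] == [key(r) for r in m2]

    def test_unknown_caller_errors(self, layout):
        with pytest.raises(ValueError):
            merge_consensus({"mystery": []}, layout=layout,
                            known_callers={"manta", "delly", "lumpy"})


class TestGroupClusters:
    def test_distant_svs_separate(self):
        svs = [deletion("a", "chr1", 0, 50_000),
               deletion("b", "chr1", 10_000_000, 10_050_000)]
        clusters = group_clusters(svs, d_cl=1_000_000)
        assert [c.size for c in clusters] == [1, 1]

    def test_lone_deletion_simple(self):
        clusters = group_clusters([deletion("a", "chr1", 0, 50_000)])
        assert clusters[0].size == 1 and not clusters[0].is_complex

    def test_three_proximal_complex(self):
        svs = [deletion(f"s{i}", "chr1", 100_000 + i * 200_000,
                        150_000 + i * 200_000) for i in range(3)]
        clusters = group_clusters(svs, d_cl=1_000_000)
        assert len(clusters) == 1 and clusters[0].is_complex

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        svs = [
            deletion(f"s{i}", f"chr{rng.integers(1, 4)}",
                     int(rng.integers(0, 50_000_000)),
                     int(rng.integers(50_000_001, 99_000_000)))
            for i in range(100)
        ]
        clusters = group_clusters(svs)
        assert sum(c.size for c in clusters) == len(svs)
        seen = [r.id for c in clusters for r in c.rearrangements]
        assert len(set(seen)) == len(svs)

    def test_dfp_gt_dcl_errors(self):
        with pytest.raises(ValueError):
            group_clusters([], d_fp=2_000_000, d_cl=1_000_000)


class TestClassifySimple:
    def one(self, r, **kw):
        return classify_simple(group_clusters([r])[0], **kw)

    def test_deletion(self):
        assert self.one(deletion("a", "chr5", 1_000_000, 1_200_000)) == "deletion"

    def test_tandem_duplication(self):
        r = rearr("a", "chr5", 1_000_000, "-", "chr5", 1_200_000, "+")
        assert self.one(r) == "tandem_duplication"

    def test_lone_inversion_junction_unclassified(self):
        r = rearr("a", "chr5", 1_000_000, "+", "chr5", 1_200_000, "+")
        assert self.one(r) == "simple_unclassified"

    def test_balanced_inversion(self):
        svs = [
            rearr("a", "chr5", 1_000_000, "+", "chr5", 2_000_000, "+"),
            rearr("b", "chr5", 1_001_000, "-", "chr5", 2_001_000, "-"),
        ]
        cluster = group_clusters(svs)[0]
        assert cluster.size == 2
        assert classify_simple(cluster) == "balanced_inversion"

    def test_balanced_translocation(self):
        svs = [
            rearr("a", "chr1", 5_000_000, "+", "chr3", 9_000_000, "-"),
            rearr("b", "chr1", 5_001_000, "-", "chr3", 9_001_000, "+"),
        ]
        cluster = group_clusters(svs)[0]
        assert classify_simple(cluster) == "balanced_translocation"

    def test_unbalanced_translocation_with_cn_step(self):
        r = rearr("a", "chr1", 5_000_000, "+", "chr3", 9_000_000, "-")
        segs = [CnSegment(Interval("chr1", 0, 5_001_000), 2, 1),
                CnSegment(Interval("chr1", 5_001_000, 10_000_000), 1, 1)]
        boundaries = cn_boundaries_from_segments(segs)
        assert self.one(r, cn_boundaries=boundaries) == "unbalanced_translocation"

    def test_lone_translocation_flat_cn_unclassified(self):
        r = rearr("a", "chr1", 5_000_000, "+", "chr3", 9_000_000, "-")
        assert self.one(r) == "simple_unclassified"

    def test_complex_cluster_rejected(self):
        svs = [deletion(f"s{i}", "chr1", 100_000 + i * 10_000,
                        120_000 + i * 10_000) for i in range(3)]
        with pytest.raises(ValueError):
            classify_simple(group_clusters(svs)[0])

    def test_totality_on_random_small_clusters(self):
        rng = np.random.default_rng(7)
        labels = {
            "deletion", "tandem_duplication", "balanced_inversion",
            "balanced_translocation", "unbalanced_translocation",
            "simple_unclassified",
        }
        svs = []
        for i in range(60):
            c1 = f"chr{rng.integers(1, 3)}"
            c2 = f"chr{rng.integers(1, 3)}"
            p1 = int(rng.integers(0, 40_000_000))
            p2 = int(rng.integers(0, 40_000_000))
            if c1 == c2 and p1 == p2:
                p2 += 1000
            o1, o2 = rng.choice(["+", "-"], size=2)
            svs.append(rearr(f"r{i}", c1, p1, o1, c2, p2, o2))
        for cluster in group_clusters(svs):
            if cluster.size <= 2:
                assert classify_simple(cluster) in labels


class TestOrientationCounts:
    def test_all_deletions(self):
        svs = [deletion(f"d{i}", "chr1", i * 1_000_000, i * 1_000_000 + 500_000)
               for i in range(4)]
        oc = orientation_counts(SvCluster(svs))
        assert oc.as_tuple() == (4, 0, 0, 0)

    def test_interchromosomal_excluded(self):
        svs = [rearr("t", "chr1", 1, "+", "chr2", 2, "-")]
        assert orientation_counts(SvCluster(svs)).as_tuple() == (0, 0, 0, 0)

    def test_one_of_each(self):
        svs = [
            rearr("a", "chr1", 1_000_000, "+", "chr1", 2_000_000, "-"),
            rearr("b", "chr1", 3_000_000, "-", "chr1", 4_000_000, "+"),
            rearr("c", "chr1", 5_000_000, "+", "chr1", 6_000_000, "+"),
            rearr("d", "chr1", 7_000_000, "-", "chr1", 8_000_000, "-"),
        ]
        assert orientation_counts(SvCluster(svs)).as_tuple() == (1, 1, 1, 1)


class TestKinaseFusions:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel("NTRK1", "chr1", 10_000_000, 10_100_000, "+",
                      kinase_domain=Interval("chr1", 10_060_000, 10_090_000)),
            GeneModel("PARTNER", "chr2", 5_000_000, 5_200_000, "+"),
        ]

    def test_fusion_detected(self, genes):
        r = rearr("f", "chr1", 10_020_000, "-", "chr2", 5_050_000, "+")
        hits = detect_kinase_fusions([r], genes, {"NTRK1"})
        assert len(hits) == 1
        assert hits[0].kinase_gene == "NTRK1" and hits[0].partner_gene == "PARTNER"

    def test_junction_after_domain_no_fusion(self, genes):
        r = rearr("f", "chr1", 10_095_000, "-", "chr2", 5_050_000, "+")
        assert detect_kinase_fusions([r], genes, {"NTRK1"}) == []

    def test_strand_incompatible_no_fusion(self, genes):
        r = rearr("f", "chr1", 10_020_000, "+", "chr2", 5_050_000, "+")
        assert detect_kinase_fusions([r], genes, {"NTRK1"}) == []

    def test_missing_domain_warns(self):
        genes = [GeneModel("RET", "chr10", 0, 100_000, "+")]
        r = rearr("f", "chr10", 10_000, "-", "chr2", 5_050_000, "+")
        with pytest.warns(UserWarning):
            assert detect_kinase_fusions([r], genes, {"RET"}) == []


class TestBedpeRoundTrip:
    def test_round_trip(self, tmp_path):
        svs = [
            deletion("a", "chr1", 100_000, 200_000, callers=frozenset({"manta"})),
            rearr("b", "chr1", 5_000_000, "-", "chr2", 1_000_000, "+",
                  sample="S1"),
        ]
        path = tmp_path / "x.bedpe"
        write_bedpe(svs, str(path))
        back = read_bedpe(str(path))
        assert len(back) == 2
        assert back[0].bnd1.pos == 100_000
        assert back[0].orientation_class == "del_like"
        assert back[1].sample_id == "S1"
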