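import numpy as np
import pytest

from svcna.catalog import Breakend, Rearrangement

from svcna.genome import GenomeLayout, Interval, build_bins
from svcna.hotspots import (
    FragileAnnotation,
    Hotspot,
    PcfParams,
    PcfSegment,
    classify_fragile,
    empirical_fdr,
    filter_and_collapse,
    imd_series,
    pcf,
    pcf_cost,
    segment_stats,
    select_parameters,
)


class TestImd:
    def test_basic(self):
        np.testing.assert_allclose(imd_series(np.array([100, 1100])), [3.0])

    def test_duplicate_positions_floored(self):
        np.testing.assert_allclose(imd_series(np.array([5, 5])), [0.0])

    def test_single_breakend_empty(self):
        assert len(imd_series(np.array([42]))) == 0

    def test_unsorted_errors(self):
        with pytest.raises(ValueError):
            imd_series(np.array([5, 1]))


def pcf_oracle(values, gamma, kmin):
    """Exhaustive enumeration over all valid segmentations."""
    n = len(values)
    v = np.asarray(values, float)
    sse = np.zeros((n, n + 1))
    for a in range(n):
        cs = np.cumsum(v[a:])
        cs2 = np.cumsum(v[a:] ** 2)
        w = np.arange(1, n - a + 1)
        sse[a, a + 1:] = cs2 - cs * cs / w
    best = [None]

    def rec(start, cost, bounds):
        if start == n:
            key = (cost, len(bounds), tuple(bounds))
            if best[0] is None or key < best[0]:
                best[0] = key
            return
        for e in range(start + kmin, n + 1):
            if e != n and n - e < kmin:
                continue
            rec(e, cost + sse[start, e] + gamma, bounds + [e])

    rec(0, 0.0, [])
    return best[0]


class TestPcf:
    def test_constant_series_one_segment(self):
        for gamma in (0.5, 1, 10):
            segs = pcf(np.full(20, 3.3), PcfParams(gamma=gamma, kmin=2))
            assert len(segs) == 1

    def test_step_series(self):
        segs = pcf(np.array([0, 0, 0, 5, 5, 5.0]), PcfParams(gamma=1, kmin=2))
        assert [(a, b) for a, b, _ in segs] == [(0, 3), (3, 6)]
        assert segs[0][2] == 0.0 and segs[1][2] == 5.0

    def test_short_series_single_segment_warns(self):
        with pytest.warns(UserWarning):
            segs = pcf(np.array([1.0, 2.0]), PcfParams(gamma=1, kmin=5))
        assert len(segs) == 1

    def test_kmin_respected(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        for kmin in (2, 5, 9):
            for a, b, _ in pcf(v, PcfParams(gamma=0.5, kmin=kmin)):
                assert b - a >= kmin

    def test_oracle_equivalence_random_suite(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(5, 20))
            v = rng.normal(size=n) * float(rng.uniform(0.5, 3))
            for gamma in (1, 10):
                for kmin in (2, 3):
                    got = pcf(v, PcfParams(gamma=gamma, kmin=kmin))
                    cost_o, _, bounds_o = pcf_oracle(v, gamma, kmin)
                    assert pcf_cost(v, got, gamma) == pytest.approx(cost_o)
                    assert tuple(b for _, b, _ in got) == bounds_o


@pytest.fixture
def stats_grid():
    layout = GenomeLayout(["chr1"], {"chr1": 10_000_000})
    grid = build_bins(layout, 1_000_000)
    grid.set_b(np.full(10, 3.0))
    return grid


class TestSegmentStats:
    def test_arithmetic(self, stats_grid):
        # 12 breakends spanning 100 kb inside one bin
        positions = np.linspace(500_000, 599_999, 12).astype(np.int64)
        seg = segment_stats("chr1", (0, 11), positions, stats_grid)
        assert seg.a_i == 12
        assert seg.s_i == 100_000
        assert seg.d_obs == pytest.approx(1.2e-4)
        assert seg.d_exp == pytest.approx(3e-6)
        assert seg.beta_simple == pytest.approx(40.0)

    def test_multi_bin_segment(self, stats_grid):
        positions = np.array([500_000, 2_500_000])
        seg = segment_stats("chr1", (0, 1), positions, stats_grid)
        assert seg.d_exp == pytest.approx(3 * 3.0 / (3 * 1e6))


def mk_seg(beta, chrom="chr1", start=0, end=1000):
    return PcfSegment(chrom, 0, 1, start, end, a_i=11, s_i=end - start + 1,
                      d_obs=1.0, d_exp=1.0 / beta if beta else 1.0,
                      beta_simple=beta)


class TestEmpiricalFdr:
    def test_formula(self):
        observed = [mk_seg(10.0), mk_seg(3.0), mk_seg(2.0), mk_seg(1.0)]
        # replicate beta sets: exceedances of v=1.0 are [1, 0, 1, 2]
        simulated = [[mk_seg(1.5)], [mk_seg(0.5)], [mk_seg(1.2)],
                     [mk_seg(2.5), mk_seg(1.1)]]
        out = empirical_fdr(observed, simulated)
        assert out[3].fdr == pytest.approx(1.0 / 4)

    def test_cap_at_one(self):
        observed = [mk_seg(1.0)]
        simulated = [[mk_seg(2.0), mk_seg(3.0)]] * 3
        assert empirical_fdr(observed, simulated)[0].fdr == 1.0

    def test_zero_replaced_by_min_nonzero(self):
        observed = [mk_seg(100.0), mk_seg(2.0)]
        simulated = [[mk_seg(2.5)], [mk_seg(0.5)]]
        out = empirical_fdr(observed, simulated)
        # top segment never reached in sims -> would be 0 -> floor at other fdr
        assert out[0].fdr == out[1].fdr > 0

    def test_monotone_in_beta(self):
        observed = [mk_seg(b) for b in (5.0, 4.0, 3.0, 2.0)]
        simulated = [[mk_seg(b) for b in (4.5, 2.5)], [mk_seg(3.5)]]
        out = empirical_fdr(observed, simulated)
        betas = [s.beta_simple for s in out]
        fdrs = [s.fdr for s in out]
        for i in range(len(out) - 1):
            assert (betas[i] - betas[i + 1]) * (fdrs[i + 1] - fdrs[i]) >= 0

    def test_empty_observed(self):
        assert empirical_fdr([], [[mk_seg(1.0)]]) == []

    def test_no_replicates_errors(self):
        with pytest.raises(ValueError):
            empirical_fdr([mk_seg(1.0)], [])


class TestSelectParameters:
    def test_single_point_grid(self, stats_grid):
        rng = np.random.default_rng(0)
        pos = {"chr1": np.sort(rng.integers(0, 10_000_000, size=60))}
        sims = [
            {"chr1": np.sort(rng.integers(0, 10_000_000, size=60))}
            for _ in range(3)
        ]
        params = select_parameters(pos, sims, stats_grid, gamma_grid=[5],
                                   kmin_grid=[4])
        assert params == PcfParams(gamma=5.0, kmin=4)

    def test_null_tie_break_lowest(self, stats_grid):
        # simulated sets identical to the observed one: every FDR is 1,
        # no hotspots anywhere, so ties resolve to lowest gamma then kmin
        rng = np.random.default_rng(1)
        pos = {"chr1": np.sort(rng.integers(0, 10_000_000, size=40))}
        sims = [pos, pos]
        params = select_parameters(
            pos, sims, stats_grid, gamma_grid=[3, 9], kmin_grid=[12, 15],
        )
        assert params.gamma == 3 and params.kmin == 12


def make_sv(id_, chrom, start, end, sample="S0"):
    return Rearrangement(id_, sample, Breakend(chrom, start, "+"),
                         Breakend(chrom, end, "-"))


class TestFilterCollapse:
    def test_threshold_and_merge(self):
        segs = [
            mk_seg(10.0, start=1000, end=5000),
            mk_seg(8.0, start=4000, end=9000),
            mk_seg(5.0, start=50_000, end=60_000),
        ]
        for s, f in zip(segs, (0.01, 0.02, 0.5)):
            s.fdr = f
        hs = filter_and_collapse(segs, sv_class="deletion")
        assert len(hs) == 1
        h = hs[0]
        assert (h.interval.start, h.interval.end) == (1000, 9001)
        assert h.fdr == 0.01 and h.beta_simple == 10.0

    def test_cna_support_filter(self):
        seg = mk_seg(10.0, start=1000, end=5000)
        seg.fdr = 0.001
        svs = [make_sv("a", "chr1", 2000, 3000)]
        no_support = {"S0": {"chr1": np.array([500_000])}}
        assert filter_and_collapse([seg], svs=svs,
                                   cn_boundaries_by_sample=no_support) == []
        support = {"S0": {"chr1": np.array([2500])}}
        out = filter_and_collapse([seg], svs=svs,
                                  cn_boundaries_by_sample=support)
        assert len(out) == 1 and out[0].cna_supported

    def test_sample_count(self):
        seg = mk_seg(10.0, start=1000, end=5000)
        seg.fdr = 0.001
        svs = [make_sv("a", "chr1", 2000, 3000, sample="S1"),
               make_sv("b", "chr1", 2500, 3500, sample="S2"),
               make_sv("c", "chr1", 900_000, 990_000, sample="S3")]
        out = filter_and_collapse([seg], svs=svs)
        assert out[0].n_samples == 2

    def test_focal_length_cutoff(self):
        from svcna.catalog import GeneModel

        seg = mk_seg(10.0, start=1_000_000, end=1_200_000)
        seg.fdr = 0.001
        genes = [GeneModel("G", "chr1", 1_000_000, 1_100_000, "+")]
        svs = [
            make_sv("short", "chr1", 1_050_000, 3_000_000, sample="S1"),
            make_sv("long", "chr1", 1_050_000, 5_100_000, sample="S2"),
        ]
        out = filter_and_collapse([seg], svs=svs, genes=genes, drivers={"G"})
        assert out[0].candidate_genes == ["G"]
        assert out[0].n_focal_samples == 1  # the 4-Mb SV is excluded


class TestFragile:
    def hotspot(self, genes=()):
        return Hotspot(Interval("chr1", 0, 1_000_000), "deletion", 5.0, 0.01,
                       20, candidate_genes=list(genes))

    def test_three_criteria_fragile(self):
        ann = FragileAnnotation(mean_replication_timing=-1.2, genes_per_mb=8,
                                largest_gene_length=400_000,
                                in_gene_flank_density_ratio=6.0)
        fragile, criteria = classify_fragile(self.hotspot(), ann)
        assert fragile and sum(criteria) == 3

    def test_two_criteria_not_fragile(self):
        ann = FragileAnnotation(mean_replication_timing=-1.2,
                                largest_gene_length=400_000)
        fragile, criteria = classify_fragile(self.hotspot(), ann)
        assert not fragile and sum(criteria) == 2

    def test_driver_exclusion(self):
        ann = FragileAnnotation(mean_replication_timing=-1.0, genes_per_mb=1,
                                largest_gene_length=500_000,
                                overlaps_known_fragile_list_1=True)
        fragile, criteria = classify_fragile(
            self.hotspot(["APC"]), ann, drivers_contained={"APC"}
        )
        assert sum(criteria) == 4 and not fragile

    def test_missing_annotation_unmet(self):
        fragile, criteria = classify_fragile(self.hotspot(), FragileAnnotation())
        assert not fragile and sum(criteria) == 0
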