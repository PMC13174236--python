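import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicrearr.breakpoints import BreakpointCall
from hicrearr.genome import GenomeLayout, toy_layout
from hicrearr.matrix import balance_sqrt_vc
from hicrearr.rearrange import (
    Assembly,
    CNVSegment,
    Segment,
    assembled_matrix,
    coverage_cnv,
    detect_neoloops,
    reconstruct_assembly,
    virtual_4c,
)
from hicrearr.simulate import (
    PlantedSV,
    SimulationConfig,
    default_config,
    simulate_hic,
)

from conftest import dense_to_matrix


class TestCoverageCNV:
    def test_uniform_coverage_single_segment(self):
        m = dense_to_matrix(np.ones((80, 80)), resolution=25_000)
        segs = coverage_cnv(m)
        assert len(segs) == 1
        assert segs[0].start == 0 and segs[0].end == 80 * 25_000
        assert abs(segs[0].ratio - 1.0) < 1e-6

    def test_all_zero_chromosome(self):
        m = dense_to_matrix(np.zeros((40, 40)), resolution=25_000)
        segs = coverage_cnv(m)
        assert len(segs) == 1 and segs[0].ratio == 0.0

    def test_planted_loss_recovered(self):
        # 0.5x over 100 bins at 25 kb; exhaustive-scan oracle for the best
        # single changepoint pair is the planted boundary itself
        cfg = default_config(seed=3, tads=(), loops=(),
                             cnvs=(("chr3", 2_000_000, 4_500_000, 0.5),))
        mats, _ = simulate_hic(cfg, resolutions=(25_000,))
        segs = [s for s in coverage_cnv(mats[25_000]) if s.chrom == "chr3"]
        loss = [s for s in segs if s.ratio < 0.75]
        assert len(loss) == 1
        assert abs(loss[0].start - 2_000_000) <= 25_000
        assert abs(loss[0].end - 4_500_000) <= 25_000
        assert abs(loss[0].ratio - 0.5) <= 0.1

    def test_focal_gain_resolution_limit(self):
        # 3x over 500 kb: resolved at 25 kb, but a 1-bin event at 500 kb is
        # below the minimum segment length (documented resolution limit)
        cfg = default_config(seed=4, tads=(), loops=(),
                             cnvs=(("chr4", 5_000_000, 5_500_000, 3.0),))
        mats, _ = simulate_hic(cfg, resolutions=(25_000, 500_000))
        fine = [s for s in coverage_cnv(mats[25_000])
                if s.chrom == "chr4" and s.ratio > 1.5]
        assert fine
        assert abs(fine[0].start - 5_000_000) <= 50_000
        coarse = [s for s in coverage_cnv(mats[500_000])
                  if s.chrom == "chr4"
                  and abs(s.start - 5_000_000) <= 500_000
                  and abs(s.end - 5_500_000) <= 500_000]
        assert not coarse

    def test_depth_invariance(self, default_sim):
        from hicrearr.matrix import ContactMatrix

        m = default_sim["mats"][25_000]
        m2 = ContactMatrix(m.bins, m.counts * 3, uvp=m.uvp * 3)
        r1 = [s.ratio for s in coverage_cnv(m)]
        r2 = [s.ratio for s in coverage_cnv(m2)]
        assert np.allclose(r1, r2)

    def test_segments_tile_chromosomes(self, default_sim):
        segs = coverage_cnv(default_sim["mats"][25_000])
        for chrom in default_sim["truth"].layout.names:
            mine = [s for s in segs if s.chrom == chrom]
            assert mine[0].start == 0
            assert mine[-1].end == default_sim["truth"].layout.length_of(chrom)
            for a, b in zip(mine, mine[1:]):
                assert a.end == b.start


LAYOUT = toy_layout()


class TestReconstructAssembly:
    def test_no_breakpoints_reference_window(self):
        asm = reconstruct_assembly([], LAYOUT, region=("chr2", 1_000_000, 3_000_000))
        assert asm.segments == [Segment("chr2", 1_000_000, 3_000_000, "forward")]

    def test_single_sv_two_forward_segments(self):
        call = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        asm = reconstruct_assembly([call], LAYOUT, flank=2_000_000)
        assert asm.segments == [
            Segment("chr1", 4_000_000, 6_000_000, "forward"),
            Segment("chr2", 3_000_000, 5_000_000, "forward"),
        ]
        # coordinate-arithmetic oracle, bin by bin at 10 kb
        for k in range(0, 2_000_000, 10_000):
            assert asm.to_reference(k) == ("chr1", 4_000_000 + k)
            assert asm.to_reference(2_000_000 + k) == ("chr2", 3_000_000 + k)
            assert asm.from_reference("chr1", 4_000_000 + k) == k

    def test_reverse_orientation_segments(self):
        call = BreakpointCall("chr1", 6_000_000, "-", "chr2", 3_000_000, "+")
        asm = reconstruct_assembly([call], LAYOUT, flank=1_000_000)
        assert asm.segments[0] == Segment("chr1", 6_000_000, 7_000_000, "reverse")
        assert asm.segments[1] == Segment("chr2", 2_000_000, 3_000_000, "reverse")
        # first assembly base is the far end of the reversed first segment
        assert asm.to_reference(0) == ("chr1", 6_999_999)

    def test_three_segment_chain(self):
        # two junctions sharing a middle segment on chr2
        c1 = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        c2 = BreakpointCall("chr2", 5_000_000, "+", "chr3", 7_000_000, "-")
        asm = reconstruct_assembly([c1, c2], LAYOUT, flank=1_500_000)
        assert [s.chrom for s in asm.segments] == ["chr1", "chr2", "chr3"]
        assert asm.segments[1] == Segment("chr2", 3_000_000, 5_000_000, "forward")

    def test_conflicting_chain_raises(self):
        c1 = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        c2 = BreakpointCall("chr2", 2_000_000, "+", "chr3", 7_000_000, "-")
        with pytest.raises(ValueError, match="junction"):
            reconstruct_assembly([c1, c2], LAYOUT)

    def test_breakend_reuse_raises(self):
        c = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        with pytest.raises(ValueError, match="reuse"):
            reconstruct_assembly([c, c], LAYOUT)

    def test_cnv_changepoint_bounds_flank(self):
        call = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        cnv = [CNVSegment("chr1", 0, 5_000_000, 1.0),
               CNVSegment("chr1", 5_000_000, 10_000_000, 2.0)]
        asm = reconstruct_assembly([call], LAYOUT, cnv=cnv, flank=4_000_000)
        assert asm.segments[0].start == 5_000_000

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(pos=st.integers(min_value=0, max_value=3_999_999))
    def test_map_round_trip_identity(self, pos):
        call = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "+")
        asm = reconstruct_assembly([call], LAYOUT, flank=2_000_000)
        chrom, ref = asm.to_reference(pos)
        assert asm.from_reference(chrom, ref) == pos


@pytest.fixture(scope="module")
def sv_sim():
    sv = PlantedSV("chr1", 6_000_000, "+", "chr2", 3_000_000, "-",
                   neo_loops=((5_500_000, 3_400_000, 8.0),))
    cfg = SimulationConfig(layout=LAYOUT, depth=4_000_000, svs=(sv,), seed=21)
    mats, truth = simulate_hic(cfg, resolutions=(10_000,))
    m = balance_sqrt_vc(mats[10_000])
    call = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
    asm = reconstruct_assembly([call], LAYOUT, flank=3_000_000)
    return m, asm, truth


class TestAssembledMatrix:
    def test_identity_assembly_identical(self, sv_sim):
        m, _, _ = sv_sim
        asm = reconstruct_assembly([], LAYOUT, region=("chr1", 0, 10_000_000))
        am = assembled_matrix(m, asm)
        direct = m.dense("chr1", balanced=False)
        got = am.matrix.dense("assembly", balanced=False)
        assert np.allclose(got, direct)

    def test_junction_continuity(self, sv_sim):
        m, asm, _ = sv_sim
        am = assembled_matrix(m, asm)
        blk = am.matrix.dense("assembly", balanced=True)
        n1 = 300  # bins in segment 1
        d = 20
        cross = np.nanmean([blk[n1 - 1 - k, n1 + d - k - 1] for k in range(1, d)])
        intra = np.nanmean(np.diagonal(blk, d))
        assert 0.5 <= cross / intra <= 2.0

    def test_reversed_segment_rows_reversed(self, sv_sim):
        m, _, _ = sv_sim
        asm = Assembly([Segment("chr1", 0, 1_000_000, "reverse")], [])
        am = assembled_matrix(m, asm)
        fwd = m.dense("chr1", balanced=False)[:100, :100]
        rev = am.matrix.dense("assembly", balanced=False)
        assert np.allclose(rev, fwd[::-1, ::-1])
        # map round-trip confirms the reversal
        assert am.assembly.to_reference(0) == ("chr1", 999_999)

    def test_map_outside_matrix_raises(self, sv_sim):
        m, _, _ = sv_sim
        asm = Assembly([Segment("chrX", 0, 1_000_000, "forward")], [])
        with pytest.raises(KeyError):
            assembled_matrix(m, asm)


class TestVirtual4C:
    def test_window_zero_is_row_over_uvp(self, toy3x3):
        m = toy3x3
        track = virtual_4c(m, 1, window=0, balanced=False)
        assert np.allclose(track.values, np.array([2, 6, 2]) / 8)

    def test_hand_example_window_one(self, toy3x3):
        track = virtual_4c(toy3x3, 1, window=1, balanced=False)
        assert np.allclose(track.values, np.array([2, 10 / 3, 2]) / 8)

    def test_joint_scaling_invariance(self, default_sim):
        from hicrearr.matrix import ContactMatrix

        m = default_sim["m10"]
        m2 = balance_sqrt_vc(ContactMatrix(m.bins, m.counts * 2, uvp=m.uvp * 2))
        t1 = virtual_4c(m, ("chr2", 2_000_000), window=1)
        t2 = virtual_4c(m2, ("chr2", 2_000_000), window=1)
        ok = np.isfinite(t1.values)
        assert np.allclose(t1.values[ok], t2.values[ok])

    def test_zero_coverage_viewpoint_all_missing(self):
        dense = np.ones((5, 5))
        dense[2, :] = 0
        dense[:, 2] = 0
        m = balance_sqrt_vc(dense_to_matrix(dense))
        track = virtual_4c(m, 2, window=0)
        assert np.isnan(track.values).all()

    def test_interval_viewpoint(self, default_sim):
        t = virtual_4c(default_sim["m10"], ("chr2", 2_000_000, 2_030_000), window=0)
        assert np.isfinite(t.values).sum() > 0


class TestDetectNeoloops:
    def test_planted_cross_junction_loop_recovered(self, sv_sim):
        m, asm, truth = sv_sim
        am = assembled_matrix(m, asm)
        calls = detect_neoloops(am)
        cross = [c for c in calls if c.crosses_junction]
        assert len(cross) >= 1
        hit = min(cross, key=lambda c: abs(c.ref_a[1] - 5_500_000))
        assert hit.ref_a == ("chr1", 5_500_000)
        assert hit.ref_b == ("chr2", 3_400_000)

    def test_intra_segment_loop_not_flagged(self):
        sv = PlantedSV("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        cfg = SimulationConfig(
            layout=LAYOUT, depth=4_000_000, svs=(sv,),
            loops=(("chr1", 4_000_000, 4_500_000, 8.0),), seed=23,
        )
        mats, _ = simulate_hic(cfg, resolutions=(10_000,))
        m = balance_sqrt_vc(mats[10_000])
        call = BreakpointCall("chr1", 6_000_000, "+", "chr2", 3_000_000, "-")
        asm = reconstruct_assembly([call], LAYOUT, flank=3_000_000)
        calls = detect_neoloops(assembled_matrix(m, asm))
        near = [
            c for c in calls
            if abs(c.ref_a[1] - 4_000_000) <= 20_000
            and abs(c.ref_b[1] - 4_500_000) <= 20_000
        ]
        assert near and not near[0].crosses_junction

    def test_reference_anchors_inside_segments(self, sv_sim):
        m, asm, _ = sv_sim
        calls = detect_neoloops(assembled_matrix(m, asm))
        for c in calls:
            seg_hit = any(
                s.chrom == c.ref_a[0] and s.start <= c.ref_a[1] < s.end
                for s in asm.segments
            )
            assert seg_hit
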