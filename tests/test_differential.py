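from itertools import combinations

import numpy as np
import pytest
from scipy.stats import hypergeom

from hicrearr.differential import (
    Sample,
    SampleGroup,
    benjamini_hochberg,
    binned_jaccard,
    compartment_pca,
    differential_compartments,
    differential_insulation,
    differential_presence,
    mann_whitney,
    track_correlation,
)
from hicrearr.genome import BinIndex, toy_layout
from hicrearr.simulate import SimTruth, default_config, synth_compartment_scores, synth_insulation_scores
from hicrearr.tracks import BinnedTrack


LAYOUT = toy_layout()
BINS100 = BinIndex(LAYOUT, 100_000)


def _track(values):
    return BinnedTrack(BINS100, np.asarray(values, dtype=float))


def _const_track(v):
    return _track(np.full(BINS100.n_bins, v))


class TestTrackCorrelation:
    def test_identical_tracks(self):
        rng = np.random.default_rng(0)
        t = _track(rng.normal(size=BINS100.n_bins))
        assert track_correlation(t, t) == pytest.approx(1.0)

    def test_negation(self):
        rng = np.random.default_rng(1)
        t = _track(rng.normal(size=BINS100.n_bins))
        neg = _track(-t.values)
        assert track_correlation(t, neg) == pytest.approx(-1.0)

    def test_toy_closed_form(self):
        # 5-bin pair against the hand-computed covariance ratio
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        vx = np.full(BINS100.n_bins, np.nan)
        vy = np.full(BINS100.n_bins, np.nan)
        vx[:5], vy[:5] = x, y
        expected = np.sum((x - 3) * (y - 3)) / np.sqrt(
            np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2)
        )
        assert track_correlation(_track(vx), _track(vy)) == pytest.approx(expected)

    def test_constant_input_undefined(self):
        r = track_correlation(_const_track(2.0), _const_track(3.0))
        assert np.isnan(r)

    def test_mask_applied(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=BINS100.n_bins)
        b = a.copy()
        b[:50] = -b[:50]  # disagreement only on chr1 start
        r_raw = track_correlation(_track(a), _track(b))
        r_masked = track_correlation(_track(a), _track(b),
                                     mask=[("chr1", 0, 5_000_000)])
        assert r_masked == pytest.approx(1.0) and r_raw < 1.0


class TestBinnedJaccard:
    def test_identical_sets(self):
        feats = [("chr1", 100_000), ("chr2", 5_000_000)]
        assert binned_jaccard(feats, feats, LAYOUT) == 1.0

    def test_partial_overlap_thirds(self):
        a = [("chr1", 10_000), ("chr1", 60_000)]   # 50 kb bins 0 and 1
        b = [("chr1", 60_000), ("chr1", 110_000)]  # bins 1 and 2
        assert binned_jaccard(a, b, LAYOUT) == pytest.approx(1 / 3)

    def test_disjoint_and_empty(self):
        a = [("chr1", 10_000)]
        b = [("chr2", 10_000)]
        assert binned_jaccard(a, b, LAYOUT) == 0.0
        assert binned_jaccard([], [], LAYOUT) == 1.0


class TestExactStatistics:
    def test_mann_whitney_exact_example(self):
        p = mann_whitney([0.5, 0.6, 0.7], [-0.5, -0.4, -0.3])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_exhaustive_enumeration_agreement(self):
        # independent oracle: enumerate all label assignments, symmetric
        # two-sided tail of the exact null U distribution
        rng = np.random.default_rng(3)
        for n1 in range(2, 5):
            for n2 in range(2, 5):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                pooled = np.concatenate([x, y])
                u_obs = sum(
                    1 for xi in x for yj in y if xi > yj
                ) + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
                us = []
                for idx in combinations(range(n1 + n2), n1):
                    xs = pooled[list(idx)]
                    ys = np.delete(pooled, list(idx))
                    us.append(sum(1 for a in xs for b in ys if a > b))
                us = np.array(us)
                lo = min(u_obs, n1 * n2 - u_obs)
                hi = max(u_obs, n1 * n2 - u_obs)
                p_oracle = np.mean((us <= lo) | (us >= hi))
                assert mann_whitney(x, y) == pytest.approx(p_oracle)

    def test_bh_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_bh_monotone_and_dominates(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _group(label, tracks, uvp=20_000_000, ins=None, boundaries=(), loops=()):
    return SampleGroup(
        label,
        [
            Sample(f"{label}{k}", t, None if ins is None else ins[k],
                   list(boundaries), list(loops), uvp=uvp)
            for k, t in enumerate(tracks)
        ],
    )


class TestDifferentialCompartments:
    def test_identical_groups_empty_test_set(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0.5, 0.01, BINS100.n_bins)
        a = _group("A", [_track(base)] * 3)
        b = _group("B", [_track(base)] * 3)
        out = differential_compartments(a, b)
        assert len(out) == 0

    def test_planted_flip_recovered(self):
        truth = SimTruth(default_config(seed=0))
        flip = (("chr2", 1_000_000, 2_000_000),)
        a = _group("A", synth_compartment_scores(truth, 4, seed=1))
        b = _group("B", synth_compartment_scores(truth, 4, flip_intervals=flip, seed=2))
        out = differential_compartments(a, b)
        sig = out[out["significant"]]
        assert len(sig) == 10
        assert set(sig["chrom"]) == {"chr2"}
        assert sig["start"].min() == 1_000_000 and sig["end"].max() == 2_000_000

    def test_group_below_minimum_raises(self):
        t = [_const_track(0.5)] * 2
        with pytest.raises(ValueError, match="included members"):
            differential_compartments(_group("A", t), _group("B", t))

    def test_uvp_filter_excludes_members(self):
        truth = SimTruth(default_config(seed=0))
        tracks = synth_compartment_scores(truth, 4, seed=3)
        a = _group("A", tracks, uvp=5_000_000)  # all below threshold
        b = _group("B", tracks)
        with pytest.raises(ValueError):
            differential_compartments(a, b)


class TestDifferentialInsulation:
    def _groups(self, shift):
        truth = SimTruth(default_config(seed=0))
        ins_a = synth_insulation_scores(truth, 6, seed=1)
        ins_b = synth_insulation_scores(
            truth, 6, shift_intervals=shift, seed=2
        )
        a = _group("A", [_const_track(0)] * 6, ins=ins_a)
        b = _group("B", [_const_track(0)] * 6, ins=ins_b)
        return a, b

    def test_identical_groups_p_near_one(self):
        truth = SimTruth(default_config(seed=0))
        ins = synth_insulation_scores(truth, 4, noise_sd=0.0, seed=1)
        a = _group("A", [_const_track(0)] * 4, ins=ins)
        b = _group("B", [_const_track(0)] * 4, ins=ins)
        out = differential_insulation(a, b, [("chr1", 2_800_000)])
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_shift_detected_elsewhere_null(self):
        shift = (("chr1", 2_780_000, 2_830_000, -0.8),)
        a, b = self._groups(shift)
        out = differential_insulation(
            a, b, [("chr1", 2_800_000), ("chr3", 5_500_000)]
        )
        assert bool(out[out["pos"] == 2_800_000]["significant"].iloc[0])
        assert not bool(out[out["pos"] == 5_500_000]["significant"].iloc[0])

    def test_group_swap_symmetry(self):
        shift = (("chr1", 2_780_000, 2_830_000, -0.8),)
        a, b = self._groups(shift)
        p1 = differential_insulation(a, b, [("chr1", 2_800_000)])["p"].iloc[0]
        p2 = differential_insulation(b, a, [("chr1", 2_800_000)])["p"].iloc[0]
        assert p1 == pytest.approx(p2)


class TestDifferentialPresence:
    def test_three_vs_zero_fisher_example(self):
        # hypergeometric enumeration over C(6,3) = 20 arrangements gives 0.1
        bdry = [("chr1", 500_000)]
        a = _group("A", [_const_track(0.5)] * 3, boundaries=bdry)
        b = _group("B", [_const_track(0.5)] * 3, boundaries=[])
        out = differential_presence(a, b, feature="boundary")
        assert len(out) == 1
        assert out["p"].iloc[0] == pytest.approx(0.1)
        assert out["p"].iloc[0] == pytest.approx(
            hypergeom.pmf(3, 6, 3, 3) * 2
        )

    def test_identical_patterns_p_one(self):
        bdry = [("chr1", 500_000), ("chr2", 700_000)]
        a = _group("A", [_const_track(0.5)] * 3, boundaries=bdry)
        b = _group("B", [_const_track(0.5)] * 3, boundaries=bdry)
        out = differential_presence(a, b, feature="boundary")
        assert (out["p"] == 1.0).all()

    def test_uvp_excluded_sample_not_in_margins(self):
        bdry = [("chr1", 500_000)]
        a = SampleGroup("A", [
            Sample("a1", _const_track(0.5), None, bdry, [], uvp=20_000_000),
            Sample("a2", _const_track(0.5), None, bdry, [], uvp=1_000_000),
        ])
        b = _group("B", [_const_track(0.5)] * 2, boundaries=[])
        out = differential_presence(a, b, feature="boundary")
        assert out["nA"].iloc[0] == 1

    def test_loop_anchor_bins_at_50kb(self):
        loops = [("chr1", 500_000, 1_200_000)]
        a = _group("A", [_const_track(0.5)] * 3, loops=loops)
        b = _group("B", [_const_track(0.5)] * 3, loops=[])
        out = differential_presence(a, b, feature="loop-anchor")
        assert len(out) == 2  # both anchors, in 50 kb bins
        assert set(out["start"]) == {500_000, 1_200_000}


class TestCompartmentPCA:
    def test_duplicated_sample_identical_coordinates(self):
        truth = SimTruth(default_config(seed=0))
        tracks = synth_compartment_scores(truth, 3, seed=7)
        coords, var = compartment_pca([tracks[0], tracks[0], tracks[1], tracks[2]])
        assert np.allclose(coords[0], coords[1])
        assert var.sum() <= 1.0 + 1e-9

    def test_two_groups_separate_on_pc1(self):
        truth = SimTruth(default_config(seed=0))
        flip = (("chr1", 0, 3_000_000),)
        a = synth_compartment_scores(truth, 4, seed=1)
        b = synth_compartment_scores(truth, 4, flip_intervals=flip, seed=2)
        coords, _ = compartment_pca(a + b)
        ga, gb = coords[:4, 0], coords[4:, 0]
        assert max(ga) < min(gb) or min(ga) > max(gb)
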