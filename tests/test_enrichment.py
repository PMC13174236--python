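import numpy as np
import pytest
from scipy.stats import binom

from hicrearr.enrichment import (
    anchor_track_signal,
    apa,
    compartment_pair_enrichment,
    loop_convergence,
    motif_enrichment,
)
from hicrearr.simulate import synth_tracks
from hicrearr.topology import compartment_scores
from hicrearr.tracks import BinnedTrack

from conftest import dense_to_matrix


class TestMotifEnrichment:
    def test_motif_within_window_counts_as_hit(self, layout):
        motifs = [("chr1", 1_010_000, 1_010_020, "m", 0, "+")]
        res = motif_enrichment([("chr1", 1_000_000)], motifs, layout,
                               window=25_000, replicates=10, seed=0)
        assert res.observed == 1.0

    def test_no_motifs_observed_zero_p_one(self, layout):
        res = motif_enrichment([("chr1", 1_000_000)], [], layout,
                               replicates=50, seed=0)
        assert res.observed == 0.0
        assert res.p == 1.0

    def test_zero_features_undefined(self, layout):
        res = motif_enrichment([], [("chr1", 5, 25, "m", 0, "+")], layout)
        assert np.isnan(res.observed) and res.n_features == 0

    def test_planted_boundary_motifs_enriched(self, default_sim, layout):
        truth = default_sim["truth"]
        motifs = default_sim["motifs"]
        feats = list(truth.tad_internal_boundaries)
        res = motif_enrichment(feats, motifs, layout, window=25_000,
                               replicates=1000, seed=1)
        assert res.observed > 0.8
        assert res.p <= 0.05
        # independent binomial/hypergeometric-style oracle on binned space:
        # probability that one random position lies within the window of any
        # motif on its chromosome
        n = len(feats)
        covered = {}
        for c, s, e, *_ in motifs:
            covered.setdefault(c, 0)
            covered[c] += (e - s) + 50_000
        qs = [min(1.0, covered.get(c, 0) / layout.length_of(c)) for c, _ in feats]
        p_binom = float(np.prod(qs))  # P(all n random features hit)
        assert p_binom < 0.05  # both routes call the enrichment significant

    def test_reproducible_under_seed(self, default_sim, layout):
        feats = list(default_sim["truth"].tad_internal_boundaries)
        a = motif_enrichment(feats, default_sim["motifs"], layout,
                             replicates=200, seed=5)
        b = motif_enrichment(feats, default_sim["motifs"], layout,
                             replicates=200, seed=5)
        assert np.array_equal(a.replicates, b.replicates) and a.p == b.p

    def test_mask_excluded_from_randomization(self, layout):
        # mask everything except one interval: all random draws land there
        mask = [("chr1", 0, 4_000_000), ("chr1", 5_000_000, 10_000_000)]
        motifs = [("chr1", 4_500_000, 4_500_020, "m", 0, "+")]
        res = motif_enrichment([("chr1", 4_400_000)], motifs, layout,
                               window=600_000, replicates=100, mask=mask, seed=0)
        assert res.replicates.mean() == 1.0


class TestLoopConvergence:
    MOTIFS = [
        ("chr1", 1_000_000, 1_000_020, "m", 0, "+"),
        ("chr1", 2_000_000, 2_000_020, "m", 0, "-"),
        ("chr1", 3_000_000, 3_000_020, "m", 0, "+"),
        ("chr1", 4_000_000, 4_000_020, "m", 0, "+"),
    ]

    def test_convergent_pair(self):
        out = loop_convergence([("chr1", 1_000_000, 2_000_000)], self.MOTIFS)
        assert out == {
            "n_loops": 1, "any_anchor": 1.0, "each_anchor": 1.0,
            "convergent_of_each": 1.0,
        }

    def test_same_strand_counts_each_but_not_convergent(self):
        out = loop_convergence([("chr1", 3_000_000, 4_000_000)], self.MOTIFS)
        assert out["each_anchor"] == 1.0
        assert out["convergent_of_each"] == 0.0

    def test_planted_convergence_vs_strand_shuffle(self, default_sim):
        truth = default_sim["truth"]
        motifs = default_sim["motifs"]
        loops = [(c, a, b) for c, a, b, _ in truth.loops]
        out = loop_convergence(loops, motifs)
        assert out["convergent_of_each"] >= 0.8
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(50):
            shuffled = [
                (c, s, e, n, sc, rng.choice(["+", "-"]))
                for c, s, e, n, sc, _ in motifs
            ]
            fracs.append(loop_convergence(loops, shuffled)["convergent_of_each"])
        assert abs(np.nanmean(fracs) - 0.25) < 0.15


class TestAPA:
    def test_close_pairs_excluded_error(self, default_sim):
        with pytest.raises(ValueError, match="no qualifying"):
            apa(default_sim["m10"], [("chr1", 2_000_000, 2_250_000)])

    def test_single_pair_equals_window(self, default_sim):
        m = default_sim["m10"]
        agg, _ = apa(m, [("chr2", 2_000_000, 2_500_000)], oe=False)
        w = m.require_weights()
        sym = m.symmetric()
        lo, _ = m.bins.chrom_span("chr2")
        ba, bb = lo + 200, lo + 250
        rows = np.arange(ba - 10, ba + 11)
        cols = np.arange(bb - 10, bb + 11)
        win = np.asarray(sym[rows][:, cols].todense())
        win = win * w[rows, None] * w[None, cols] / m.uvp
        assert np.allclose(agg, win, equal_nan=True)

    def test_planted_loops_vs_shuffled_anchors(self, default_sim):
        m = default_sim["m10"]
        truth = default_sim["truth"]
        _, score = apa(m, [(c, a, b) for c, a, b, _ in truth.loops])
        assert score > 2
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(30):
            a = int(rng.integers(1_000_000, 8_000_000))
            pairs.append(("chr3", a, a + int(rng.integers(400_000, 1_800_000))))
        _, null_score = apa(m, pairs)
        assert abs(null_score - 1) <= 0.3


class TestAnchorTrackSignal:
    def test_zero_and_constant_tracks(self, default_sim):
        bins = default_sim["h3k27ac"].bins
        zero = BinnedTrack(bins, np.zeros(bins.n_bins))
        four = BinnedTrack(bins, np.full(bins.n_bins, 4.0))
        anchors = [("chr1", 2_000_000), ("chr2", 5_000_000)]
        _, mz = anchor_track_signal(anchors, zero)
        per, mf = anchor_track_signal(anchors, four)
        assert mz == 0.0 and mf == 4.0 and np.allclose(per, 4.0)

    def test_end_margin_exclusion(self, default_sim):
        four = BinnedTrack(default_sim["h3k27ac"].bins,
                           np.full(default_sim["h3k27ac"].bins.n_bins, 4.0))
        per, _ = anchor_track_signal(
            [("chr1", 50_000), ("chr1", 2_000_000)], four
        )
        assert len(per) == 1

    def test_all_excluded_warns_nan(self, default_sim):
        four = BinnedTrack(default_sim["h3k27ac"].bins,
                           np.full(default_sim["h3k27ac"].bins.n_bins, 4.0))
        per, mean = anchor_track_signal([("chr1", 10_000)], four)
        assert len(per) == 0 and np.isnan(mean)


@pytest.fixture(scope="module")
def profile(default_sim):
    return compartment_scores(
        default_sim["m100"],
        h3k27ac=default_sim["h3k27ac"],
        mask_intervals=default_sim["truth"].mask_intervals,
    )


class TestCompartmentPairEnrichment:

    def test_positive_scores_labeled_aa(self, profile, default_sim):
        labels = default_sim["truth"].compartment_labels(100_000)
        bins = labels.bins
        a_bins = [
            b for b in range(bins.n_bins)
            if labels.values[b] > 0.5 and np.isfinite(profile.track.values[b])
            and profile.track.values[b] > 0
        ][:4]
        iv = [bins.bin_interval(b) for b in a_bins]
        pairs = [(iv[0][0], iv[0][1], iv[1][0], iv[1][1]),
                 (iv[2][0], iv[2][1], iv[3][0], iv[3][1])]
        res, states = compartment_pair_enrichment(pairs, profile,
                                                  replicates=50, seed=0)
        assert states["AA"] == 2 and res.observed == 1.0

    def test_all_a_profile_ratio_one(self, default_sim):
        bins = default_sim["m100"].bins
        prof = compartment_scores(default_sim["m100"])
        prof.track.values[:] = 0.5  # force all-A
        pairs = [("chr1", 1_000_000, "chr2", 2_000_000)]
        res, _ = compartment_pair_enrichment(pairs, prof, replicates=50, seed=0)
        assert res.observed == 1.0 and np.all(res.replicates == 1.0)

    def test_aa_planted_pairs_enriched_vs_random(self, profile, default_sim):
        labels = default_sim["truth"].compartment_labels(100_000)
        bins = labels.bins
        rng = np.random.default_rng(2)
        pairs = []
        # planted neo-loop-like anchors exclusively in A-label bins
        for _ in range(30):
            ca, cb = "chr1", "chr2"
            while True:
                pa = int(rng.integers(0, 10_000_000))
                if labels.values[bins.bin_id(ca, pa)] > 0.5:
                    break
            while True:
                pb = int(rng.integers(0, 10_000_000))
                if labels.values[bins.bin_id(cb, pb)] > 0.5:
                    break
            pairs.append((ca, pa, cb, pb))
        res, states = compartment_pair_enrichment(pairs, profile,
                                                  replicates=500, seed=3)
        assert res.observed > np.mean(res.replicates)
        assert res.p <= 0.05

    def test_masked_anchor_dropped(self, profile):
        pairs = [("chr3", 5_100_000, "chr1", 1_000_000)]  # first anchor masked
        _, states = compartment_pair_enrichment(pairs, profile,
                                                replicates=10, seed=0)
        assert states["dropped"] == 1
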