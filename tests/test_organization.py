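"""Co-occupancy, composite profiles, cross-link estimation, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exoorg import organization as org
from exoorg import simdata
from exoorg.io_formats import TagTrack
from exoorg.simdata import revcomp

from conftest import make_track


def anchor(point, strand="+", chrom="c"):
    return pd.DataFrame({"chrom": [chrom], "point": [point],
                         "strand": [strand]})


class TestClassifyCooccupancy:
    def _locs(self, mids):
        return pd.DataFrame({"chrom": "c", "midpoint": mids})

    def test_within_forty_is_cobound(self):
        res = org.classify_cooccupancy(self._locs([100]), self._locs([135]))
        assert res.venn_counts == {"cobound": 1, "first_only": 0,
                                   "second_only": 0}

    def test_beyond_forty_both_factor_only(self):
        res = org.classify_cooccupancy(self._locs([100]), self._locs([141]))
        assert res.venn_counts == {"cobound": 0, "first_only": 1,
                                   "second_only": 1}

    def test_boundary_inclusive(self):
        res = org.classify_cooccupancy(self._locs([100]), self._locs([140]))
        assert len(res.cobound) == 1

    def test_empty_second_list_all_first_only(self):
        res = org.classify_cooccupancy(self._locs([100, 200]), self._locs([]))
        assert res.venn_counts == {"cobound": 0, "first_only": 2,
                                   "second_only": 0}

    def test_one_to_one_nearest_first(self):
        # one TAL1 between two GATA1: matches the nearer one only
        res = org.classify_cooccupancy(self._locs([100, 160]),
                                       self._locs([130]))
        assert len(res.cobound) == 1
        assert res.cobound.iloc[0].first_midpoint == 100
        assert list(res.first_only.midpoint) == [160]


class TestCompositeProfile:
    def test_plus_anchor_direct_placement(self):
        track = make_track([("+", 986)])
        prof = org.composite_profile(track, anchor(1000, "+"),
                                     flank=50, smooth=1)
        assert prof.plus_density[prof.offsets.tolist().index(-14)] == 1.0
        assert prof.plus_density.sum() == 1.0
        assert prof.minus_density.sum() == 0.0

    def test_minus_anchor_flips_offset_and_strand(self):
        track = make_track([("+", 986)])
        prof = org.composite_profile(track, anchor(1000, "-"),
                                     flank=50, smooth=1)
        assert prof.minus_density[prof.offsets.tolist().index(14)] == 1.0
        assert prof.plus_density.sum() == 0.0

    def test_no_tags_all_zero(self):
        track = TagTrack({"c": 2000})
        prof = org.composite_profile(track, anchor(1000), flank=50)
        assert not prof.plus_density.any() and not prof.minus_density.any()

    def test_densities_normalized_per_anchor(self):
        track = make_track([("+", 100), ("+", 300)])
        anchors = pd.DataFrame({"chrom": "c", "point": [100, 300],
                                "strand": "+"})
        prof = org.composite_profile(track, anchors, flank=10, smooth=1)
        assert prof.plus_density[10] == 1.0  # 2 tags / 2 anchors at offset 0

    def test_reverse_complement_equivariance(self, sim_genome_truth,
                                             gata_exo_track, anchors):
        """Mirroring the whole dataset reproduces the composite profile."""
        genome, _ = sim_genome_truth
        L = len(next(iter(genome.values())))
        track = gata_exo_track
        mirrored = TagTrack({"chrSim": L})
        for strand, flip in (("+", "-"), ("-", "+")):
            pos, cnt = track.positions_counts("chrSim", strand)
            for p, c in zip(pos, cnt):
                mirrored.add("chrSim", flip, L - 1 - int(p), int(c))
        flipped_anchors = anchors.copy()
        flipped_anchors["point"] = L - 1 - flipped_anchors["point"]
        flipped_anchors["strand"] = np.where(
            flipped_anchors["strand"] == "+", "-", "+")
        a = org.composite_profile(track, anchors, flank=60, smooth=5)
        b = org.composite_profile(mirrored, flipped_anchors, flank=60,
                                  smooth=5)
        np.testing.assert_allclose(a.plus_density, b.plus_density, atol=1e-12)
        np.testing.assert_allclose(a.minus_density, b.minus_density,
                                   atol=1e-12)


class TestEstimateCrosslinks:
    def _profile(self, plus_peaks, minus_peaks, flank=40):
        n = 2 * flank + 1
        plus = np.zeros(n)
        minus = np.zeros(n)
        for off, h in plus_peaks:
            plus[off + flank] = h
        for off, h in minus_peaks:
            minus[off + flank] = h
        # light smoothing so maxima are well-defined plateaus of width 1
        return org.CompositeProfile(np.arange(-flank, flank + 1),
                                    plus, minus, 1, 3)

    def test_symmetric_pair_gives_zero_offset(self):
        prof = self._profile([(-6, 1.0)], [(6, 1.0)])
        (est,) = org.estimate_crosslinks(prof, max_pairs=1)
        assert est.offset == 0.0 and est.separation == 12

    def test_minus_fourteen_minus_two_gives_minus_eight(self):
        prof = self._profile([(-14, 1.0)], [(-2, 1.0)])
        (est,) = org.estimate_crosslinks(prof, max_pairs=1)
        assert est.offset == -8.0

    def test_two_pairs_sixteen_apart(self):
        prof = self._profile([(-14, 0.75), (2, 0.25)],
                             [(-2, 0.75), (14, 0.25)])
        ests = org.estimate_crosslinks(prof, max_pairs=2)
        assert len(ests) == 2
        offsets = sorted(e.offset for e in ests)
        assert offsets == [-8.0, 8.0]
        assert offsets[1] - offsets[0] == 16.0
        # major (higher-intensity) estimate is the -8 pair
        assert ests[0].offset == -8.0

    def test_no_pairable_maxima_empty(self):
        prof = self._profile([(-30, 1.0)], [(30, 1.0)])  # separation 60
        assert org.estimate_crosslinks(prof) == []

    def test_recovers_simulated_gata_geometry(self, gata_exo_track, anchors):
        prof = org.composite_profile(gata_exo_track, anchors, flank=60,
                                     smooth=5)
        ests = org.estimate_crosslinks(prof, max_pairs=2)
        assert len(ests) == 2
        offsets = sorted(e.offset for e in ests)
        assert abs(offsets[0] - (-8)) <= 1 and abs(offsets[1] - 8) <= 1

    def test_recovers_simulated_tal_geometry(self, tal_exo_track,
                                             sim_genome_truth):
        _, truth = sim_genome_truth
        cobound = truth[truth.site_class == "cobound"]
        anchors = cobound.rename(columns={"ref_point": "point",
                                          "motif_strand": "strand"})
        prof = org.composite_profile(tal_exo_track, anchors, flank=60,
                                     smooth=5)
        ests = org.estimate_crosslinks(prof, max_pairs=2)
        offsets = sorted(e.offset for e in ests)
        assert abs(offsets[0] - (-21)) <= 1 and abs(offsets[1] - (-13)) <= 1


class TestOccupancyTable:
    def test_gata_window_boundaries(self):
        track = make_track([("+", 980), ("+", 970)])  # offsets -20, -30
        table = org.occupancy_table({"GATA1": track}, anchor(1000))
        assert table["GATA1"].iloc[0] == 1

    def test_tal_window_is_asymmetric(self):
        track = make_track([("+", 965), ("-", 1028), ("-", 1032)],
                           length=2000)
        table = org.occupancy_table({"TAL1": track}, anchor(1000))
        # offsets -35 and +28 are inside (-40, +30); +32 is out
        assert table["TAL1"].iloc[0] == 2

    def test_minus_anchor_orients_window(self):
        # upstream on a minus-strand motif is to the genomic right
        track = make_track([("+", 1035)], length=2000)
        table = org.occupancy_table({"TAL1": track}, anchor(1000, "-"))
        assert table["TAL1"].iloc[0] == 1
        table = org.occupancy_table({"TAL1": track}, anchor(1000, "+"))
        assert table["TAL1"].iloc[0] == 0

    def test_no_tags_zero(self):
        track = TagTrack({"c": 2000})
        table = org.occupancy_table({"GATA1": track}, anchor(1000))
        assert table["GATA1"].iloc[0] == 0

    def test_shared_strength_gives_positive_spearman(self, sim_genome_truth,
                                                     gata_exo_track,
                                                     tal_exo_track):
        _, truth = sim_genome_truth
        cobound = truth[truth.site_class == "cobound"]
        anchors = cobound.rename(columns={"ref_point": "point",
                                          "motif_strand": "strand"})
        table = org.occupancy_table(
            {"GATA1": gata_exo_track, "TAL1": tal_exo_track}, anchors)
        rho = stats.spearmanr(table["GATA1"], table["TAL1"]).statistic
        assert rho > 0.3

    def test_independent_occupancies_give_near_zero_spearman(
            self, sim_genome_truth):
        genome, truth = sim_genome_truth
        cobound = truth[truth.site_class == "cobound"].copy()
        rng = np.random.default_rng(42)
        shuffled = cobound.copy()
        shuffled["occ_TAL1"] = rng.permutation(shuffled["occ_TAL1"].to_numpy())
        tal = simdata.simulate_exo_tags(genome, shuffled,
                                        simdata.tal1_model(), 50, seed=43)
        gata = simdata.simulate_exo_tags(genome, cobound,
                                         simdata.gata1_model(), 50, seed=44)
        anchors = cobound.rename(columns={"ref_point": "point",
                                          "motif_strand": "strand"})
        table = org.occupancy_table({"GATA1": gata, "TAL1": tal}, anchors)
        rho = stats.spearmanr(table["GATA1"], table["TAL1"]).statistic
        assert abs(rho) < 0.2


class TestHeatmapMatrix:
    def test_rows_sorted_descending_by_occupancy(self):
        track = make_track([("+", 100)] * 5 + [("+", 300)] * 9 +
                           [("+", 500)] * 1, length=1000)
        anchors = pd.DataFrame({"chrom": "c", "point": [100, 300, 500],
                                "strand": "+"})
        res = org.heatmap_matrix(track, anchors, flank=20)
        assert list(res.order) == [1, 0, 2]
        assert list(res.sort_keys) == [9, 5, 1]

    def test_sense1_counts_only_plus_tags_upstream(self):
        track = make_track([("+", 990), ("-", 990), ("+", 1010)],
                           length=2000)
        res = org.heatmap_matrix(track, anchor(1000), flank=30,
                                 sort_key="sense1")
        assert res.sort_keys[0] == 1  # only the plus tag at offset -10

    def test_ties_keep_coordinate_order(self):
        track = make_track([("+", 100), ("+", 300)], length=1000)
        anchors = pd.DataFrame({"chrom": "c", "point": [100, 300],
                                "strand": "+"})
        res = org.heatmap_matrix(track, anchors, flank=20)
        assert list(res.order) == [0, 1]

    def test_unknown_sort_key_lists_options(self):
        track = make_track([("+", 100)])
        with pytest.raises(ValueError, match="sense1"):
            org.heatmap_matrix(track, anchor(100), sort_key="bogus")


class TestSequenceComposition:
    def test_consensus_anchor_base_frequency_one(self, sim_genome_truth):
        genome, truth = sim_genome_truth
        wg = truth[truth.site_class != "tal_only"]
        anchors = wg.rename(columns={"ref_point": "point",
                                     "motif_strand": "strand"})
        tab = org.sequence_composition(anchors, genome, window=(-18, 3))
        # offset 0 is the reference A; -1..-4 spell GATA backwards
        assert tab.loc[0, "A"] == 1.0
        assert tab.loc[-1, "T"] == 1.0
        assert tab.loc[-2, "A"] == 1.0
        assert tab.loc[-3, "G"] == 1.0
        assert tab.loc[1, "A"] == 1.0

    def test_random_anchors_near_uniform(self, rng):
        genome = simdata.generate_genome(50_000, 0.5, seed=31, chrom="c")
        points = rng.integers(100, 49_900, 400)
        anchors = pd.DataFrame({"chrom": "c", "point": points, "strand": "+"})
        tab = org.sequence_composition(anchors, genome, window=(-10, 10))
        assert np.all(np.abs(tab.to_numpy() - 0.25) < 0.1)

    def test_edge_anchor_skipped(self):
        genome = {"c": "ACGT" * 10}
        anchors = pd.DataFrame({"chrom": "c", "point": [2], "strand": "+"})
        tab = org.sequence_composition(anchors, genome, window=(-18, 3))
        assert tab.attrs["n_skipped"] == 1

    def test_four_color_matrix_codes(self):
        genome = {"c": "A" * 30 + "ACGT" + "A" * 30}
        anchors = pd.DataFrame({"chrom": "c", "point": [30], "strand": "+"})
        mat = org.four_color_matrix(anchors, genome, flank=3)
        assert list(mat[0]) == [0, 0, 0, 0, 1, 2, 3]


def brute_force_clusters(midpoints, max_gap=500):
    """Independent oracle: transitive closure over all pairs < max_gap."""
    n = len(midpoints)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(midpoints[i] - midpoints[j]) < max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = sorted(tuple(sorted(g)) for g in groups.values() if len(g) > 1)
    single = sorted(i for g in groups.values() if len(g) == 1 for i in g)
    return clusters, single


class TestFindClusters:
    def _locs(self, mids):
        return pd.DataFrame({"chrom": "c", "midpoint": mids})

    def test_pair_cluster_and_noncluster(self):
        res = org.find_clusters(self._locs([1000, 1400, 5000]))
        assert len(res.clusters) == 1
        assert res.clusters[0].coordinate == 1200
        assert sorted(res.clusters[0].member_ids) == [0, 1]
        assert res.noncluster_ids == [2]

    def test_chain_forms_single_cluster_with_median(self):
        res = org.find_clusters(self._locs([0, 400, 800]))
        assert len(res.clusters) == 1
        assert res.clusters[0].coordinate == 400
        assert res.frac_clustered == 1.0

    def test_all_gaps_at_or_over_500_noncluster(self):
        res = org.find_clusters(self._locs([0, 500, 1000]))
        assert res.clusters == [] and res.noncluster_ids == [0, 1, 2]

    def test_even_cluster_median_is_rounded_central_mean(self):
        res = org.find_clusters(self._locs([100, 200, 300, 401]))
        assert res.clusters[0].coordinate == 250  # round((200+300)/2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            mids = sorted(int(m) for m in rng.integers(0, 200_000, 200))
            res = org.find_clusters(self._locs(mids))
            ours = (sorted(tuple(sorted(c.member_ids)) for c in res.clusters),
                    res.noncluster_ids)
            # brute force on sorted points: transitive adjacency = chaining
            assert ours == brute_force_clusters(mids)


class TestExpressionByCluster:
    def test_nearest_tss_assignment(self):
        tss = pd.DataFrame({"gene": ["g1", "g2"], "chrom": "c",
                            "tss": [800, 2000]})
        assert org.nearest_tss_gene("c", 1000, tss) == "g1"

    def test_identical_groups_give_high_p(self, rng):
        locs = pd.DataFrame({"chrom": "c",
                             "midpoint": [100, 200, 5000, 10_000, 15_000,
                                          20_000]})
        cluster_set = org.find_clusters(locs)
        tss = pd.DataFrame({"gene": [f"g{i}" for i in range(6)],
                            "chrom": "c",
                            "tss": [150, 160, 5000, 10_000, 15_000, 20_000]})
        expr = pd.DataFrame({"gene": [f"g{i}" for i in range(6)],
                             "log2fc": [1.0] * 6})
        res = org.expression_by_cluster(cluster_set, locs, tss, expr)
        assert res.p_value > 0.9

    def test_cobound_cluster_effect_detected_with_power(self,
                                                        sim_genome_truth):
        """With a 2-log2FC effect at cobound-nearest genes the Mann-Whitney
        test should reject in >= 95% of seeded replicates."""
        genome, truth = sim_genome_truth
        cobound = truth[truth.site_class == "cobound"]
        other = truth[truth.site_class != "cobound"]
        # clusters around cobound sites, nonclusters at the others
        rows = []
        for _, s in cobound.iterrows():
            rows.append({"chrom": s.chrom, "midpoint": s.ref_point - 50})
            rows.append({"chrom": s.chrom, "midpoint": s.ref_point + 50})
        for _, s in other.iterrows():
            rows.append({"chrom": s.chrom, "midpoint": s.ref_point})
        locs = pd.DataFrame(rows)
        cluster_set = org.find_clusters(locs)
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            tss, expr = simdata.simulate_annotation(
                genome, truth, n_genes=200, effect_log2fc_cobound=2.0,
                noise_sd=0.5, seed=500 + seed)
            res = org.expression_by_cluster(cluster_set, locs, tss, expr)
            if res.p_value < 0.05:
                rejections += 1
        assert rejections >= 0.95 * n_rep

    def test_empty_group_warns_and_skips(self):
        locs = pd.DataFrame({"chrom": "c", "midpoint": [100, 200]})
        cluster_set = org.find_clusters(locs)  # one cluster, no nonclusters
        tss = pd.DataFrame({"gene": ["g"], "chrom": "c", "tss": [150]})
        expr = pd.DataFrame({"gene": ["g"], "log2fc": [0.0]})
        with pytest.warns(UserWarning, match="empty group"):
            res = org.expression_by_cluster(cluster_set, locs, tss, expr)
        assert np.isnan(res.p_value)
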