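"""M-type feature suite, histogram decompositions, consensus clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from columncensus import mtypes as mt
from columncensus.consensus import ConsensusError, ConsensusLeidenClustering
from columncensus.skeleton import Skeleton

from conftest import chain_skeleton


def straight_dendrite(length=100.0, step=2.0):
    n = int(length / step) + 1
    skel = chain_skeleton(n, step=step)
    skel.radius[:] = 0.4
    return skel


def syn_table(skel, vertices, geometry, sizes=None):
    pos = skel.positions[np.asarray(vertices, dtype=int)]
    df = pd.DataFrame({
        "post_vertex": np.asarray(vertices, dtype=int),
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "size": sizes if sizes is not None else np.full(len(vertices), 100.0),
    })
    df["depth"] = geometry.depth(pos)
    return df


class TestScalarFeatures:
    def test_straight_uniform_dendrite(self, geometry):
        # 100 um straight dendrite with 50 uniform synapses: cable 100,
        # tip distance 100, tortuosity 1, density 0.5 /um.
        skel = straight_dendrite(100.0)
        from columncensus.compartments import assign_compartments
        assign_compartments(skel, [])
        verts = np.linspace(1, skel.n_vertices - 1, 50).astype(int)
        feats = mt.morphology_feature_suite(skel, syn_table(skel, verts, geometry),
                                            geometry)
        assert feats["total_cable_length"] == pytest.approx(100.0)
        assert feats["tip_distance_median"] == pytest.approx(100.0)
        assert feats["tip_tortuosity_median"] == pytest.approx(1.0)
        assert feats["dendritic_input_count"] == 50
        assert feats["linear_density_median"] == pytest.approx(0.5, abs=0.05)

    def test_constant_sizes_have_zero_dynamic_range(self, geometry):
        skel = straight_dendrite(100.0)
        from columncensus.compartments import assign_compartments
        assign_compartments(skel, [])
        verts = np.arange(1, skel.n_vertices, 2)
        feats = mt.morphology_feature_suite(
            skel, syn_table(skel, verts, geometry,
                            sizes=np.full(len(verts), 77.0)), geometry)
        assert feats["synapse_size_dynamic_range"] == 0.0
        assert feats["dendritic_synapse_size_median"] == 77.0

    def test_l_shaped_branch_tortuosity(self, geometry):
        # 60 um down then 80 um lateral: tip path 140, Euclid 100 -> 1.4.
        pos = [[0.0, 0.0, 0.0]]
        parent = [-1]
        for k in range(30):  # 60 um in y
            pos.append([0.0, 2.0 * (k + 1), 0.0])
            parent.append(len(pos) - 2)
        for k in range(40):  # 80 um in x
            pos.append([2.0 * (k + 1), 60.0, 0.0])
            parent.append(len(pos) - 2)
        skel = Skeleton(np.array(pos), np.array(parent))
        from columncensus.compartments import assign_compartments
        assign_compartments(skel, [])
        verts = np.arange(1, skel.n_vertices)
        feats = mt.morphology_feature_suite(skel, syn_table(skel, verts, geometry),
                                            geometry)
        assert feats["tip_distance_median"] == pytest.approx(140.0)
        assert feats["tip_tortuosity_median"] == pytest.approx(1.4)

    def test_no_dendritic_synapses_errors(self, geometry):
        skel = straight_dendrite(50.0)
        from columncensus.compartments import assign_compartments
        assign_compartments(skel, [])
        with pytest.raises(mt.FeatureError):
            mt.morphology_feature_suite(skel, syn_table(skel, [0], geometry),
                                        geometry)


class TestHistogramComponents:
    def _cells(self, rng, geometry, n=30, archetype=None):
        syn_by_cell, ids = {}, []
        for i in range(n):
            center = 150.0 if (archetype and i < n // 2) else 500.0
            if archetype is None:
                center = 300.0
            depths = rng.normal(center, 40.0, size=200)
            df = pd.DataFrame({"depth": np.clip(depths, 1, 799)})
            syn_by_cell[i] = df
            ids.append(i)
        return ids, syn_by_cell

    def test_loading_shapes(self, geometry):
        rng = np.random.default_rng(0)
        ids, syn = self._cells(rng, geometry)
        H = mt.depth_histograms(ids, syn, geometry)
        loadings, comps = mt.sparse_components(H, k=6)
        assert loadings.shape == (30, 6)
        assert comps.shape == (6, geometry.n_depth_bins)

    def test_row_zscore_means(self):
        H = np.random.default_rng(1).poisson(5.0, size=(10, 40)).astype(float)
        Z = mt._zscore_rows(H)
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)

    def test_two_depth_archetypes_separated_by_first_component(self, geometry):
        rng = np.random.default_rng(2)
        ids, syn = self._cells(rng, geometry, n=30, archetype=True)
        H = mt.depth_histograms(ids, syn, geometry)
        loadings, _ = mt.sparse_components(H, k=6)
        a, b = loadings[:15, 0], loadings[15:, 0]
        # The dominant component separates shallow from deep archetypes
        # with perfectly split loading signs.
        assert (np.sign(np.median(a)) != np.sign(np.median(b)))
        thresh = (np.median(a) + np.median(b)) / 2
        assert ((a > thresh).all() and (b < thresh).all()) or (
            (a < thresh).all() and (b > thresh).all())

    def test_soma_adjusted_translation_invariance(self, geometry):
        rng = np.random.default_rng(3)
        depths = rng.normal(0.0, 30.0, size=150)
        d1 = pd.DataFrame({"depth": 200.0 + depths})
        d2 = pd.DataFrame({"depth": 450.0 + depths})  # translated copy
        H = mt.soma_adjusted_histograms([0, 1], {0: d1, 1: d2},
                                        np.array([200.0, 450.0]))
        np.testing.assert_array_equal(H[0], H[1])

    def test_too_few_cells_rejected(self, geometry):
        with pytest.raises(mt.FeatureError):
            mt.sparse_components(np.zeros((3, 40)), k=6)


class TestBranchProfile:
    def test_unbranched_dendrite_profile_is_ones(self):
        skel = straight_dendrite(320.0, step=4.0)
        np.testing.assert_array_equal(mt.branch_count_profile(skel),
                                      np.ones(10))

    def test_single_bifurcation_counts_two_components(self):
        # Bifurcation at 45 um: one component at d=30, two from d=60 on.
        pos = [[0.0, 0.0, 0.0]]
        parent = [-1]
        for k in range(9):  # chain to 45 um
            pos.append([0.0, 5.0 * (k + 1), 0.0])
            parent.append(len(pos) - 2)
        junction = 9
        for d in ([1.0, 0.0], [-1.0, 0.0]):
            par = junction
            for k in range(60):  # each child extends ~300 um
                pos.append([d[0] * 5.0 * (k + 1), 45.0 + 5.0 * (k + 1), 0.0])
                parent.append(par)
                par = len(pos) - 1
        skel = Skeleton(np.array(pos), np.array(parent))
        profile = mt.branch_count_profile(skel)
        assert profile[0] == 1  # d = 30
        assert (profile[1:] == 2).all()  # d = 60..300

    def test_short_arbor_profile_is_zero(self):
        skel = straight_dendrite(16.0, step=4.0)
        np.testing.assert_array_equal(mt.branch_count_profile(skel),
                                      np.zeros(10))


class TestConsensusClustering:
    def _blobs(self, rng, n_per=20, sep=10.0, d=6):
        a = rng.normal(0, 1, size=(n_per, d))
        b = rng.normal(0, 1, size=(n_per, d)) + sep
        return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)

    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X, y = self._blobs(rng)
        eng = ConsensusLeidenClustering(n_runs=30, random_state=1).fit(X)
        assert eng.n_clusters_ == 2
        assert adjusted_rand_score(y, eng.labels_) == 1.0

    def test_duplicated_cells_fully_co_cluster(self):
        rng = np.random.default_rng(1)
        X, _ = self._blobs(rng, n_per=12)
        X = np.vstack([X, X[:3]])  # exact duplicates of the first 3 cells
        eng = ConsensusLeidenClustering(n_runs=30, random_state=2).fit(X)
        for i in range(3):
            assert eng.co_clustering_[i, 24 + i] == pytest.approx(1.0)

    def test_same_seed_reproduces_labels(self):
        rng = np.random.default_rng(2)
        X, _ = self._blobs(rng)
        l1 = ConsensusLeidenClustering(n_runs=20, random_state=5).fit_predict(X)
        l2 = ConsensusLeidenClustering(n_runs=20, random_state=5).fit_predict(X)
        np.testing.assert_array_equal(l1, l2)

    def test_co_clustering_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        X, _ = self._blobs(rng)
        eng = ConsensusLeidenClustering(n_runs=20, random_state=7).fit(X)
        co = eng.co_clustering_
        np.testing.assert_allclose(co, co.T)
        np.testing.assert_allclose(np.diag(co), 1.0)
        assert (co >= 0).all() and (co <= 1).all()

    def test_run_and_size_preconditions(self):
        X = np.random.default_rng(4).normal(size=(40, 3))
        with pytest.raises(ConsensusError):
            ConsensusLeidenClustering(n_runs=1).fit(X)
        with pytest.raises(ConsensusError):
            ConsensusLeidenClustering(n_runs=10).fit(X[:10])


class TestNaming:
    def test_modal_names_with_depth_ordered_suffixes(self):
        labels = pd.Series({i: (0 if i < 10 else 1 if i < 20 else 2)
                            for i in range(30)})
        expert = pd.Series({i: ("L4" if i < 20 else "L5") for i in range(30)})
        expert.iloc[[3, 15]] = None
        depths = pd.Series({i: (380.0 if i < 10 else 430.0 if i < 20 else 600.0)
                            for i in range(30)})
        named = mt.name_and_order_clusters(labels, expert, depths)
        assert (named[labels == 0] == "L4a").all()
        assert (named[labels == 1] == "L4b").all()
        assert (named[labels == 2] == "L5").all()

    def test_unlabeled_cluster_named_by_index(self):
        labels = pd.Series({0: 0, 1: 0, 2: 1, 3: 1})
        expert = pd.Series({0: "L2", 1: "L2", 2: None, 3: None})
        depths = pd.Series({0: 100.0, 1: 110.0, 2: 300.0, 3: 310.0})
        named = mt.name_and_order_clusters(labels, expert, depths)
        assert named[2] == "unlabeled_1"

    def test_modal_tie_takes_alphabetical_first(self, caplog):
        labels = pd.Series({0: 0, 1: 0})
        expert = pd.Series({0: "L3", 1: "L2"})
        depths = pd.Series({0: 100.0, 1: 110.0})
        named = mt.name_and_order_clusters(labels, expert, depths)
        assert (named == "L2").all()


class TestFeatureImportance:
    def test_importances_normalized_per_mtype(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 8)))
        y = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        imp = mt.mtype_feature_importance(X, y, random_state=0)
        np.testing.assert_allclose(imp.sum(axis=1), 1.0)

    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 8)))
        y = pd.Series(["pos"] * 12 + ["neg"] * 48)
        X.loc[y == "pos", 3] += 8.0  # class separable on feature 3 only
        imp = mt.mtype_feature_importance(X, y, random_state=1)
        assert imp.loc["pos"].idxmax() == 3
        assert imp.loc["pos", 3] > imp.loc["pos"].drop(3).max()

    def test_permuted_labels_give_near_uniform_importances(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(80, 8)))
        maxima = []
        for s in range(10):
            y = pd.Series(rng.permutation(["a"] * 40 + ["b"] * 40))
            imp = mt.mtype_feature_importance(X, y, random_state=s)
            maxima.append(imp.to_numpy().max())
        assert np.mean(maxima) < 2.0 * (1.0 / 8)
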