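"""Targeting features, the LDA subclass model, and inhibition-of-inhibition."""

import numpy as np
import pandas as pd
import pytest

from columncensus import subclasses as sc
from columncensus.skeleton import Skeleton

from conftest import chain_skeleton


def make_synapses(rows):
    """Synapse table from (pre, post, compartment, post_class, pre_vertex)."""
    df = pd.DataFrame(rows, columns=["pre_cell", "post_cell", "compartment",
                                     "post_class", "pre_vertex"])
    df["synapse_id"] = np.arange(len(df))
    df["x"] = 0.0; df["y"] = 0.0; df["z"] = 0.0
    df["size"] = 100.0
    df["post_vertex"] = 0
    return df


class TestTargetingFeatures:
    def test_fraction_arithmetic(self):
        # 100 outputs: 10 inhibitory; of the 90 excitatory-target synapses
        # 45 soma, 18 proximal, 9 apical -> (0.10, 0.50, 0.20, 0.10, ...).
        rows = []
        rows += [(1, 900, "inhibitory", "inhibitory", -1)] * 10
        rows += [(1, 901, "soma", "excitatory", -1)] * 45
        rows += [(1, 902, "proximal", "excitatory", -1)] * 18
        rows += [(1, 903, "apical", "excitatory", -1)] * 9
        rows += [(1, 904, "distal_basal", "excitatory", -1)] * 18
        f = sc.targeting_features(1, make_synapses(rows))
        assert f.frac_inhibitory_targets == pytest.approx(0.10)
        assert f.frac_soma == pytest.approx(0.50)
        assert f.frac_proximal == pytest.approx(0.20)
        assert f.frac_apical == pytest.approx(0.10)

    def test_clumped_fraction_on_axon_path(self):
        # Synapses of one connection at axon path positions 0, 10, 40 um:
        # the pair at distance 10 is clumped, the synapse at 40 is not -> 2/3.
        axon = chain_skeleton(5, step=10.0)
        rows = [(1, 50, "distal_basal", "excitatory", v) for v in (0, 1, 4)]
        f = sc.targeting_features(1, make_synapses(rows), pre_skeleton=axon)
        assert f.frac_multisyn == pytest.approx(1.0)
        assert f.frac_clumped == pytest.approx(2.0 / 3.0)

    def test_all_single_synapse_connections(self):
        rows = [(1, 50 + k, "distal_basal", "excitatory", -1) for k in range(5)]
        f = sc.targeting_features(1, make_synapses(rows))
        assert f.frac_multisyn == 0.0
        assert f.frac_clumped == 0.0

    def test_zero_outputs_errors(self):
        with pytest.raises(sc.SubclassError, match="no valid"):
            sc.targeting_features(99, make_synapses(
                [(1, 2, "soma", "excitatory", -1)]))

    @pytest.mark.parametrize("thresholds", [(5, 10, 15, 30, 60, 100)])
    def test_clumped_fraction_monotone_in_threshold(self, thresholds):
        rng = np.random.default_rng(4)
        axon = chain_skeleton(120, step=2.0)
        rows = []
        for post in range(20):
            k = int(rng.integers(1, 6))
            verts = rng.integers(0, 120, size=k)
            rows += [(1, 500 + post, "distal_basal", "excitatory", int(v))
                     for v in verts]
        syn = make_synapses(rows)
        fracs = [sc.targeting_features(1, syn, pre_skeleton=axon,
                                       clump_threshold=t).frac_clumped
                 for t in thresholds]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_euclidean_fallback_without_skeleton(self, caplog):
        rows = [(1, 50, "distal_basal", "excitatory", -1)] * 2
        syn = make_synapses(rows)
        syn.loc[1, "x"] = 5.0  # 5 um apart -> clumped
        f = sc.targeting_features(1, syn, pre_skeleton=None)
        assert f.frac_clumped == pytest.approx(1.0)


class TestSubclassClassifier:
    def _features(self, rng, centers, n=30):
        X, y = [], []
        for label, c in centers.items():
            X.append(np.clip(c + 0.03 * rng.normal(size=(n, 6)), 0, 1))
            y += [label] * n
        return np.vstack(X), np.array(y)

    CENTERS = {
        "PeriTC": np.array([0.08, 0.55, 0.30, 0.02, 0.7, 0.6]),
        "DistTC": np.array([0.10, 0.02, 0.08, 0.30, 0.6, 0.5]),
        "SparTC": np.array([0.10, 0.05, 0.20, 0.20, 0.05, 0.02]),
        "InhTC": np.array([0.85, 0.02, 0.03, 0.02, 0.6, 0.5]),
    }

    def test_disjoint_profiles_recovered_on_held_out_cells(self):
        rng = np.random.default_rng(0)
        X, y = self._features(rng, self.CENTERS, n=40)
        train = np.arange(len(y)) % 2 == 0
        model = sc.SubclassClassifier().fit(X[train], y[train])
        acc = (model.predict(X[~train]) == y[~train]).mean()
        assert acc >= 0.95

    def test_duplicated_labeled_cell_predicts_same_class(self):
        rng = np.random.default_rng(1)
        X, y = self._features(rng, self.CENTERS, n=10)
        model = sc.SubclassClassifier().fit(X, y)
        assert model.predict(X[:1])[0] == y[0]

    def test_constant_features_rejected(self):
        X = np.ones((8, 6))
        y = np.array(["PeriTC", "DistTC", "SparTC", "InhTC"] * 2)
        with pytest.raises(sc.SubclassError, match="degenerate"):
            sc.SubclassClassifier().fit(X, y)

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(2)
        centers = {k: v for k, v in self.CENTERS.items() if k != "InhTC"}
        X, y = self._features(rng, centers, n=5)
        with pytest.raises(sc.SubclassError, match="absent"):
            sc.SubclassClassifier().fit(X, y)

    def test_fit_and_assign_covers_all_cells(self):
        rng = np.random.default_rng(3)
        X, y = self._features(rng, self.CENTERS, n=10)
        feats = pd.DataFrame(X, index=np.arange(len(y)),
                             columns=sc.FEATURE_NAMES)
        expert = pd.Series(y, index=feats.index)
        expert.iloc[::3] = None  # unlabeled subset still gets predictions
        model, pred = sc.fit_and_assign_subclasses(feats, expert)
        assert len(pred) == len(feats)
        assert set(pred.unique()) <= set(sc.SUBCLASSES)


class TestSubclassConnectivity:
    def test_mean_input_arithmetic(self):
        # 2 PeriTCs send 3 and 5 synapses to one of two DistTCs:
        # entry (PeriTC, DistTC) = (8 + 0) / 2 = 4.
        sub = pd.Series({1: "PeriTC", 2: "PeriTC", 3: "DistTC", 4: "DistTC",
                         5: "SparTC", 6: "InhTC"})
        rows = [(1, 3, "inhibitory", "inhibitory", -1)] * 3
        rows += [(2, 3, "inhibitory", "inhibitory", -1)] * 5
        mat = sc.subclass_connectivity_matrix(make_synapses(rows), sub)
        assert mat.loc["PeriTC", "DistTC"] == pytest.approx(4.0)
        assert mat.loc["DistTC", "PeriTC"] == 0.0

    def test_no_synapses_gives_zero_matrix(self):
        sub = pd.Series({1: "PeriTC", 2: "DistTC", 3: "SparTC", 4: "InhTC"})
        mat = sc.subclass_connectivity_matrix(make_synapses([]), sub)
        assert (mat.fillna(0) == 0).all().all()

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(7)
        cells = np.arange(1, 13)
        sub = pd.Series(
            {c: s for c, s in zip(cells, np.repeat(sc.SUBCLASSES, 3))})
        rows = []
        for _ in range(60):
            pre, post = rng.choice(cells, 2, replace=False)
            rows.append((pre, post, "inhibitory", "inhibitory", -1))
        syn = make_synapses(rows)
        mat = sc.subclass_connectivity_matrix(syn, sub)
        for pre_s in sc.SUBCLASSES:
            for post_s in sc.SUBCLASSES:
                manual = sum(
                    ((syn.pre_cell.map(sub) == pre_s)
                     & (syn.post_cell.map(sub) == post_s)).sum()
                    for _ in [0]) / 3.0
                assert mat.loc[pre_s, post_s] == pytest.approx(manual)

    def test_totals_conserved(self):
        rng = np.random.default_rng(8)
        cells = np.arange(1, 13)
        sub = pd.Series(
            {c: s for c, s in zip(cells, np.repeat(sc.SUBCLASSES, 3))})
        rows = []
        for _ in range(80):
            pre, post = rng.choice(cells, 2, replace=False)
            rows.append((pre, post, "inhibitory", "inhibitory", -1))
        mat = sc.subclass_connectivity_matrix(make_synapses(rows), sub)
        n_post = sub.value_counts()
        total = sum(mat.loc[a, b] * n_post[b]
                    for a in sc.SUBCLASSES for b in sc.SUBCLASSES)
        assert total == pytest.approx(80)


class TestInhTCSplit:
    def test_subtypes_by_dominant_target(self):
        sub = pd.Series({1: "InhTC", 2: "InhTC", 3: "DistTC", 4: "PeriTC"})
        rows = [(1, 3, "inhibitory", "inhibitory", -1)] * 74
        rows += [(1, 4, "inhibitory", "inhibitory", -1)] * 26
        rows += [(2, 4, "inhibitory", "inhibitory", -1)] * 82
        rows += [(2, 3, "inhibitory", "inhibitory", -1)] * 18
        assign, fractions = sc.split_inhtc(make_synapses(rows), sub)
        assert assign[1] == "InhTC_Dist"
        assert assign[2] == "InhTC_Peri"
        assert fractions.loc[1, "DistTC"] == pytest.approx(0.74)
        assert fractions.loc[2, "PeriTC"] == pytest.approx(0.82)

    def test_tie_breaks_to_dist(self, caplog):
        sub = pd.Series({1: "InhTC", 3: "DistTC", 4: "PeriTC"})
        rows = [(1, 3, "inhibitory", "inhibitory", -1)] * 5
        rows += [(1, 4, "inhibitory", "inhibitory", -1)] * 5
        assign, _ = sc.split_inhtc(make_synapses(rows), sub)
        assert assign[1] == "InhTC_Dist"

    def test_silent_inhtc_left_unassigned(self):
        sub = pd.Series({1: "InhTC", 3: "DistTC"})
        assign, _ = sc.split_inhtc(make_synapses([]), sub)
        assert assign[1] is None


class TestConnectionComparison:
    def _group(self, sizes, conn_sizes, pre=1, post_start=100):
        rows = []
        post = post_start
        i = 0
        for k in conn_sizes:
            for _ in range(k):
                rows.append((pre, post, "soma", "excitatory", -1))
                i += 1
            post += 1
        df = make_synapses(rows)
        df["size"] = np.resize(np.asarray(sizes, dtype=float), len(df))
        return df

    def test_identical_groups_not_significant(self):
        sizes = np.linspace(80, 120, 12)
        a = self._group(sizes, [2, 3, 4, 3])
        b = self._group(sizes, [2, 3, 4, 3], pre=2, post_start=200)
        res = sc.connection_property_comparison(a, b, rng=0)
        assert res["count_ttest"]["p"] == pytest.approx(1.0)
        assert res["size_ttest"]["p"] == pytest.approx(1.0)

    def test_separated_connection_counts_significant(self):
        # Connections {4,4,4} vs {1,1,1}: means 4 vs 1, p < 0.01.
        rng = np.random.default_rng(0)
        a = self._group(rng.normal(100, 5, 12), [4, 4, 4])
        b = self._group(rng.normal(100, 5, 3), [1, 1, 1], pre=2, post_start=200)
        res = sc.connection_property_comparison(a, b, rng=0, welch=False)
        assert res["a"]["mean_syn_per_connection"] == pytest.approx(4.0)
        assert res["b"]["mean_syn_per_connection"] == pytest.approx(1.0)
        assert res["count_ttest"]["p"] < 0.01

    def test_bootstrap_of_constant_sample_has_zero_width_ci(self):
        a = self._group([100.0] * 9, [3, 3, 3])
        b = self._group([90.0] * 9, [3, 3, 3], pre=2, post_start=200)
        res = sc.connection_property_comparison(a, b, rng=0)
        lo, hi = res["a"]["size_ci"]
        assert lo == hi == 100.0
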