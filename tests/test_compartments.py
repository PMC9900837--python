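"""Soma collapse, axon split, pruning, apical scoring, compartments."""

import math

import numpy as np
import pytest

from columncensus import compartments as comp
from columncensus.skeleton import (
    COMP_APICAL, COMP_DISTAL_BASAL, COMP_PROXIMAL, COMP_SOMA,
    SWC_DENDRITE, Skeleton,
)
from columncensus.synthetic import generate_mixed_neuron

from conftest import chain_skeleton, random_tree


class TestSomaCollapse:
    def test_analytic_collapse_radius(self):
        # A nucleus of volume (4 pi / 3) * 10^3 um^3 has equivalent radius
        # 10 um; padded by 1.25 the collapse radius is 12.5 um.
        v = (4 * math.pi / 3) * 10.0 ** 3
        assert comp.soma_collapse_radius(v) == pytest.approx(12.5)

    def test_threshold_vertex_merged_or_kept(self):
        v = (4 * math.pi / 3) * 10.0 ** 3
        pos = np.array([[0, 0, 0], [0, 12.4, 0], [0, 13.0, 0], [0, 25.0, 0]],
                       dtype=float)
        skel = Skeleton(pos, np.array([-1, 0, 1, 2]))
        out, vmap = comp.collapse_soma(skel, v)
        # vertex at 12.4 um merged; vertex at 13 um kept
        assert out.n_vertices == 3
        assert vmap[1] == out.root
        assert vmap[2] != out.root

    def test_in_radius_vertex_not_merged_without_in_radius_path(self):
        v = (4 * math.pi / 3) * 10.0 ** 3  # collapse radius 12.5
        # Path leaves the collapse sphere (30 um out) then curls back to a
        # point 5 um from the soma: connectivity through in-radius vertices
        # fails, so the returning vertex must stay.
        pos = np.array([[0, 0, 0], [0, 30, 0], [5, 15, 0], [5, 0, 0]],
                       dtype=float)
        skel = Skeleton(pos, np.array([-1, 0, 1, 2]))
        out, vmap = comp.collapse_soma(skel, v)
        assert out.n_vertices == 4  # nothing merged
        assert vmap[3] != out.root

    def test_flood_fill_matches_masked_component_oracle(self):
        # Oracle: connected component of the root in the graph induced on
        # in-radius vertices.
        rng = np.random.default_rng(5)
        skel = random_tree(rng, 80, scale=8.0)
        vol = (4 * math.pi / 3) * 12.0 ** 3
        r = comp.soma_collapse_radius(vol)
        within = np.linalg.norm(skel.positions - skel.positions[skel.root],
                                axis=1) <= r
        expected = np.zeros(skel.n_vertices, dtype=bool)
        expected[skel.root] = True
        for v in skel.topological_order[1:]:
            expected[v] = within[v] and expected[skel.parent[v]]
        out, vmap = comp.collapse_soma(skel, vol)
        merged = vmap == out.root
        merged[skel.root] = True
        np.testing.assert_array_equal(merged, expected)


class TestFlowCentrality:
    def test_chain_pair_count(self):
        # 2 inputs at one end, 3 outputs at the other: the middle vertex is
        # crossed by all 2 * 3 = 6 pairs.
        skel = chain_skeleton(3)
        cent = comp.synapse_flow_centrality(skel, [0, 0], [2, 2, 2])
        assert cent[1] == 6

    def test_vertex_distal_to_all_synapses_is_zero(self):
        skel = chain_skeleton(4)
        cent = comp.synapse_flow_centrality(skel, [0], [1])
        assert cent[3] == 0

    def test_requires_inputs_and_outputs(self):
        skel = chain_skeleton(3)
        with pytest.raises(comp.CompartmentError, match="cannot split"):
            comp.synapse_flow_centrality(skel, [], [1])

    def test_equals_brute_force_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            skel = random_tree(rng, n)
            inputs = rng.integers(0, n, size=rng.integers(1, 12))
            outputs = rng.integers(0, n, size=rng.integers(1, 12))
            cent = comp.synapse_flow_centrality(skel, inputs, outputs)
            brute = brute_force_flow(skel, inputs, outputs)
            np.testing.assert_array_equal(cent, brute)


def brute_force_flow(skel, inputs, outputs):
    """Exhaustive (input, output)-pair path enumeration."""
    n = skel.n_vertices
    cent = np.zeros(n, dtype=np.int64)
    paths = {}
    def path(a, b):
        key = (a, b)
        if key not in paths:
            anc_a = []
            u = a
            while u != -1:
                anc_a.append(u)
                u = int(skel.parent[u])
            anc_set = set(anc_a)
            walk = []
            u = b
            while u not in anc_set:
                walk.append(u)
                u = int(skel.parent[u])
            lca = u
            upper = anc_a[:anc_a.index(lca) + 1]
            paths[key] = upper + walk
        return paths[key]
    for i in inputs:
        for o in outputs:
            for v in path(int(i), int(o)):
                cent[v] += 1
    return cent


class TestSegregationIndex:
    def test_perfect_segregation_is_one(self):
        skel = chain_skeleton(4)
        res = comp.segregation_index(skel, 2, [0, 0, 1], [2, 3, 3])
        assert res.index == pytest.approx(1.0, abs=1e-12)

    def test_uniform_mixing_is_zero(self):
        skel = chain_skeleton(4)
        res = comp.segregation_index(skel, 2, [0, 1, 2, 3], [0, 1, 2, 3])
        assert res.index == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mixed_split(self):
        # Part A: 9 inputs / 1 output; part B: 1 / 9 (N = 20).
        # index = 1 - H(0.1)/H(0.5) = 0.53097...
        skel = chain_skeleton(2)
        inputs = [1] * 9 + [0] * 1
        outputs = [1] * 1 + [0] * 9
        res = comp.segregation_index(skel, 1, inputs, outputs)
        h01 = -(0.1 * math.log(0.1) + 0.9 * math.log(0.9))
        expected = 1.0 - h01 / math.log(2)
        assert res.index == pytest.approx(expected, abs=1e-12)
        assert res.index == pytest.approx(0.531, abs=5e-4)

    def test_no_synapses_errors(self):
        skel = chain_skeleton(2)
        with pytest.raises(comp.CompartmentError):
            comp.segregation_index(skel, 1, [], [])


class TestDetectAxon:
    def test_perfectly_segregated_neuron_recovers_planted_axon(self):
        mixed = generate_mixed_neuron(epsilon=0.0, seed=0)
        split = comp.detect_axon(mixed.skeleton, mixed.input_vertices,
                                 mixed.output_vertices, "inhibitory")
        found = np.flatnonzero(split.axon_mask)
        np.testing.assert_array_equal(np.sort(found),
                                      np.sort(mixed.axon_vertices))

    def test_excitatory_uses_flow_split_above_segregation_threshold(self):
        mixed = generate_mixed_neuron(epsilon=0.05, seed=1)
        split = comp.detect_axon(mixed.skeleton, mixed.input_vertices,
                                 mixed.output_vertices, "excitatory")
        assert split.method == "flow"
        assert split.segregation >= 0.7

    def test_excitatory_falls_back_below_threshold(self):
        mixed = generate_mixed_neuron(epsilon=0.5, seed=2)
        split = comp.detect_axon(mixed.skeleton, mixed.input_vertices,
                                 mixed.output_vertices, "excitatory")
        assert split.method == "fallback"
        assert split.segregation < 0.7

    def test_fallback_density_rule(self):
        # Soma-adjacent 25-um branches: 1 input (0.04/um) -> axonal;
        # 5 inputs (0.2/um) -> dendritic.
        pos = [[0, 0, 0], [0, 5, 0]]
        parent = [-1, 0]
        for k in range(5):  # branch A: 5 x 5 um = 25 um
            pos.append([5 * (k + 1), 5, 0])
            parent.append(1 if k == 0 else len(pos) - 2)
        branch_a = list(range(2, 7))
        for k in range(5):  # branch B
            pos.append([-5 * (k + 1), 5, 0])
            parent.append(1 if k == 0 else len(pos) - 2)
        branch_b = list(range(7, 12))
        skel = Skeleton(np.array(pos, dtype=float), np.array(parent))
        inputs = [branch_a[-1]] + [branch_b[0], branch_b[1], branch_b[2],
                                   branch_b[3], branch_b[4]]
        split = comp.detect_axon(skel, inputs, [], "excitatory")
        assert split.method == "fallback"
        assert split.axon_mask[branch_a].all()
        assert not split.axon_mask[branch_b].any()

    def test_inhibitory_without_outputs_flagged(self):
        skel = chain_skeleton(3)
        split = comp.detect_axon(skel, [1], [], "inhibitory")
        assert split.flagged and not split.axon_mask.any()


class TestPruning:
    def _counts(self, skel, vertices):
        return np.bincount(np.asarray(vertices, dtype=int),
                           minlength=skel.n_vertices)

    def test_bare_terminal_segment_pruned(self):
        skel = chain_skeleton(4)  # 30 um terminal run, 0 inputs
        pruned = comp.prune_false_merges(skel, self._counts(skel, []))
        assert pruned[1:].all()

    def test_dense_terminal_segment_kept(self):
        skel = chain_skeleton(4)  # 30 um, 10 inputs = 0.33/um
        counts = self._counts(skel, [1, 1, 1, 2, 2, 2, 3, 3, 3, 3])
        pruned = comp.prune_false_merges(skel, counts)
        assert not pruned.any()

    def test_cascade_reaches_fixed_point(self):
        # Bifurcation: one dense child, one bare chain whose removal exposes
        # a bare parent run that must be pruned on the next iteration.
        pos = [[0, 0, 0]]
        parent = [-1]
        for k in range(3):  # trunk, no inputs beyond the junction
            pos.append([0, 10 * (k + 1), 0])
            parent.append(len(pos) - 2)
        junction = 3
        for k in range(3):  # dense side branch
            pos.append([10 * (k + 1), 30, 0])
            parent.append(junction if k == 0 else len(pos) - 2)
        dense = [4, 5, 6]
        for k in range(3):  # bare terminal chain
            pos.append([-10 * (k + 1), 30, 0])
            parent.append(junction if k == 0 else len(pos) - 2)
        bare = [7, 8, 9]
        skel = Skeleton(np.array(pos, dtype=float), np.array(parent))
        counts = self._counts(skel, dense * 4)
        pruned = comp.prune_false_merges(skel, counts)
        assert pruned[bare].all()
        # The trunk (now terminalward of nothing) feeds the dense branch and
        # must survive; pruning again changes nothing (idempotence).
        assert not pruned[dense].any()
        # Fixed point: a second pass prunes nothing new.
        again = comp.prune_false_merges(skel, counts)
        assert not again.any()


class TestApicalFeatures:
    def test_root_conventions(self, geometry):
        skel = chain_skeleton(3)
        feats = comp.vertex_apical_features(skel, geometry)
        names = comp.APICAL_FEATURE_NAMES
        root = feats[0]
        assert root[names.index("path_dist_to_soma")] == 0.0
        assert root[names.index("tortuosity_to_root")] == 1.0
        assert root[names.index("angle_to_vertical")] == 0.0

    def test_straight_ascending_branch(self, geometry):
        # Straight toward the pia: tortuosity 1, angle 0.
        skel = chain_skeleton(5, step=10.0, direction=(0.0, -1.0, 0.0))
        skel.positions += np.array([0.0, 400.0, 0.0])
        feats = comp.vertex_apical_features(skel, geometry)
        names = comp.APICAL_FEATURE_NAMES
        assert feats[4, names.index("tortuosity_to_root")] == pytest.approx(1.0)
        assert feats[4, names.index("angle_to_vertical")] == pytest.approx(0.0)

    def test_trigonometric_example(self, geometry):
        # 30 um lateral, 40 um above the soma: Euclid 50, radial 30,
        # angle atan2(30, 40) = 36.87 degrees.
        pos = np.array([[0, 100, 0], [30, 60, 0]], dtype=float)
        skel = Skeleton(pos, np.array([-1, 0]))
        feats = comp.vertex_apical_features(skel, geometry)
        names = comp.APICAL_FEATURE_NAMES
        assert feats[1, names.index("euclidean_dist_from_soma")] == pytest.approx(50.0)
        assert feats[1, names.index("radial_dist_from_soma")] == pytest.approx(30.0)
        assert feats[1, names.index("angle_to_vertical")] == pytest.approx(
            math.degrees(math.atan2(30, 40)))


def two_branch_skeleton(n_per_branch=20, step=5.0):
    """Two straight branches off the root, each n * step um long."""
    pos = [np.zeros(3)]
    parent = [-1]
    branches = []
    for d in (np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])):
        verts = []
        par = 0
        for k in range(n_per_branch):
            pos.append(d * step * (k + 1))
            parent.append(par)
            par = len(pos) - 1
            verts.append(par)
        branches.append(verts)
    return Skeleton(np.array(pos), np.array(parent)), branches


class TestApicalScoring:
    def test_hand_computed_softmax(self):
        # R1 = +50, R2 = -10: S1 = e^1 / (e^1 + e^-0.2) = 0.7685; only
        # branch 1 qualifies.
        skel, (b1, b2) = two_branch_skeleton()
        p = np.full(skel.n_vertices, 0.5)
        p[b1] = 1.0 / (1.0 + math.exp(-50.0 / len(b1)))
        p[b2] = 1.0 / (1.0 + math.exp(10.0 / len(b2)))
        scores = {s.branch_root: s for s in comp.score_apical_branches(skel, p)}
        s1, s2 = scores[b1[0]], scores[b2[0]]
        assert s1.R == pytest.approx(50.0, rel=1e-9)
        assert s1.S == pytest.approx(
            math.exp(1.0) / (math.exp(1.0) + math.exp(-0.2)), abs=1e-9)
        assert s1.S == pytest.approx(0.7685, abs=1e-4)
        assert s1.qualifies and not s2.qualifies

    def test_log_odds_saturate_at_200(self):
        skel, (b1, _) = two_branch_skeleton()
        p = np.full(skel.n_vertices, 0.5)
        p[b1] = 1.0 / (1.0 + math.exp(-15.0))  # raw sum = 300
        scores = {s.branch_root: s for s in comp.score_apical_branches(skel, p)}
        assert scores[b1[0]].R == pytest.approx(200.0)

    def test_four_way_tie_yields_no_apical(self):
        # Four equal branches with R = +100 each: S = 0.25 exactly, and the
        # strict S > 0.25 rule rejects all of them.
        pos = [np.zeros(3)]
        parent = [-1]
        for d in ([1, 0, 0], [-1, 0, 0], [0, 0, 1], [0, 0, -1]):
            par = 0
            for k in range(20):
                pos.append(np.asarray(d, dtype=float) * 5.0 * (k + 1))
                parent.append(par)
                par = len(pos) - 1
        skel = Skeleton(np.array(pos), np.array(parent))
        p = np.full(skel.n_vertices, 1.0 / (1.0 + math.exp(-5.0)))
        scores = comp.score_apical_branches(skel, p)
        assert all(s.S == pytest.approx(0.25) for s in scores)
        assert not any(s.qualifies for s in scores)

    def test_short_branches_excluded_from_softmax(self):
        skel, (b1, b2) = two_branch_skeleton(n_per_branch=20)
        # Shrink branch 2 below the 50-um tip threshold.
        skel.positions[b2] *= 0.4  # 40 um tip
        p = np.full(skel.n_vertices, 0.6)
        scores = {s.branch_root: s for s in comp.score_apical_branches(skel, p)}
        assert scores[b1[0]].S == pytest.approx(1.0)
        assert scores[b2[0]].S == 0.0 and not scores[b2[0]].qualifies


class TestCompartmentAssignment:
    def test_proximal_boundary_inclusive_at_50(self):
        skel = chain_skeleton(8, step=10.0)  # vertices at 0..70 um
        comp.assign_compartments(skel, [])
        assert skel.compartment[5] == COMP_PROXIMAL   # 50 um
        assert skel.compartment[6] == COMP_DISTAL_BASAL  # 60 um
        assert skel.compartment[0] == COMP_SOMA

    def test_apical_beyond_proximal_only(self):
        skel = chain_skeleton(8, step=10.0)
        comp.assign_compartments(skel, [1])
        assert skel.compartment[5] == COMP_PROXIMAL
        assert skel.compartment[6] == COMP_APICAL

    def test_labels_partition_dendritic_vertices(self):
        rng = np.random.default_rng(9)
        skel = random_tree(rng, 100, scale=12.0)
        labels = comp.assign_compartments(skel, [])
        dend = skel.dendrite_mask()
        assert (labels[dend] >= 0).all()


class TestWorkedF1:
    def test_f1_from_confusion_counts(self):
        # Leave-one-out vertex-classifier confusion: 86 TP, 2 FP, 11 FN.
        assert comp.f1_from_confusion(86, 2, 11) == pytest.approx(0.9297, abs=5e-5)
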