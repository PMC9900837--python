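"""Skeleton processing: soma collapse, axon split, pruning, compartments.

The stages mirror how dense EM reconstructions are prepared for connectivity
analysis:

1. **Soma collapse** merges vertices near the soma centroid into a single
   root so perisomatic cable does not masquerade as dendrite.
2. **Axon identification** splits the arbor at the maximum of synapse flow
   centrality — the vertex crossed by the most (input, output) synapse
   pairs — validated (for excitatory cells) by an entropy-based segregation
   index, with a low-input-density branch rule as fallback.
3. **False-merge pruning** iteratively strips terminal dendritic segments
   whose synaptic input density is implausibly low.
4. **Apical detection** aggregates per-vertex apical probabilities from a
   pluggable vertex model into per-branch log-odds, compared by a soft-max.
5. **Compartment assignment** labels every remaining vertex (and hence every
   synapse) as soma, proximal, distal basal, or apical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .skeleton import (
    COMP_APICAL,
    COMP_DISTAL_BASAL,
    COMP_NONE,
    COMP_PROXIMAL,
    COMP_SOMA,
    SWC_AXON,
    SWC_DENDRITE,
    SWC_PRUNED,
    SWC_SOMA,
    Skeleton,
)

logger = logging.getLogger(__name__)

SOMA_PAD_FACTOR = 1.25          # padding on the nucleus-equivalent radius
SEGREGATION_THRESHOLD = 0.7     # min segregation index to trust the flow split
FALLBACK_SOMA_WINDOW = 30.0     # um (path distance) for soma-adjacent branches
FALLBACK_MIN_LENGTH = 20.0      # um minimum branch length for the fallback rule
MIN_INPUT_DENSITY = 0.1         # synaptic inputs per um
PROXIMAL_RADIUS = 50.0          # um path distance bounding the proximal zone
APICAL_MIN_TIP = 50.0           # um minimum tip length for an apical candidate
LOG_ODDS_CLIP = 200.0           # saturation of aggregated branch log-odds
SOFTMAX_SCALE = 50.0            # soft-max temperature on branch log-odds
SOFTMAX_THRESHOLD = 0.25        # strict lower bound on the soft-max share


class CompartmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Soma collapse
# ---------------------------------------------------------------------------

def soma_collapse_radius(nucleus_volume: float) -> float:
    """Radius of the soma-collapse sphere for a nucleus volume (um^3).

    The nucleus-equivalent sphere radius, padded by 1.25 to absorb lopsided
    cell bodies.
    """
    if nucleus_volume <= 0:
        raise CompartmentError("nucleus_volume must be > 0")
    return SOMA_PAD_FACTOR * (3.0 * nucleus_volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def collapse_soma(skel: Skeleton, nucleus_volume: float):
    """Merge perisomatic vertices into the root.

    Vertices within the collapse radius of the soma centroid *and*
    topologically connected to it through in-radius vertices are merged.
    Returns ``(collapsed_skeleton, vertex_map)`` where ``vertex_map[v]`` is
    the new index of old vertex ``v`` (merged vertices map to the new root);
    callers re-assign synapse vertex references through it.
    """
    r = soma_collapse_radius(nucleus_volume)
    center = skel.positions[skel.root]
    within = np.linalg.norm(skel.positions - center, axis=1) <= r
    # Flood fill from the root through in-radius vertices only.
    merge = np.zeros(skel.n_vertices, dtype=bool)
    merge[skel.root] = True
    for v in skel.topological_order[1:]:
        if within[v] and merge[skel.parent[v]]:
            merge[v] = True
    keep = ~merge
    keep[skel.root] = True
    old_idx = np.flatnonzero(keep)
    new_of_old = -np.ones(skel.n_vertices, dtype=np.int64)
    new_of_old[old_idx] = np.arange(len(old_idx))
    vertex_map = np.where(merge, new_of_old[skel.root], new_of_old)
    # Reattach: the nearest kept ancestor of any kept vertex is either its
    # parent (if kept) or the root (merged region is connected to the root).
    new_parent = np.empty(len(old_idx), dtype=np.int64)
    for k, v in enumerate(old_idx):
        p = skel.parent[v]
        new_parent[k] = -1 if p < 0 else vertex_map[p]
    out = Skeleton(
        skel.positions[old_idx],
        new_parent,
        skel.radius[old_idx],
        skel.vertex_label[old_idx],
    )
    out.vertex_label[out.root] = SWC_SOMA
    return out, vertex_map


# ---------------------------------------------------------------------------
# Synapse flow centrality and segregation index
# ---------------------------------------------------------------------------

def _vertex_counts(n, vertices):
    return np.bincount(np.asarray(vertices, dtype=np.int64), minlength=n).astype(np.int64)


def synapse_flow_centrality(skel: Skeleton, input_vertices, output_vertices) -> np.ndarray:
    """Per-vertex count of (input, output) synapse pairs whose path crosses it.

    A pair's tree path contains vertex ``v`` exactly when its endpoints fall
    in different components of the tree with ``v`` removed (or one endpoint
    sits at ``v``), giving
    ``c(v) = I*O - I_above*O_above - sum_children I_c*O_c``
    with subtree synapse sums computed in one reverse topological sweep.
    """
    n = skel.n_vertices
    ic = _vertex_counts(n, input_vertices)
    oc = _vertex_counts(n, output_vertices)
    I, O = int(ic.sum()), int(oc.sum())
    if I == 0 or O == 0:
        raise CompartmentError("cannot split: need at least one input and one output")
    sub_i = ic.astype(np.int64).copy()
    sub_o = oc.astype(np.int64).copy()
    child_term = np.zeros(n, dtype=np.int64)
    for v in skel.topological_order[::-1]:
        p = skel.parent[v]
        if p >= 0:
            child_term[p] += sub_i[v] * sub_o[v]
            sub_i[p] += sub_i[v]
            sub_o[p] += sub_o[v]
    above_i = I - sub_i
    above_o = O - sub_o
    return I * O - above_i * above_o - child_term


@dataclass
class SegregationSplit:
    """Input/output segregation at a candidate axon split.

    ``index`` is ``1 - sum_i n_i H_i / (N H_total)`` over the two parts
    (subtree at the split vertex vs. the rest), with binary input/output
    entropies in nats and the convention ``0 ln 0 = 0``; clipped to [0, 1].
    """

    split_vertex: int
    counts: tuple[tuple[int, int], tuple[int, int]]  # (inputs, outputs) per part
    entropies: tuple[float, float]
    index: float


def _binary_entropy(k, n) -> float:
    if n == 0:
        return 0.0
    p = k / n
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            h -= q * math.log(q)
    return h


def segregation_index(skel: Skeleton, split_vertex: int, input_vertices,
                      output_vertices) -> SegregationSplit:
    """Entropy-based 0-1 score of input/output segregation at a split.

    1 means both parts are pure (all inputs on one side, outputs on the
    other); 0 means the split explains none of the input/output mixing.
    """
    n = skel.n_vertices
    ic = _vertex_counts(n, input_vertices)
    oc = _vertex_counts(n, output_vertices)
    N = int(ic.sum() + oc.sum())
    if N == 0:
        raise CompartmentError("no synapses: segregation index undefined")
    sub = skel.subtree_mask(split_vertex)
    parts = []
    entropies = []
    weighted = 0.0
    for mask in (sub, ~sub):
        i_k, o_k = int(ic[mask].sum()), int(oc[mask].sum())
        n_k = i_k + o_k
        h_k = _binary_entropy(i_k, n_k)
        parts.append((i_k, o_k))
        entropies.append(h_k)
        weighted += n_k * h_k
    h_total = _binary_entropy(int(ic.sum()), N)
    if h_total == 0.0:
        index = 0.0
    else:
        index = 1.0 - weighted / (N * h_total)
    index = min(1.0, max(0.0, index))
    return SegregationSplit(int(split_vertex), (parts[0], parts[1]),
                            (entropies[0], entropies[1]), index)


# ---------------------------------------------------------------------------
# Axon detection
# ---------------------------------------------------------------------------

@dataclass
class AxonSplit:
    axon_mask: np.ndarray          # True on axonal vertices
    method: str                    # "flow", "fallback", or "none"
    split_vertex: int | None
    segregation: float | None
    flagged: bool = False


def _flow_split(skel, input_vertices, output_vertices):
    cent = synapse_flow_centrality(skel, input_vertices, output_vertices).astype(float)
    # The root cannot define a split (its "subtree" is the whole tree).
    cent[skel.root] = -np.inf
    best = cent.max()
    cand = np.flatnonzero(cent == best)
    # Tie-break: the candidate closest to the soma.
    v = int(cand[np.argmin(skel.dist_to_root[cand])])
    sub = skel.subtree_mask(v)
    n = skel.n_vertices
    ic = _vertex_counts(n, input_vertices)
    oc = _vertex_counts(n, output_vertices)
    # Axon = output-rich side.
    def purity(mask):
        i, o = ic[mask].sum(), oc[mask].sum()
        return o / (i + o) if (i + o) else 0.0
    axon_mask = sub if purity(sub) >= purity(~sub) else ~sub
    axon_mask = axon_mask.copy()
    axon_mask[skel.root] = False
    return v, axon_mask


def _fallback_axon_branches(skel, input_counts):
    """Soma-adjacent branches with low input density (excitatory fallback).

    Candidate branches are the distinct subtrees emerging from the
    soma-adjacent region (vertices within 30 um path distance of the soma):
    every child of the root or of an in-region branch point, plus every
    vertex exiting the region.  A candidate whose subtree (including its
    connecting edge) is longer than 20 um with input density below
    0.1 syn/um is labeled axonal.
    """
    d = skel.dist_to_root
    near = d <= FALLBACK_SOMA_WINDOW
    n_child = np.bincount(skel.parent[skel.parent >= 0],
                          minlength=skel.n_vertices)
    axon = np.zeros(skel.n_vertices, dtype=bool)
    for v in range(skel.n_vertices):
        p = skel.parent[v]
        if p < 0 or not near[p]:
            continue
        starts_branch = (p == skel.root) or (n_child[p] >= 2) or not near[v]
        if not starts_branch:
            continue
        sub = skel.subtree_mask(v)
        length = skel.total_cable_length(sub) + float(skel.edge_lengths[v])
        if length <= FALLBACK_MIN_LENGTH:
            continue
        density = input_counts[sub].sum() / length
        if density < MIN_INPUT_DENSITY:
            axon |= sub
    return axon


def detect_axon(skel: Skeleton, input_vertices, output_vertices,
                coarse_class: str) -> AxonSplit:
    """Identify the axonal vertex set.

    Inhibitory cells: split at maximum synapse flow centrality, axon is the
    output-rich side (no segregation gate).  Excitatory cells: the flow
    split is used when its segregation index is >= 0.7; otherwise every
    soma-adjacent branch longer than 20 um with input density below
    0.1 syn/um is labeled axonal.
    """
    n = skel.n_vertices
    input_vertices = np.asarray(input_vertices, dtype=np.int64)
    output_vertices = np.asarray(output_vertices, dtype=np.int64)
    if coarse_class == "inhibitory":
        if len(output_vertices) == 0:
            logger.warning("inhibitory cell with no synaptic outputs; axon left empty")
            return AxonSplit(np.zeros(n, dtype=bool), "none", None, None, flagged=True)
        v, axon_mask = _flow_split(skel, input_vertices, output_vertices)
        return AxonSplit(axon_mask, "flow", v, None)
    # Excitatory
    if len(output_vertices) and len(input_vertices):
        v, axon_mask = _flow_split(skel, input_vertices, output_vertices)
        seg = segregation_index(skel, v, input_vertices, output_vertices)
        if seg.index >= SEGREGATION_THRESHOLD:
            return AxonSplit(axon_mask, "flow", v, seg.index)
        seg_index = seg.index
    else:
        seg_index = None
    ic = _vertex_counts(n, input_vertices)
    axon_mask = _fallback_axon_branches(skel, ic)
    return AxonSplit(axon_mask, "fallback", None, seg_index)


# ---------------------------------------------------------------------------
# False-merge pruning
# ---------------------------------------------------------------------------

def prune_false_merges(skel: Skeleton, input_counts) -> np.ndarray:
    """Iteratively prune low-input-density terminal dendritic segments.

    Terminal segments of the non-axonal region with input density below
    0.1 syn/um are removed; exposure of new bare terminals iterates to a
    fixed point.  Returns the pruned-vertex mask (and sets vertex labels).
    """
    input_counts = np.asarray(input_counts)
    pruned = np.zeros(skel.n_vertices, dtype=bool)
    region = skel.dendrite_mask()
    while True:
        active = region & ~pruned
        segments = skel.decompose_segments(mask=active)
        changed = False
        for seg in segments:
            if not seg.is_terminal or seg.path_length <= 0:
                continue
            density = input_counts[seg.vertices].sum() / seg.path_length
            if density < MIN_INPUT_DENSITY:
                pruned[seg.vertices] = True
                changed = True
        if not changed:
            break
    skel.vertex_label[pruned] = SWC_PRUNED
    return pruned


# ---------------------------------------------------------------------------
# Apical-branch detection
# ---------------------------------------------------------------------------

APICAL_FEATURE_NAMES = [
    "vertex_depth", "soma_depth", "depth_difference", "path_dist_to_soma",
    "dist_to_farthest_tip", "normalized_tip_distance", "tortuosity_to_root",
    "branch_points_to_root", "radial_dist_from_soma", "euclidean_dist_from_soma",
    "angle_to_vertical",
]


def vertex_apical_features(skel: Skeleton, geometry) -> np.ndarray:
    """The 11 per-vertex features used by the apical vertex model.

    Returned for every vertex as an (n, 11) array; rows for non-dendritic
    vertices are computed but are typically masked by the caller.  Root
    conventions: path distance 0, tortuosity 1, angle 0.
    """
    n = skel.n_vertices
    depths = np.asarray(geometry.depth(skel.positions))
    soma_depth = depths[skel.root]
    d_path = skel.dist_to_root
    # Farthest downstream tip distance per vertex (reverse sweep).
    tip = np.zeros(n)
    el = skel.edge_lengths
    for v in skel.topological_order[::-1]:
        p = skel.parent[v]
        if p >= 0:
            tip[p] = max(tip[p], tip[v] + el[v])
    with np.errstate(invalid="ignore", divide="ignore"):
        norm_tip = np.where(d_path + tip > 0, d_path / (d_path + tip), 0.0)
    delta = skel.positions - skel.positions[skel.root]
    euclid = np.linalg.norm(delta, axis=1)
    tort = np.ones(n)
    nz = euclid > 0
    tort[nz] = d_path[nz] / euclid[nz]
    # Branch points on the path to root.
    n_child = np.bincount(skel.parent[skel.parent >= 0], minlength=n)
    bp_to_root = np.zeros(n)
    for v in skel.topological_order[1:]:
        p = skel.parent[v]
        bp_to_root[v] = bp_to_root[p] + (1 if n_child[p] >= 2 else 0)
    radial = np.asarray(geometry.radial(skel.positions, skel.positions[skel.root]))
    rise = soma_depth - depths  # positive toward pia
    angle = np.zeros(n)
    nz = (radial > 0) | (rise != 0)
    angle[nz] = np.degrees(np.arctan2(radial[nz], rise[nz]))
    angle[skel.root] = 0.0
    return np.column_stack([
        depths, np.full(n, soma_depth), depths - soma_depth, d_path, tip,
        norm_tip, tort, bp_to_root, radial, euclid, angle,
    ])


class ApicalVertexModel(ClassifierMixin, BaseEstimator):
    """Random-forest vertex classifier for apical membership.

    A retrainable stand-in for an expert-trained vertex model: fit on
    vertices with known apical labels (e.g. planted synthetic apical
    subtrees), it predicts the per-vertex probability that a dendritic
    vertex belongs to an apical dendrite.  Any external per-vertex
    probability vector can be used instead of this model wherever branch
    scores are computed.
    """

    def __init__(self, n_estimators=100, max_depth=None, random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def apical_probability(self, X, eps=1e-6):
        """P(apical) per vertex, clipped away from 0/1 for finite log-odds."""
        X = np.asarray(X, dtype=float)
        if 1 not in self.classes_:
            # Trained on a column without apical dendrites.
            return np.full(len(X), eps)
        proba = self.predict_proba(X)
        col = int(np.flatnonzero(self.classes_ == 1)[0])
        return np.clip(proba[:, col], eps, 1.0 - eps)


@dataclass
class ApicalScore:
    """Aggregated apical evidence for one soma-child branch."""

    branch_root: int
    R: float            # summed vertex log-odds, clipped to +-200
    S: float            # soft-max share among long-enough branches
    max_tip_length: float
    qualifies: bool     # max tip >= 50 um and R > 0 and S > 0.25


def score_apical_branches(skel: Skeleton, vertex_probability,
                          dendrite_mask=None) -> list[ApicalScore]:
    """Aggregate per-vertex apical probabilities into per-branch calls.

    For each dendritic branch off the soma, the vertex log-odds
    ``ln(p/(1-p))`` are summed and clipped at +-200; branches whose farthest
    tip lies under 50 um are excluded from the soft-max denominator
    ``S_i = exp(R_i/50) / sum_j exp(R_j/50)``.  A branch is apical when it
    is long enough, its net evidence is positive, and ``S_i > 0.25``
    (strict, so four equally weighted branches all fail).
    """
    p = np.clip(np.asarray(vertex_probability, dtype=float), 1e-12, 1 - 1e-12)
    if dendrite_mask is None:
        dendrite_mask = skel.dendrite_mask()
    log_odds = np.log(p) - np.log1p(-p)
    d = skel.dist_to_root
    scores = []
    for verts in skel.root_branches(mask=dendrite_mask):
        R = float(np.clip(log_odds[verts].sum(), -LOG_ODDS_CLIP, LOG_ODDS_CLIP))
        tip = float(d[verts].max()) if len(verts) else 0.0
        scores.append(ApicalScore(int(verts[0]), R, 0.0, tip, False))
    eligible = [s for s in scores if s.max_tip_length >= APICAL_MIN_TIP]
    if eligible:
        z = np.array([s.R / SOFTMAX_SCALE for s in eligible])
        z -= z.max()  # numerical stability; shares are shift-invariant
        expz = np.exp(z)
        shares = expz / expz.sum()
        for s, share in zip(eligible, shares):
            s.S = float(share)
            s.qualifies = s.R > 0 and s.S > SOFTMAX_THRESHOLD
    return scores


# ---------------------------------------------------------------------------
# Compartment assignment
# ---------------------------------------------------------------------------

def assign_compartments(skel: Skeleton, apical_branch_roots) -> np.ndarray:
    """Label every non-axon, non-pruned vertex with its compartment.

    soma = the collapsed root; proximal = dendritic vertices within 50 um
    path distance of the root (boundary inclusive); apical = beyond-proximal
    vertices in an apical branch; distal basal = the rest.  The labels are
    written to ``skel.compartment`` and returned.
    """
    comp = np.full(skel.n_vertices, COMP_NONE, dtype=np.int64)
    dend = skel.dendrite_mask()
    d = skel.dist_to_root
    comp[dend & (d <= PROXIMAL_RADIUS)] = COMP_PROXIMAL
    comp[dend & (d > PROXIMAL_RADIUS)] = COMP_DISTAL_BASAL
    apical = np.zeros(skel.n_vertices, dtype=bool)
    for r in apical_branch_roots:
        apical |= skel.subtree_mask(int(r))
    sel = dend & apical & (d > PROXIMAL_RADIUS)
    comp[sel] = COMP_APICAL
    comp[skel.root] = COMP_SOMA
    if np.any((comp == COMP_NONE) & dend):
        raise CompartmentError("internal error: unlabeled dendritic vertex")
    skel.compartment = comp
    return comp


# ---------------------------------------------------------------------------
# Worked-example metric
# ---------------------------------------------------------------------------

def f1_from_confusion(tp: int, fp: int, fn: int) -> float:
    """F1 score from confusion counts: 2TP / (2TP + FP + FN)."""
    denom = 2 * tp + fp + fn
    return 2.0 * tp / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Per-cell pipeline
# ---------------------------------------------------------------------------

def label_synapses(synapses, cells, processed: dict) -> "pd.DataFrame":
    """Attach target-side compartment labels to a synapse table.

    Adds ``compartment`` (soma / proximal / distal_basal / apical for
    excitatory targets, the pooled fifth compartment ``inhibitory`` for
    inhibitory targets, ``none`` for synapses landing on axonal or pruned
    cable, which downstream statistics exclude) and ``post_class``.
    ``processed`` maps cell_id to :class:`ProcessedCell`.
    """
    import pandas as pd
    from .skeleton import COMPARTMENT_NAMES

    out = synapses.copy()
    comp = np.full(len(out), "none", dtype=object)
    post_class = np.full(len(out), "none", dtype=object)
    class_of = dict(zip(cells["cell_id"].astype(int), cells["coarse_class"]))
    pv = out["post_vertex"].to_numpy()
    for cid, idx in out.groupby("post_cell").groups.items():
        cid = int(cid)
        if cid not in processed:
            continue
        pc = processed[cid]
        idx = np.asarray(idx)
        v = pc.vertex_map[pv[idx].astype(np.int64)]
        skel = pc.skeleton
        on_dend = skel.dendrite_mask()[v]
        cls = class_of.get(cid, "none")
        post_class[idx] = cls
        if cls == "inhibitory":
            comp[idx] = np.where(on_dend, "inhibitory", "none")
        else:
            names = np.array([COMPARTMENT_NAMES[c] for c in skel.compartment[v]],
                             dtype=object)
            comp[idx] = np.where(on_dend, names, "none")
    out["compartment"] = comp
    out["post_class"] = post_class
    return out


@dataclass
class ProcessedCell:
    skeleton: Skeleton
    vertex_map: np.ndarray      # original vertex -> processed vertex
    axon: AxonSplit
    pruned: np.ndarray
    apical_scores: list[ApicalScore]
    apical_roots: list[int]


def process_cell(skel: Skeleton, nucleus_volume: float, coarse_class: str,
                 input_vertices, output_vertices,
                 apical_probability=None, apical_roots=None) -> ProcessedCell:
    """Run the full compartment pipeline on one cell.

    ``input_vertices`` / ``output_vertices`` index the *original* skeleton.
    Apical branches are taken from ``apical_roots`` (original-skeleton
    vertex ids, e.g. planted ground truth) if given, else scored from
    ``apical_probability`` (per collapsed vertex); with neither, no apical
    compartment is assigned (valid for inhibitory cells).
    """
    collapsed, vmap = collapse_soma(skel, nucleus_volume)
    inputs = vmap[np.asarray(input_vertices, dtype=np.int64)]
    outputs = vmap[np.asarray(output_vertices, dtype=np.int64)]
    axon = detect_axon(collapsed, inputs, outputs, coarse_class)
    collapsed.vertex_label[axon.axon_mask] = SWC_AXON
    in_counts = _vertex_counts(collapsed.n_vertices, inputs)
    if coarse_class == "excitatory":
        pruned = prune_false_merges(collapsed, in_counts)
    else:
        pruned = np.zeros(collapsed.n_vertices, dtype=bool)
    scores: list[ApicalScore] = []
    if apical_roots is not None:
        roots = [int(vmap[int(r)]) for r in apical_roots]
        roots = [r for r in roots if r != collapsed.root]
    elif apical_probability is not None and coarse_class == "excitatory":
        scores = score_apical_branches(collapsed, apical_probability)
        roots = [s.branch_root for s in scores if s.qualifies]
    else:
        roots = []
    assign_compartments(collapsed, roots)
    return ProcessedCell(collapsed, vmap, axon, pruned, scores, roots)
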