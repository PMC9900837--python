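"""Excitatory M-types: the 29-feature suite and consensus clustering.

Each excitatory cell is described by 15 morphology/synapse scalars, 6
sparse-component loadings of its absolute-depth synapse histogram, 5
loadings of a soma-centred histogram, and 3 singular-vector loadings of its
branch-count-vs-distance profile.  Features are z-scored per column and
clustered with the shared consensus engine; clusters are named by the modal
expert label (letter suffixes by ascending median soma depth) and
per-M-type feature importances come from one-vs-rest random forests with
minority oversampling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import SparsePCA
from sklearn.ensemble import RandomForestClassifier

from ._stats import smote_oversample
from .consensus import ConsensusLeidenClustering
from .skeleton import COMP_SOMA, Skeleton

logger = logging.getLogger(__name__)

SCALAR_FEATURES = [
    "tip_distance_median", "tip_tortuosity_median", "dendritic_input_count",
    "somatic_input_count", "total_cable_length", "radial_extent_p97",
    "synapse_soma_distance_median", "soma_synapse_size_median",
    "dendritic_synapse_size_median", "synapse_size_dynamic_range",
    "synapse_depth_p5", "synapse_depth_p95", "synapse_vertical_extent",
    "linear_density_median", "vertex_radius_median_beyond30",
]

BRANCH_PROFILE_DISTANCES = np.arange(30, 301, 30)  # um
BRANCH_PROFILE_WINDOW = 10.0                       # um toward the soma


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Per-cell scalar features
# ---------------------------------------------------------------------------

def morphology_feature_suite(skel: Skeleton, synapses, geometry) -> dict:
    """The 15 scalar features for one processed excitatory cell.

    ``skel`` must have passed the compartment pipeline (axon masked, soma
    collapsed); ``synapses`` are the cell's input synapses with ``depth``
    and ``post_vertex`` referring to this skeleton's vertices.
    """
    dend = skel.dendrite_mask()
    dend_nonroot = dend.copy()
    dend_nonroot[skel.root] = False
    if not dend_nonroot.any():
        raise FeatureError("cell has no dendritic cable")
    d = skel.dist_to_root
    # Tips of the dendritic region.
    n_child = np.zeros(skel.n_vertices, dtype=int)
    for v in range(skel.n_vertices):
        p = skel.parent[v]
        if p >= 0 and dend[v] and dend[p]:
            n_child[p] += 1
    tips = np.flatnonzero(dend_nonroot & (n_child == 0))
    euclid = np.linalg.norm(skel.positions - skel.positions[skel.root], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tip_tort = np.where(euclid[tips] > 0, d[tips] / euclid[tips], 1.0)

    on_soma = skel.compartment[synapses["post_vertex"].to_numpy()] == COMP_SOMA
    syn_dend = synapses[~on_soma]
    syn_soma = synapses[on_soma]
    if len(syn_dend) == 0:
        raise FeatureError("cell has no dendritic input synapses")
    sizes = syn_dend["size"].to_numpy(dtype=float)
    depths = synapses["depth"].to_numpy(dtype=float)

    radial = geometry.radial(skel.positions, skel.positions[skel.root])

    # Median linear density over depth bins with nonzero cable.
    el = skel.edge_lengths
    vdepth = geometry.depth(skel.positions)
    vbin = geometry.depth_bin(vdepth)
    ok = dend_nonroot & dend[np.maximum(skel.parent, 0)] & (skel.parent >= 0)
    cable_per_bin = np.bincount(vbin[ok], weights=el[ok],
                                minlength=geometry.n_depth_bins)
    syn_bin = geometry.depth_bin(syn_dend["depth"].to_numpy())
    syn_per_bin = np.bincount(syn_bin, minlength=geometry.n_depth_bins)
    nz = cable_per_bin > 0
    density_median = float(np.median(syn_per_bin[nz] / cable_per_bin[nz]))

    far = dend_nonroot & (d > 30.0)
    radius_median = (
        float(np.median(skel.radius[far])) if far.any() else np.nan)

    p5, p95 = np.percentile(depths, [5, 95])
    return {
        "tip_distance_median": float(np.median(d[tips])),
        "tip_tortuosity_median": float(np.median(tip_tort)),
        "dendritic_input_count": float(len(syn_dend)),
        "somatic_input_count": float(len(syn_soma)),
        "total_cable_length": skel.total_cable_length(dend),
        "radial_extent_p97": float(np.percentile(radial[dend], 97)),
        "synapse_soma_distance_median": float(
            np.median(d[syn_dend["post_vertex"].to_numpy()])),
        "soma_synapse_size_median": (
            float(syn_soma["size"].median()) if len(syn_soma) else np.nan),
        "dendritic_synapse_size_median": float(np.median(sizes)),
        "synapse_size_dynamic_range": float(
            np.percentile(sizes, 95) - np.percentile(sizes, 5)),
        "synapse_depth_p5": float(p5),
        "synapse_depth_p95": float(p95),
        "synapse_vertical_extent": float(p95 - p5),
        "linear_density_median": density_median,
        "vertex_radius_median_beyond30": radius_median,
    }


# ---------------------------------------------------------------------------
# Histogram decompositions
# ---------------------------------------------------------------------------

def _zscore_rows(H):
    mu = H.mean(axis=1, keepdims=True)
    sd = H.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (H - mu) / sd


def _fix_component_signs(components):
    """Sign-fix so each component's largest-magnitude entry is positive."""
    comps = components.copy()
    for i, c in enumerate(comps):
        j = int(np.argmax(np.abs(c)))
        if c[j] < 0:
            comps[i] = -c
    return comps


def depth_histograms(cell_ids, synapses_by_cell, geometry) -> np.ndarray:
    """Per-cell synapse counts over the column's absolute depth bins."""
    n_bins = geometry.n_depth_bins
    H = np.zeros((len(cell_ids), n_bins))
    for i, cid in enumerate(cell_ids):
        b = geometry.depth_bin(synapses_by_cell[cid]["depth"].to_numpy())
        H[i] = np.bincount(b, minlength=n_bins)
    return H


def soma_adjusted_histograms(cell_ids, synapses_by_cell, soma_depths,
                             n_bins=13, span=100.0) -> np.ndarray:
    """Per-cell synapse counts in soma-centred bins spanning +-``span`` um."""
    edges = np.linspace(-span, span, n_bins + 1)
    H = np.zeros((len(cell_ids), n_bins))
    for i, cid in enumerate(cell_ids):
        rel = synapses_by_cell[cid]["depth"].to_numpy() - soma_depths[i]
        H[i], _ = np.histogram(rel, bins=edges)
    return H


def sparse_components(H, k, alpha=1.0, random_state=0):
    """Top-``k`` SparsePCA loadings of row-z-scored histograms.

    Returns ``(loadings, components)``; components are sign-fixed so the
    largest-magnitude entry of each is positive (loadings flipped to match).
    """
    if H.shape[0] < k:
        raise FeatureError(f"need at least {k} cells for {k} components")
    Z = _zscore_rows(np.asarray(H, dtype=float))
    model = SparsePCA(n_components=k, alpha=alpha, random_state=random_state)
    loadings = model.fit_transform(Z)
    comps = model.components_
    signs = np.ones(k)
    for i, c in enumerate(comps):
        j = int(np.argmax(np.abs(c)))
        if c[j] < 0:
            signs[i] = -1.0
    return loadings * signs, comps * signs[:, None]


def branch_count_profile(skel: Skeleton) -> np.ndarray:
    """Connected dendritic components in 10-um bands at 30..300 um.

    At each distance d the band covers path distances in ``[d - 10, d]``;
    the count is the number of connected components of the skeleton induced
    on band vertices (robust to exact branch-point locations).
    """
    dend = skel.dendrite_mask()
    d = skel.dist_to_root
    profile = np.zeros(len(BRANCH_PROFILE_DISTANCES))
    for i, dist in enumerate(BRANCH_PROFILE_DISTANCES):
        band = dend & (d >= dist - BRANCH_PROFILE_WINDOW) & (d <= dist)
        band[skel.root] = False
        if not band.any():
            continue
        # Union-find-free component count: a band vertex starts a new
        # component iff its parent is outside the band.
        starts = 0
        for v in np.flatnonzero(band):
            p = skel.parent[v]
            if p < 0 or not band[p]:
                starts += 1
        profile[i] = starts
    return profile


def branch_profile_loadings(profiles, k=3):
    """Top-``k`` right-singular-vector loadings of stacked branch profiles."""
    P = np.asarray(profiles, dtype=float)
    if P.shape[0] < k:
        raise FeatureError(f"need at least {k} cells for {k} SVD components")
    Pc = P - P.mean(axis=0)
    U, S, Vt = np.linalg.svd(Pc, full_matrices=False)
    Vt = _fix_component_signs(Vt[:k])
    return Pc @ Vt.T, Vt


# ---------------------------------------------------------------------------
# Feature matrix assembly
# ---------------------------------------------------------------------------

def assemble_feature_matrix(cell_ids, scalar_rows, depth_loadings,
                            soma_loadings, branch_loadings) -> pd.DataFrame:
    """Stack all feature blocks, impute, and z-score per column.

    Missing values (e.g. soma synapse size for a cell with no somatic
    inputs) are imputed with the feature's median before z-scoring.
    """
    df = pd.DataFrame(scalar_rows, index=cell_ids)[SCALAR_FEATURES]
    for name, block in (("depth_spca", depth_loadings),
                        ("soma_spca", soma_loadings),
                        ("branch_svd", branch_loadings)):
        block = np.asarray(block)
        for j in range(block.shape[1]):
            df[f"{name}_{j}"] = block[:, j]
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d missing feature values with column medians",
                    n_missing)
        df = df.fillna(df.median())
    z = (df - df.mean()) / df.std(ddof=0).replace(0, 1.0)
    return z


# ---------------------------------------------------------------------------
# Cluster naming and feature importance
# ---------------------------------------------------------------------------

def name_and_order_clusters(labels: pd.Series, expert_labels: pd.Series,
                            soma_depths: pd.Series) -> pd.Series:
    """Name clusters by modal expert label, suffixed by median soma depth.

    Clusters sharing a modal label get letter suffixes (a, b, ...) in order
    of ascending median soma depth; clusters without any expert-labeled
    member are named ``unlabeled_<k>``.  Ties in the modal label go to the
    alphabetically first label, with a warning.
    """
    names = {}
    by_name: dict[str, list] = {}
    for k in sorted(labels.unique()):
        members = labels.index[labels == k]
        exp = expert_labels.reindex(members).dropna()
        if len(exp) == 0:
            names[k] = f"unlabeled_{k}"
            continue
        counts = exp.value_counts()
        top = counts[counts == counts.max()].index.sort_values()
        if len(top) > 1:
            logger.warning("cluster %s: tied modal expert labels %s; using %s",
                           k, list(top), top[0])
        base = top[0]
        depth = float(soma_depths.reindex(members).median())
        by_name.setdefault(base, []).append((depth, k))
    for base, entries in by_name.items():
        entries.sort()
        if len(entries) == 1:
            names[entries[0][1]] = base
        else:
            for suffix, (_, k) in zip("abcdefghijklmnopqrstuvwxyz", entries):
                names[k] = f"{base}{suffix}"
    return labels.map(names)


def mtype_feature_importance(features: pd.DataFrame, labels: pd.Series,
                             n_estimators=100, random_state=0) -> pd.DataFrame:
    """One-vs-rest random-forest feature importances per M-type.

    Minority class is oversampled (SMOTE-style interpolation) before
    fitting; importances are Mean Decrease in Impurity, normalised to sum
    to 1 per M-type.  Single-member classes are skipped with a warning.
    """
    rows = {}
    X = features.to_numpy(dtype=float)
    classes = [c for c in pd.unique(labels)]
    if len(classes) < 2:
        raise FeatureError("need at least 2 classes for feature importance")
    for mtype in classes:
        y = (labels == mtype).to_numpy().astype(int)
        if y.sum() < 2:
            logger.warning("M-type %s has a single member; importance skipped", mtype)
            continue
        Xo, yo = smote_oversample(X, y, rng=random_state)
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state).fit(Xo, yo)
        imp = forest.feature_importances_
        rows[mtype] = imp / imp.sum()
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=features.columns)


# ---------------------------------------------------------------------------
# End-to-end M-type extraction
# ---------------------------------------------------------------------------

def extract_mtype_features(cells, processed, synapses, geometry,
                           spca_alpha=1.0, random_state=0):
    """Full 29-feature matrix for all excitatory cells.

    ``processed`` maps cell_id to the compartment pipeline's
    :class:`ProcessedCell`; input synapses are mapped through each cell's
    vertex map and restricted to non-axonal, non-pruned targets.
    """
    exc = cells[cells["coarse_class"] == "excitatory"]["cell_id"].astype(int).tolist()
    scalar_rows, syn_by_cell, profiles, soma_depths = [], {}, [], []
    for cid in exc:
        pc = processed[cid]
        skel = pc.skeleton
        syn = synapses[synapses["post_cell"] == cid].copy()
        syn["post_vertex"] = pc.vertex_map[syn["post_vertex"].to_numpy(dtype=np.int64)]
        keep = skel.dendrite_mask()[syn["post_vertex"].to_numpy()]
        syn = syn[keep]
        scalar_rows.append(morphology_feature_suite(skel, syn, geometry))
        syn_by_cell[cid] = syn
        profiles.append(branch_count_profile(skel))
        soma_depths.append(float(geometry.depth(skel.positions[skel.root][None])[0]))
    H_abs = depth_histograms(exc, syn_by_cell, geometry)
    depth_load, depth_comps = sparse_components(H_abs, k=6, alpha=spca_alpha,
                                                random_state=random_state)
    H_soma = soma_adjusted_histograms(exc, syn_by_cell, np.array(soma_depths))
    soma_load, soma_comps = sparse_components(H_soma, k=5, alpha=spca_alpha,
                                              random_state=random_state)
    branch_load, branch_comps = branch_profile_loadings(np.array(profiles), k=3)
    fm = assemble_feature_matrix(exc, scalar_rows, depth_load, soma_load,
                                 branch_load)
    components = {"depth": depth_comps, "soma_adjusted": soma_comps,
                  "branch": branch_comps}
    return fm, components


def consensus_cluster(features: pd.DataFrame, n_runs=500, subsample=0.95,
                      knn=10, resolution=1.3, k_range=(2, 30), seed=0):
    """Consensus-cluster a feature matrix; returns the fitted engine."""
    engine = ConsensusLeidenClustering(
        n_runs=n_runs, subsample=subsample, n_neighbors=knn,
        resolution=resolution, k_range=k_range, random_state=seed)
    engine.fit(features.to_numpy(dtype=float))
    return engine
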