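"""Inhibitory subclasses from synaptic targeting properties.

Six features summarise how an interneuron distributes its output: the
fraction of synapses onto other inhibitory neurons; the fractions of
excitatory-target synapses onto somata, proximal dendrites, and apical
dendrites (distal basal is the complement and is not a feature); the
fraction of synapses belonging to multisynaptic connections (>= 2 synapses
between the same cell pair); and the fraction of multisynaptic-connection
synapses lying within a path-distance threshold (default 15 um) of another
synapse of the same connection along the presynaptic axon ("clumped").

A linear discriminant trained on expert-annotated cells assigns every
interneuron to one of the four cardinal connectivity subclasses: PeriTC
(perisomatic-targeting), DistTC (distal-dendrite-targeting), SparTC
(sparsely-targeting) and InhTC (inhibitory-targeting).  Disagreements with
expert labels are retained as the model's view of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from ._stats import bootstrap_ci, holm_sidak
from .tables import exclude_autapses

logger = logging.getLogger(__name__)

SUBCLASSES = ("PeriTC", "DistTC", "SparTC", "InhTC")
CLUMP_THRESHOLD = 15.0  # um of presynaptic axonal path

FEATURE_NAMES = [
    "frac_inhibitory_targets", "frac_soma", "frac_proximal", "frac_apical",
    "frac_multisyn", "frac_clumped",
]


class SubclassError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Targeting features
# ---------------------------------------------------------------------------

def _connection_clumped_fraction(offsets, threshold):
    """Fraction of a connection's synapses within ``threshold`` of another."""
    x = np.sort(np.asarray(offsets, dtype=float))
    if len(x) < 2:
        return 0.0
    near = np.zeros(len(x), dtype=bool)
    gaps = np.diff(x) <= threshold
    near[:-1] |= gaps
    near[1:] |= gaps
    return float(near.mean())


def _presyn_offsets(group, skeleton):
    """Per-synapse path positions along the presynaptic axon.

    Path distances are measured between skeleton nodes; distances to a
    common reference (the root) linearise only within an unbranched chain,
    so pairwise clump checks use full tree path distances.  Falls back to
    Euclidean positions when the skeleton (or vertex assignment) is absent.
    """
    pv = group["pre_vertex"].to_numpy()
    if skeleton is None or (pv < 0).any():
        logger.warning("presynaptic skeleton unavailable; clump distances fall back to Euclidean")
        return None
    return pv.astype(np.int64)


@dataclass
class TargetingFeatures:
    frac_inhibitory_targets: float
    frac_soma: float
    frac_proximal: float
    frac_apical: float
    frac_multisyn: float
    frac_clumped: float

    def as_array(self):
        return np.array([
            self.frac_inhibitory_targets, self.frac_soma, self.frac_proximal,
            self.frac_apical, self.frac_multisyn, self.frac_clumped,
        ])


def targeting_features(cell_id, synapses, pre_skeleton=None,
                       clump_threshold=CLUMP_THRESHOLD) -> TargetingFeatures:
    """The six targeting features for one interneuron.

    ``synapses`` must carry ``compartment`` and ``post_class`` columns (see
    :func:`columncensus.compartments.label_synapses`); rows with
    compartment ``none`` (pruned/axonal targets) are ignored.  Autapses are
    excluded.
    """
    out = exclude_autapses(synapses)
    out = out[(out["pre_cell"] == cell_id) & (out["compartment"] != "none")]
    n = len(out)
    if n == 0:
        raise SubclassError(f"cell {cell_id} has no valid synaptic outputs")
    onto_inh = out["post_class"] == "inhibitory"
    frac_inh = float(onto_inh.mean())
    exc = out[~onto_inh]
    n_exc = len(exc)
    def frac(compartment):
        return float((exc["compartment"] == compartment).mean()) if n_exc else 0.0
    # Multisynaptic connections and clumping.
    conn_sizes = out.groupby("post_cell")["synapse_id"].transform("size")
    multi = conn_sizes >= 2
    frac_multi = float(multi.mean())
    if frac_multi == 0:
        frac_clumped = 0.0
    else:
        clumped, total = 0.0, 0
        for post, grp in out[multi].groupby("post_cell"):
            pv = _presyn_offsets(grp, pre_skeleton)
            if pv is not None:
                d = pre_skeleton.dist_to_root
                # Pairwise tree path distances between presynaptic vertices.
                m = len(pv)
                flags = np.zeros(m, dtype=bool)
                for i in range(m):
                    for j in range(i + 1, m):
                        if pre_skeleton.path_distance(int(pv[i]), int(pv[j])) <= clump_threshold:
                            flags[i] = flags[j] = True
                frac_c = float(flags.mean())
            else:
                pos = grp[["x", "y", "z"]].to_numpy()
                m = len(pos)
                dd = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
                np.fill_diagonal(dd, np.inf)
                frac_c = float((dd.min(axis=1) <= clump_threshold).mean())
            clumped += frac_c * m
            total += m
        frac_clumped = clumped / total if total else 0.0
    return TargetingFeatures(frac_inh, frac("soma"), frac("proximal"),
                             frac("apical"), frac_multi, frac_clumped)


def targeting_feature_table(synapses, cells, skeletons=None,
                            clump_threshold=CLUMP_THRESHOLD) -> pd.DataFrame:
    """Targeting features for every inhibitory cell with outputs."""
    inh = cells[cells["coarse_class"] == "inhibitory"]["cell_id"].astype(int)
    rows = {}
    for cid in inh:
        try:
            skel = skeletons.get(cid) if skeletons else None
            rows[cid] = targeting_features(cid, synapses, skel,
                                           clump_threshold).as_array()
        except SubclassError:
            logger.warning("cell %d skipped: no valid outputs", cid)
    return pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_NAMES)


# ---------------------------------------------------------------------------
# Linear discriminant subclass model
# ---------------------------------------------------------------------------

class SubclassClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant over the six targeting features."""

    def __init__(self):
        pass

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        missing = [c for c in SUBCLASSES if c not in classes]
        if missing:
            raise SubclassError(f"classes absent from training labels: {missing}")
        if (counts < 2).any():
            raise SubclassError("need at least 2 labeled cells per class")
        if np.allclose(X.var(axis=0), 0):
            raise SubclassError("degenerate features: zero variance everywhere")
        self.lda_ = LinearDiscriminantAnalysis().fit(X, y)
        self.classes_ = self.lda_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(np.asarray(X, dtype=float))


def fit_and_assign_subclasses(features: pd.DataFrame, expert_labels: pd.Series):
    """Fit on expert-annotated cells, predict for all inhibitory cells.

    Returns ``(model, assignments)`` where ``assignments`` is a Series over
    all cells in ``features``.  Disagreements with the expert labels are
    retained (and logged), per the data-driven-classification contract.
    """
    labeled = expert_labels.dropna()
    labeled = labeled[labeled.index.isin(features.index)]
    model = SubclassClassifier().fit(features.loc[labeled.index], labeled.to_numpy())
    pred = pd.Series(model.predict(features), index=features.index, name="subclass")
    disagree = (pred.loc[labeled.index] != labeled).sum()
    if disagree:
        logger.info("%d cells classified differently from expert labels", disagree)
    return model, pred


# ---------------------------------------------------------------------------
# Inhibition of inhibition
# ---------------------------------------------------------------------------

def subclass_connectivity_matrix(synapses, subclasses: pd.Series) -> pd.DataFrame:
    """Mean synaptic input per postsynaptic cell, by (pre, post) subclass.

    Entry (pre, post) = total synapses from all pre-subclass cells onto
    each post-subclass cell, averaged over post-subclass cells (cells with
    zero input included).  Empty subclasses yield NaN.
    """
    syn = exclude_autapses(synapses)
    sub = dict(subclasses)
    syn = syn[syn["pre_cell"].isin(sub) & syn["post_cell"].isin(sub)]
    mat = pd.DataFrame(np.nan, index=list(SUBCLASSES), columns=list(SUBCLASSES))
    n_post = subclasses.value_counts()
    totals = (
        syn.assign(pre_sub=syn["pre_cell"].map(sub), post_sub=syn["post_cell"].map(sub))
        .groupby(["pre_sub", "post_sub"], observed=True)
        .size()
    )
    for pre in SUBCLASSES:
        for post in SUBCLASSES:
            if n_post.get(post, 0) == 0:
                continue
            mat.loc[pre, post] = totals.get((pre, post), 0) / n_post[post]
    return mat


def split_inhtc(synapses, subclasses: pd.Series):
    """Partition InhTCs into DistTC-preferring and PeriTC-preferring subtypes.

    Each InhTC's output fractions over the four target subclasses are
    computed from its synapses onto inhibitory cells; the subtype is the
    larger of the DistTC vs PeriTC share (ties go to InhTC_Dist with a
    warning).  Cells with no inhibitory-target synapses are left
    unassigned and flagged.
    """
    syn = exclude_autapses(synapses)
    sub = dict(subclasses)
    inhtc = [c for c, s in sub.items() if s == "InhTC"]
    fractions = {}
    assignment = {}
    for cid in inhtc:
        out = syn[(syn["pre_cell"] == cid) & syn["post_cell"].isin(sub)]
        if len(out) == 0:
            logger.warning("InhTC %d has no inhibitory-target synapses; unassigned", cid)
            assignment[cid] = None
            continue
        shares = out["post_cell"].map(sub).value_counts(normalize=True)
        fractions[cid] = {s: float(shares.get(s, 0.0)) for s in SUBCLASSES}
        d, p = fractions[cid]["DistTC"], fractions[cid]["PeriTC"]
        if d == p:
            logger.warning("InhTC %d: tied DistTC/PeriTC share; assigned InhTC_Dist", cid)
        assignment[cid] = "InhTC_Dist" if d >= p else "InhTC_Peri"
    return assignment, pd.DataFrame.from_dict(fractions, orient="index")


def connection_property_comparison(group_a, group_b, n_boot=1000, rng=0,
                                   welch=True):
    """Compare synapse sizes and synapses-per-connection between two groups.

    ``group_a`` / ``group_b`` are synapse sub-tables (e.g. preferred vs
    non-preferred targets of a set of cells).  Returns median sizes with
    percentile-bootstrap 95% CIs, a Welch t-test (classical Student's by
    flag) on per-connection synapse counts, and the group means, with
    Holm-Sidak-adjusted p-values across the comparisons made.
    """
    res = {}
    pvals = []
    for name, grp in (("a", group_a), ("b", group_b)):
        if len(grp) == 0:
            raise SubclassError("comparison groups must be non-empty")
        sizes = grp["size"].to_numpy(dtype=float)
        if len(sizes) >= 2:
            med, ci = bootstrap_ci(sizes, np.median, n_boot=n_boot, rng=rng)
        else:
            med, ci = float(np.median(sizes)), (np.nan, np.nan)
        counts = grp.groupby(["pre_cell", "post_cell"]).size().to_numpy(dtype=float)
        res[name] = {"median_size": med, "size_ci": ci,
                     "syn_per_connection": counts,
                     "mean_syn_per_connection": float(counts.mean())}
    t_size, p_size = stats.ttest_ind(
        group_a["size"], group_b["size"], equal_var=not welch)
    t_cnt, p_cnt = stats.ttest_ind(
        res["a"]["syn_per_connection"], res["b"]["syn_per_connection"],
        equal_var=not welch)
    pvals = [float(p_size), float(p_cnt)]
    p_adj, reject = holm_sidak(pvals)
    res["size_ttest"] = {"t": float(t_size), "p": pvals[0], "p_adj": float(p_adj[0])}
    res["count_ttest"] = {"t": float(t_cnt), "p": pvals[1], "p_adj": float(p_adj[1])}
    return res
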