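"""Inhibition-onto-excitation summaries and motif-group discovery.

Net input matrices, connection densities and their correlations, the
perisomatic/dendritic input balance, normalised output budgets, and
consensus clustering of budgets into motif groups — sets of interneurons
that distribute output across the same excitatory M-types.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import holm_sidak
from .consensus import ConsensusLeidenClustering
from .tables import exclude_autapses

logger = logging.getLogger(__name__)


class ConnectivityError(ValueError):
    pass


def _inh_to_exc(synapses, subclasses, mtypes):
    syn = exclude_autapses(synapses)
    return syn[syn["pre_cell"].isin(subclasses.index)
               & syn["post_cell"].isin(mtypes.index)]


# ---------------------------------------------------------------------------
# Net input
# ---------------------------------------------------------------------------

def net_input_summary(synapses, subclasses: pd.Series, mtypes: pd.Series):
    """Mean net synapses per target cell, by (subclass, M-type).

    Returns ``(matrix, per_post_cell, per_pre_cell)``: the subclass x
    M-type mean-net-input matrix (averaged over all M-type cells, zero
    receivers included), per-postsynaptic-cell totals by subclass, and
    per-presynaptic-cell totals.
    """
    syn = _inh_to_exc(synapses, subclasses, mtypes)
    pre_sub = syn["pre_cell"].map(subclasses)
    post_mt = syn["post_cell"].map(mtypes)
    counts = syn.groupby([pre_sub.rename("subclass"),
                          post_mt.rename("mtype")], observed=True).size()
    n_per_mtype = mtypes.value_counts()
    mat = counts.unstack(fill_value=0).reindex(
        index=sorted(subclasses.unique()),
        columns=sorted(mtypes.unique()), fill_value=0).astype(float)
    mat = mat.div(n_per_mtype.reindex(mat.columns), axis=1)
    per_post = (syn.groupby([syn["post_cell"], pre_sub], observed=True).size()
                .unstack(fill_value=0)
                .reindex(mtypes.index, fill_value=0))
    per_pre = syn.groupby("pre_cell").size().reindex(subclasses.index, fill_value=0)
    return mat, per_post, per_pre


# ---------------------------------------------------------------------------
# Connection density
# ---------------------------------------------------------------------------

def connection_density(interneuron, mtype_cells, synapses) -> float:
    """Fraction of the M-type's cells receiving >= 1 synapse from the cell."""
    if len(mtype_cells) == 0:
        raise ConnectivityError("empty M-type: connection density undefined")
    syn = exclude_autapses(synapses)
    hit = syn[(syn["pre_cell"] == interneuron)
              & syn["post_cell"].isin(mtype_cells)]["post_cell"].nunique()
    return hit / len(mtype_cells)


def density_table(synapses, subclasses: pd.Series, mtypes: pd.Series) -> pd.DataFrame:
    """Connection density per (interneuron, M-type)."""
    syn = _inh_to_exc(synapses, subclasses, mtypes)
    post_mt = syn["post_cell"].map(mtypes)
    contacted = (syn.assign(mtype=post_mt)
                 .groupby(["pre_cell", "mtype"], observed=True)["post_cell"]
                 .nunique()
                 .unstack(fill_value=0))
    contacted = contacted.reindex(index=subclasses.index,
                                  columns=sorted(mtypes.unique()),
                                  fill_value=0).astype(float)
    return contacted.div(mtypes.value_counts().reindex(contacted.columns), axis=1)


def density_correlation_matrix(densities: pd.DataFrame,
                               presyn_subclass: pd.Series,
                               subclass: str) -> pd.DataFrame:
    """Pearson correlation of connection density between M-types.

    Computed across interneurons of one presynaptic subclass.  Zero-
    variance M-type columns yield NaN entries (reported missing, never
    propagated).
    """
    rows = densities.loc[presyn_subclass[presyn_subclass == subclass].index]
    if len(rows) < 3:
        raise ConnectivityError(
            f"need >= 3 interneurons of subclass {subclass}, got {len(rows)}")
    X = rows.to_numpy(dtype=float)
    sd = X.std(axis=0)
    cols = densities.columns
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        mat.loc[cols[ok], cols[ok]] = sub
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("density correlation: %d zero-variance M-types reported missing",
                    n_dropped)
    return mat


# ---------------------------------------------------------------------------
# PeriTC / DistTC balance
# ---------------------------------------------------------------------------

def peri_dist_balance(per_post: pd.DataFrame, mtypes: pd.Series,
                      n_boot=2000, rng=0, min_cells=5) -> pd.DataFrame:
    """Spearman correlation of PeriTC vs DistTC net input, per M-type.

    ``per_post`` holds per-cell input counts by subclass (from
    :func:`net_input_summary`).  The CI is a percentile bootstrap over
    cells (n=2000); significance is a Holm-Sidak-corrected bootstrap test
    of r != 0 across M-types.
    """
    gen = np.random.default_rng(rng)
    rows = {}
    for mtype in sorted(mtypes.unique()):
        cells = mtypes.index[mtypes == mtype]
        if len(cells) < min_cells:
            raise ConnectivityError(
                f"too few cells in M-type {mtype} ({len(cells)} < {min_cells})")
        x = per_post.reindex(cells).get("PeriTC", pd.Series(0, index=cells)).to_numpy(dtype=float)
        y = per_post.reindex(cells).get("DistTC", pd.Series(0, index=cells)).to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows[mtype] = {"r": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                           "p_boot": np.nan, "flagged": True}
            continue
        r = stats.spearmanr(x, y).statistic
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = gen.integers(0, len(x), size=len(x))
            if np.std(x[idx]) == 0 or np.std(y[idx]) == 0:
                boots[b] = 0.0
            else:
                boots[b] = stats.spearmanr(x[idx], y[idx]).statistic
        lo, hi = np.percentile(boots, [2.5, 97.5])
        p_boot = 2 * min((boots <= 0).mean(), (boots >= 0).mean())
        p_boot = min(1.0, (p_boot * n_boot + 1) / (n_boot + 1))
        rows[mtype] = {"r": float(r), "ci_lo": float(lo), "ci_hi": float(hi),
                       "p_boot": float(p_boot), "flagged": False}
    df = pd.DataFrame.from_dict(rows, orient="index")
    valid = df.index[~df["flagged"]]
    if len(valid):
        p_adj, reject = holm_sidak(df.loc[valid, "p_boot"].to_numpy())
        df.loc[valid, "p_adj"] = p_adj
        df.loc[valid, "significant"] = reject
    return df


# ---------------------------------------------------------------------------
# Output budgets and motif groups
# ---------------------------------------------------------------------------

def output_budget(interneuron, synapses, mtypes: pd.Series) -> pd.Series:
    """Fraction of the cell's excitatory-target synapses per M-type."""
    syn = exclude_autapses(synapses)
    out = syn[(syn["pre_cell"] == interneuron) & syn["post_cell"].isin(mtypes.index)]
    if len(out) == 0:
        raise ConnectivityError(
            f"cell {interneuron} has no synapses onto excitatory column cells")
    shares = out["post_cell"].map(mtypes).value_counts(normalize=True)
    return shares.reindex(sorted(mtypes.unique()), fill_value=0.0)


def budget_table(synapses, subclasses: pd.Series, mtypes: pd.Series) -> pd.DataFrame:
    """Output budgets for every interneuron with excitatory-target output."""
    rows = {}
    for cid in subclasses.index:
        try:
            rows[cid] = output_budget(cid, synapses, mtypes)
        except ConnectivityError:
            logger.warning("cell %d excluded from budgets: no excitatory targets", cid)
    return pd.DataFrame.from_dict(rows, orient="index")


def motif_groups(budgets: pd.DataFrame, mtype_depths: pd.Series,
                 n_runs=500, subsample=0.95, knn=10, resolution=1.3,
                 k_range=(2, 30), seed=0):
    """Consensus-cluster output budgets into motif groups.

    Returns ``(labels, group_output, engine)``: per-interneuron group
    labels ordered by synapse-weighted mean target depth (group 0 most
    superficial), and the per-group mean output fraction per M-type.
    """
    if len(budgets) < 2:
        raise ConnectivityError("need at least 2 interneurons for motif groups")
    engine = ConsensusLeidenClustering(
        n_runs=n_runs, subsample=subsample, n_neighbors=knn,
        resolution=resolution, k_range=k_range, random_state=seed)
    raw = pd.Series(engine.fit_predict(budgets.to_numpy(dtype=float)),
                    index=budgets.index)
    depths = mtype_depths.reindex(budgets.columns).to_numpy(dtype=float)
    order = sorted(
        raw.unique(),
        key=lambda g: float(budgets[raw == g].mean(axis=0) @ depths),
    )
    remap = {g: i for i, g in enumerate(order)}
    labels = raw.map(remap).rename("motif_group")
    group_output = budgets.groupby(labels).mean()
    return labels, group_output, engine


def input_fraction_matrix(synapses, motif_labels: pd.Series,
                          mtypes: pd.Series) -> pd.DataFrame:
    """Each M-type's share of within-column inhibitory input per motif group.

    Columns (M-types) sum to 1 over groups wherever the M-type receives any
    within-column inhibition.
    """
    syn = _inh_to_exc(synapses, motif_labels, mtypes)
    counts = (syn.assign(group=syn["pre_cell"].map(motif_labels),
                         mtype=syn["post_cell"].map(mtypes))
              .groupby(["group", "mtype"], observed=True).size()
              .unstack(fill_value=0)
              .reindex(columns=sorted(mtypes.unique()), fill_value=0)
              .astype(float))
    totals = counts.sum(axis=0)
    return counts.div(totals.where(totals > 0, 1.0), axis=1)


# ---------------------------------------------------------------------------
# Simple statistics
# ---------------------------------------------------------------------------

def spearman_vs_depth(values, depths):
    if len(values) < 3:
        raise ConnectivityError("need >= 3 points for a Spearman correlation")
    res = stats.spearmanr(depths, values)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


def oneway_anova(*groups):
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConnectivityError("ANOVA needs >= 2 groups with >= 2 points each")
    res = stats.f_oneway(*groups)
    return {"F": float(res.statistic), "p": float(res.pvalue)}


def ks_compare(a, b):
    if len(a) == 0 or len(b) == 0:
        raise ConnectivityError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b)
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def welch_ttest(a, b):
    if len(a) < 2 or len(b) < 2:
        raise ConnectivityError("t-test needs >= 2 points per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue)}
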