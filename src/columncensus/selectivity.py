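"""The Selectivity Index: conditional-shuffle null for targeting.

An interneuron's observed synapse count onto each target class is compared
with a null that preserves everything about its output except the target's
identity.  The null's substrate is the *baseline distribution*: every
somatic/dendritic input synapse of every column cell, binned by depth
(20 um bins), target compartment (soma / proximal / distal basal / apical,
plus the pooled "inhibitory" fifth compartment), and target class (M-type,
or pooled inhibitory).  Each shuffle independently redraws every observed
synapse's target class from the baseline's conditional distribution within
its (depth bin, compartment) stratum; the Selectivity Index is the
observed count divided by the shuffle median, with two-sided permutation
p-values Holm-Sidak-corrected within each interneuron across M-types with
non-zero potential connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import holm_sidak
from .tables import exclude_autapses

logger = logging.getLogger(__name__)

INHIBITORY_CLASS = "inhibitory"  # pooled target class for inhibitory cells


class SelectivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Baseline distribution
# ---------------------------------------------------------------------------

@dataclass
class BaselineDistribution:
    """Synapse counts indexed by (depth bin, compartment, target class)."""

    counts: pd.Series            # MultiIndex (depth_bin, compartment, target_class)
    target_classes: list         # M-types + pooled inhibitory
    n_depth_bins: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def stratum(self, depth_bin: int, compartment: str) -> pd.Series:
        try:
            return self.counts.loc[(depth_bin, compartment)]
        except KeyError:
            return pd.Series(dtype=float)


def build_baseline(synapses, cells, mtypes: pd.Series, geometry,
                   compartment_col="compartment") -> BaselineDistribution:
    """Bin every somatic/dendritic input synapse of every column cell.

    ``synapses`` must carry compartment labels (see
    :func:`columncensus.compartments.label_synapses`); rows labeled
    ``none`` (axonal or pruned targets) are excluded.  Synapses onto
    inhibitory cells are pooled into the fifth-compartment stratum with
    target class "inhibitory".
    """
    syn = synapses[synapses[compartment_col] != "none"].copy()
    if len(syn) == 0:
        raise SelectivityError("no compartment-labeled synapses for the baseline")
    target = syn["post_cell"].map(mtypes)
    is_inh = syn["post_class"] == "inhibitory"
    target = target.where(~is_inh, INHIBITORY_CLASS)
    if target.isna().any():
        bad = syn.loc[target.isna(), "post_cell"].unique()
        raise SelectivityError(
            f"synapses onto cells with no M-type or class: {sorted(bad)[:5]}")
    bins = geometry.depth_bin(syn["depth"].to_numpy())
    counts = (pd.DataFrame({"depth_bin": bins,
                            "compartment": syn[compartment_col].to_numpy(),
                            "target_class": target.to_numpy()})
              .groupby(["depth_bin", "compartment", "target_class"])
              .size()
              .astype(float))
    classes = sorted(mtypes.unique()) + [INHIBITORY_CLASS]
    return BaselineDistribution(counts, classes, geometry.n_depth_bins)


# ---------------------------------------------------------------------------
# Conditional shuffles
# ---------------------------------------------------------------------------

def _observed_strata(obs_synapses, geometry, compartment_col="compartment"):
    """(depth bin, compartment) -> synapse count for one interneuron."""
    syn = obs_synapses[obs_synapses[compartment_col] != "none"]
    bins = geometry.depth_bin(syn["depth"].to_numpy())
    return (pd.DataFrame({"depth_bin": bins,
                          "compartment": syn[compartment_col].to_numpy()})
            .groupby(["depth_bin", "compartment"]).size())


def shuffle_outputs(obs_synapses, baseline: BaselineDistribution, geometry,
                    n_shuffles=1000, seed=0,
                    compartment_col="compartment") -> pd.DataFrame:
    """Shuffled per-target-class synapse counts for one interneuron.

    For each shuffle, each observed synapse independently redraws its
    target class from the baseline conditional of its (depth bin,
    compartment) stratum (multinomial, with replacement).  Returns an
    (n_shuffles, n_classes) frame; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    strata = _observed_strata(obs_synapses, geometry, compartment_col)
    classes = baseline.target_classes
    out = np.zeros((n_shuffles, len(classes)))
    pos = {c: j for j, c in enumerate(classes)}
    for (depth_bin, compartment), n_obs in strata.items():
        stratum = baseline.stratum(int(depth_bin), compartment)
        if stratum.sum() == 0:
            raise SelectivityError(
                f"empty baseline stratum (bin {depth_bin}, {compartment})")
        p = (stratum / stratum.sum()).to_numpy()
        draws = rng.multinomial(int(n_obs), p, size=n_shuffles)
        cols = [pos[c] for c in stratum.index]
        out[:, cols] += draws
    return pd.DataFrame(out, columns=classes)


def potential_classes(obs_synapses, baseline: BaselineDistribution, geometry,
                      compartment_col="compartment") -> list:
    """Target classes with nonzero baseline mass in >= 1 observed stratum."""
    strata = _observed_strata(obs_synapses, geometry, compartment_col)
    found = set()
    for (depth_bin, compartment) in strata.index:
        s = baseline.stratum(int(depth_bin), compartment)
        found.update(s.index[s > 0])
    return [c for c in baseline.target_classes if c in found]


# ---------------------------------------------------------------------------
# Selectivity Index
# ---------------------------------------------------------------------------

def selectivity_index(observed_counts: pd.Series, shuffles: pd.DataFrame,
                      potential: list, alpha=0.05) -> pd.DataFrame:
    """SI, permutation p-values and Holm-Sidak correction for one cell.

    SI = observed / median(shuffled); two-sided p uses the add-one
    estimator ``2 * min(P(X <= obs), P(X >= obs))`` capped at 1.  A zero
    shuffle median with nonzero observation reports an infinite SI
    sentinel (finite p).  Only classes with nonzero potential connectivity
    are tested.
    """
    n = len(shuffles)
    rows = {}
    for cls in potential:
        obs = float(observed_counts.get(cls, 0.0))
        sh = shuffles[cls].to_numpy()
        med = float(np.median(sh))
        if med > 0:
            si = obs / med
        elif obs > 0:
            si = np.inf
        else:
            si = 1.0
        p_lo = ((sh <= obs).sum() + 1) / (n + 1)
        p_hi = ((sh >= obs).sum() + 1) / (n + 1)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        rows[cls] = {"observed": obs, "shuffle_median": med, "si": si,
                     "p": p, "n_shuffles": n}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if len(df):
        p_adj, reject = holm_sidak(df["p"].to_numpy(), alpha=alpha)
        df["p_adj"] = p_adj
        df["significant"] = reject
    return df


def cell_selectivity(interneuron, synapses, baseline: BaselineDistribution,
                     geometry, n_shuffles=1000, seed=0,
                     compartment_col="compartment") -> pd.DataFrame:
    """End-to-end SI for one interneuron's within-column output."""
    syn = exclude_autapses(synapses)
    obs = syn[(syn["pre_cell"] == interneuron)
              & (syn[compartment_col] != "none")]
    if len(obs) == 0:
        raise SelectivityError(f"cell {interneuron} has no labeled outputs")
    target = obs["target_class"]
    observed = target.value_counts().astype(float)
    shuffles = shuffle_outputs(obs, baseline, geometry, n_shuffles, seed,
                               compartment_col)
    potential = potential_classes(obs, baseline, geometry, compartment_col)
    out = selectivity_index(observed, shuffles, potential)
    out.insert(0, "pre_cell", interneuron)
    return out


def selectivity_table(synapses, cells, baseline, geometry, mtypes: pd.Series,
                      n_shuffles=1000, seed=0) -> pd.DataFrame:
    """SI for every interneuron with within-column output.

    Adds a ``target_class`` column to the synapse view (M-type of the
    postsynaptic cell, pooled "inhibitory" for inhibitory targets) and
    derives each cell's shuffle seed from the master seed.
    """
    syn = exclude_autapses(synapses).copy()
    tgt = syn["post_cell"].map(mtypes)
    tgt = tgt.where(syn["post_class"] != "inhibitory", INHIBITORY_CLASS)
    syn["target_class"] = tgt
    syn = syn[syn["target_class"].notna()]
    inh = cells[cells["coarse_class"] == "inhibitory"]["cell_id"].astype(int)
    frames = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = {int(c): int(s.generate_state(1)[0] % (2**31))
                  for c, s in zip(sorted(inh), ss.spawn(len(inh)))}
    for cid in sorted(inh):
        sub = syn[syn["pre_cell"] == cid]
        if len(sub) == 0:
            continue
        try:
            frames.append(
                cell_selectivity(cid, syn, baseline, geometry, n_shuffles,
                                 seed=cell_seeds[cid]))
        except SelectivityError as e:
            logger.warning("selectivity skipped for cell %d: %s", cid, e)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames)
    out.index.name = "target_class"
    return out.reset_index()


# ---------------------------------------------------------------------------
# Compartment-preference variant
# ---------------------------------------------------------------------------

def compartment_preference(interneuron, synapses, cells, geometry,
                           mtypes: pd.Series, n_shuffles=1000, seed=0,
                           compartment_col="compartment") -> pd.DataFrame:
    """Per-compartment SI analogue: shuffle compartments, keep M-types.

    The mirrored null preserves the observed depth and target-class
    distributions but redraws each synapse's compartment from the baseline
    conditional of its (depth bin, target class) stratum.
    """
    syn = exclude_autapses(synapses)
    labeled = syn[syn[compartment_col] != "none"].copy()
    tgt = labeled["post_cell"].map(mtypes)
    tgt = tgt.where(labeled["post_class"] != "inhibitory", INHIBITORY_CLASS)
    labeled["target_class"] = tgt
    labeled = labeled[labeled["target_class"].notna()]
    # Baseline over (depth bin, target class, compartment).
    bins = geometry.depth_bin(labeled["depth"].to_numpy())
    counts = (pd.DataFrame({"depth_bin": bins,
                            "target_class": labeled["target_class"].to_numpy(),
                            "compartment": labeled[compartment_col].to_numpy()})
              .groupby(["depth_bin", "target_class", "compartment"])
              .size().astype(float))
    compartments = sorted(labeled[compartment_col].unique())
    obs = labeled[labeled["pre_cell"] == interneuron]
    if len(obs) == 0:
        raise SelectivityError(f"cell {interneuron} has no labeled outputs")
    obs_bins = geometry.depth_bin(obs["depth"].to_numpy())
    strata = (pd.DataFrame({"depth_bin": obs_bins,
                            "target_class": obs["target_class"].to_numpy()})
              .groupby(["depth_bin", "target_class"]).size())
    rng = np.random.default_rng(seed)
    out = np.zeros((n_shuffles, len(compartments)))
    pos = {c: j for j, c in enumerate(compartments)}
    for (depth_bin, target_class), n_obs in strata.items():
        try:
            stratum = counts.loc[(int(depth_bin), target_class)]
        except KeyError:
            raise SelectivityError(
                f"empty baseline stratum (bin {depth_bin}, {target_class})")
        p = (stratum / stratum.sum()).to_numpy()
        draws = rng.multinomial(int(n_obs), p, size=n_shuffles)
        cols = [pos[c] for c in stratum.index]
        out[:, cols] += draws
    shuffles = pd.DataFrame(out, columns=compartments)
    observed = obs[compartment_col].value_counts().astype(float)
    return selectivity_index(observed, shuffles, compartments)


# ---------------------------------------------------------------------------
# Motif-group selectivity matrix
# ---------------------------------------------------------------------------

def group_selectivity_matrix(si_table: pd.DataFrame,
                             motif_labels: pd.Series) -> pd.DataFrame:
    """Median SI per (motif group, M-type), non-significant entries set to 1.

    Infinite SI sentinels are excluded from the medians.  A companion
    boolean frame flags entries whose median came from all-non-significant
    values.
    """
    df = si_table.copy()
    df["group"] = df["pre_cell"].map(motif_labels)
    df = df[df["group"].notna()]
    df.loc[~df["significant"].astype(bool), "si"] = 1.0
    df = df[np.isfinite(df["si"])]
    med = (df.groupby(["group", "target_class"])["si"].median()
           .unstack())
    all_ns = (df.assign(ns=~df["significant"].astype(bool))
              .groupby(["group", "target_class"])["ns"].all()
              .unstack())
    return med, all_ns
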