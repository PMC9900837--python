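# Methods

`columncensus` reimplements, as a tested pipeline, a columnar connectomic
analysis of inhibitory circuitry: given neuron skeletons, a synapse table,
a cell table and a column geometry, it labels dendritic compartments,
classifies inhibitory neurons into connectivity subclasses and excitatory
neurons into morphological types (M-types), discovers motif groups of
interneurons with common targeting, and quantifies cell-type selectivity
against a conditional shuffle null. A synthetic-column generator with
planted ground truth provides the study conditions for every validation.

## Coordinate conventions

The column is straight: depth is the y coordinate minus the pia depth
(depth 0 at the pia, increasing toward white matter), with an optional
rigid rotation about the z axis to flatten a tilted pial surface. All
depth binning is half-open `[lo, hi)` with 20 µm bins by default. External
(out-of-column) presynaptic sources carry the sentinel `pre_cell = -1`.

## Skeleton processing

**Soma collapse.** Vertices within `1.25 · (3V/4π)^{1/3}` of the soma
centroid (V = nucleus volume) *and* connected to it through in-radius
vertices are merged into the root; synapses on merged vertices re-attach
to the root. The padding factor absorbs lopsided cell bodies.

**Axon split.** Synapse flow centrality counts, per vertex, the
(input, output) synapse pairs whose tree path crosses it; it is computed
exactly in one reverse sweep as
`c(v) = I·O − I_above·O_above − Σ_children I_c·O_c` and verified against
brute-force pair-path enumeration. The root is excluded as a split
candidate (its "subtree" is the whole tree); ties at the maximum go to
the candidate closest to the soma. Inhibitory cells split at the flow
maximum unconditionally, the axon being the output-rich side. Excitatory
cells accept the flow split only when the entropy-based segregation index

    S = 1 − Σ_i n_i H_i / (N · H_total),   H = binary input/output entropy,

reaches 0.7; below that, every branch emerging from the 30 µm
soma-adjacent region that is longer than 20 µm with input density below
0.1 synapses/µm is labeled axonal. `S` is clipped to [0, 1] with the
convention `0·ln 0 = 0`; when the overall entropy `H_total` is zero the
index is reported as 0 (no split can demonstrate segregation).

**False-merge pruning.** Terminal dendritic segments with input density
below 0.1 synapses/µm are removed iteratively until a fixed point; pruned
cable and its synapses are excluded from every downstream statistic.

**Apical detection.** Eleven per-vertex features (depths, path and
Euclidean distances, tortuosity, branch counts, angle to vertical) feed a
vertex model that returns P(apical). The model shipped here is a
retrainable random forest fit on planted apical subtrees of the synthetic
column; any external per-vertex probability vector can be substituted —
the contribution is the aggregation, not the weights. Per soma branch,
vertex log-odds are summed and clipped at ±200; branches with a maximum
tip below 50 µm are dropped from the soft-max
`S_i = exp(R_i/50)/Σ_j exp(R_j/50)`; a branch is apical when `R_i > 0`
and `S_i > 0.25` (strict, so four equally weighted branches all fail,
bounding the count at 3).

**Compartments.** Soma = the collapsed root; proximal = dendritic
vertices within 50 µm path distance of the root (boundary inclusive,
configurable); apical = beyond-proximal vertices in an apical branch;
distal basal = the rest. Synapses inherit their vertex's compartment;
synapses onto inhibitory cells form a pooled fifth compartment. Autapses
are kept in tables but excluded from all connectivity statistics.

## Inhibitory subclasses

Six targeting features per interneuron: fraction of output onto
inhibitory cells; fractions of excitatory-target synapses onto soma,
proximal and apical compartments (distal basal is the complement and not
a feature); fraction of synapses in multisynaptic connections (≥ 2
synapses per cell pair); and the fraction of multisynaptic-connection
synapses within 15 µm presynaptic axonal path distance of another synapse
of the same connection ("clumped" — the measure is monotone in the
threshold by construction, checked 5–100 µm). Path distances are
measured on the presynaptic skeleton; if it is absent the code falls back
to Euclidean distance with a warning. A linear discriminant fit on
expert-labeled cells assigns every interneuron to PeriTC / DistTC /
SparTC / InhTC; disagreements with experts are retained as the model's
view. InhTCs are subtyped by the larger of their DistTC vs PeriTC output
share (ties → InhTC^Dist, logged); this argmax rule is deterministic and
equivalent to 2-means on the 1-simplex for separated data.

## Excitatory M-types

29 features per cell: 15 morphology/synapse scalars (tip distances and
tortuosity, input counts, cable length, 97th-percentile radial extent,
synapse size medians and 5–95% dynamic range, synapse depth percentiles,
median per-depth-bin linear density over bins with nonzero cable, median
vertex radius beyond 30 µm); 6 SparsePCA loadings of the row-z-scored
absolute-depth synapse histogram; 5 SparsePCA loadings of a 13-bin
soma-centred (±100 µm) histogram; and 3 SVD loadings of the
branch-count-vs-distance profile (components of 10 µm bands at
30–300 µm). SparsePCA uses penalty 1.0 with a fixed solver seed, and
components are sign-fixed so their largest-magnitude entry is positive.
Missing values (e.g. no somatic synapses) are median-imputed and logged;
columns are z-scored.

**Consensus clustering.** Each run subsamples 95% of cells, builds a
10-nearest-neighbour graph on Euclidean distance in feature space, and
runs Leiden (RB-modularity, resolution 1.3). Co-clustering counts are
normalised by co-sampling counts, removing the bias from cells absent in
~5% of runs. Complete-linkage agglomeration on (1 − co-clustering) is
scanned over cluster numbers 2–30; the scan range extends below 5 because
the engine is reused for planted two- and four-archetype recovery
problems. The cluster number minimises the Davies-Bouldin index, with
the silhouette maximum breaking ties within 1% of the optimum; both
traces are persisted. Partitions containing singleton clusters are
excluded from the scan: a singleton has zero within-cluster scatter,
which degenerates the Davies-Bouldin index and makes it drift downward
as outliers are shaved off (on the default column the silhouette peaks
exactly at the planted cluster number while unrestricted Davies-Bouldin
walks to the scan boundary). If every partition has singletons the
restriction is dropped.

Clusters are named by the modal expert label, with letter suffixes by
ascending median soma depth among same-name clusters; modal ties take the
alphabetically first label with a warning. Per-M-type feature importances
come from one-vs-rest random forests with SMOTE-style minority
oversampling (interpolation between minority nearest neighbours —
implemented in-package), using Mean Decrease in Impurity normalised to
sum to 1.

## Connectivity statistics

Net-input matrices average total synapses from a presynaptic subclass
over all cells of the postsynaptic M-type (zero receivers included).
Connection density is the fraction of an M-type's cells contacted at
least once; Pearson correlations of density between M-types are computed
across PeriTCs and DistTCs separately, with zero-variance M-types
reported missing rather than zero. The perisomatic/dendritic balance is
the per-M-type Spearman correlation of PeriTC vs DistTC input counts with
a 2000-resample percentile bootstrap CI and Holm-Sidak-corrected
bootstrap significance. Output budgets normalise each interneuron's
synapses over excitatory M-types only; motif groups are consensus
clusters of budget vectors (same engine), ordered by synapse-weighted
mean target depth.

## Selectivity Index

The baseline distribution bins every somatic/dendritic input synapse of
every column cell by (depth bin, compartment, target class), the target
class being the M-type for excitatory hosts and pooled "inhibitory" for
inhibitory hosts. For each interneuron, each shuffle independently
redraws every observed synapse's target class from the baseline
conditional of its (depth bin, compartment) stratum — multinomial
sampling with replacement; a without-replacement variant is unnecessary
at the stratum sizes used here. `SI = observed / median(shuffled)` with a
two-sided permutation p-value `2·min(P̂(X ≤ obs), P̂(X ≥ obs))` using the
add-one `(r+1)/(n+1)` estimator, capped at 1, then Holm-Sidak correction
within each interneuron over M-types with non-zero potential connectivity
(baseline mass in ≥ 1 observed stratum). A zero shuffle median with a
nonzero observation reports an infinite SI sentinel (finite p), excluded
from group medians. The default shuffle count is 1000 (configurable;
10,000 is the exhaustive setting). The group selectivity matrix sets
non-significant SIs to 1 before taking the per-(group, M-type) median and
flags entries where every contributing value was non-significant. A
mirrored variant redraws compartments conditional on (depth bin, M-type)
to score compartment preference.

Two properties of the SI worth knowing when interpreting it:

- **Share compression.** For a target with baseline share `p` in the
  relevant strata and true selectivity multiplier `m`,
  `SI ≈ m / (1 − p + m p)`: the index compresses toward 1 as the
  target's share grows. Recovery of a planted multiplier is therefore
  only faithful for rare targets (share of a few percent).
- **Baseline feedback.** The baseline includes the interneurons' own
  synapses. When many interneurons share the same selectivity the null
  inflates by `(E + m̄·I)/(E + I)` (`E` external, `I` inhibitory synapse
  counts, `m̄` their mean effective multiplier), attenuating SI. The
  recovery validation therefore measures against the pre-placement
  (external-input) baseline — the distribution the planted multipliers
  are defined against; the pipeline default remains the full baseline.

## Synthetic column

The generator is the package's study-condition definition, not a fixture.
Excitatory cells grow as recursive bifurcating basal trees (Gaussian
segment lengths, bounded angular jitter) plus an optional apical trunk
toward the pia with a tuft fan; inhibitory cells get small multipolar
dendrites and a sparse polyline axon (2 µm vertex spacing) spanning a
configurable depth window, so presynaptic path distances are
well-defined. Input synapses are placed per edge at the M-type's linear
density with log-normal sizes; densities default to 0.35–1.0
synapses/µm, the realistic cortical range, which also keeps every type
safely above the 0.1/µm false-merge pruning threshold. Somata land
uniformly in each type's depth range; nucleus volumes are chosen so the
soma-collapse radius stays inside the 12 µm dendritic stem, making
collapse an exercised no-op on synthetic columns and guaranteeing that
generator-side compartment labels equal pipeline labels given true apical
roots (collapse itself is unit-tested on dedicated fixtures).

Inhibitory outputs are placed in two steps: a compartment is drawn from
the cell's preference vector; then an actual baseline input slot is drawn
from the chosen compartment within the axon's depth window (aligned to
whole depth bins) with probability proportional to the host M-type's
selectivity multiplier. With multipliers ≡ 1 this law is exactly the
shuffle null, which is what makes the calibration test sharp. A
synapses-per-connection count `k ~ 1 + Poisson(mean − 1)` places the
synapses on the target's nearest same-compartment vertices, with
presynaptic vertices advanced along the axon by exponential steps at the
clump scale (5 µm default, so most within-connection pairs fall inside
the 15 µm clump threshold). Every cell draws from an independent
substream keyed by `(seed, kind, cell)`, so adding cells never perturbs
existing ones; identical seeds give byte-identical tables.

The default column holds 188 excitatory cells in 8 archetypes (L2a/b,
L3a, L4a/b, L5a/b, L6a — separated by depth range, density, size
statistics, branch counts, radius, and apical geometry) and 40
interneurons in the four subclasses (PeriTC and DistTC depth-stratified;
InhTC split 5:3 into DistTC- and PeriTC-preferring subtypes with larger
synapses onto preferred targets), ~140k synapses, generating in a few
seconds. Dedicated specs exist for calibration (200 null interneurons),
selectivity recovery, and motif archetypes.

**Calibration columns use single-synapse connections.** Multisynaptic
connections place `k` same-target synapses per draw, overdispersing
per-M-type counts by roughly `E[k²]/E[k]` relative to the per-synapse
independent-redraw null; this is a property of the shuffle method itself
(shared with any per-synapse permutation null), so the calibration of the
p-value machinery is measured where its independence assumption holds.

**Recovery columns plant each multiplier on its own rare M-type.** The
two error sources pull oppositely in the target's share `p`: compression
(matters for m > 1) grows with `p`, counting noise (matters for m < 1)
grows as `p` shrinks. Suppression (0.5) targets a ~5% type; enhancement
(4) a ~2% type; budgets (1200 synapses/cell, 24 cells per cohort) are
sized so shuffle medians stay well clear of integer granularity — a
power consideration, fixed before measuring.

## What the synthetic data does not emulate

Real EM reconstructions bring truncated and incompletely proofread
arbors, detached spines, soma-collapse geometry that actually merges
cable, slanted column geometry, synapse-detection errors, and inhibitory
populations far more heterogeneous than four planted profiles. Passing
recovery tests therefore demonstrates the correctness and calibration of
the *computations* under their stated assumptions — not that the
biological conclusions would survive those artifacts. In particular the
M-type archetypes are deliberately well-separated; consensus clustering
on real columns needs the persisted validation traces (Davies-Bouldin,
silhouette, co-clustering) to be inspected rather than trusted.

## Numerical and design choices

- Welch's t-test is the default for two-sample comparisons (classical
  Student's available by flag).
- Bootstrap CIs are percentile-based (1000 resamples for synapse-size
  medians, 2000 for the balance correlations).
- Tortuosity and angle at the root default to 1 and 0 (undefined ratios).
- Artifacts are CSV/JSON/npy; the manifest records a SHA-256 per file and
  the full pipeline is byte-deterministic given a seed.
- Cluster-number scan, resolution, neighbour count, subsample fraction,
  shuffle count and clump threshold are all exposed as parameters with
  the defaults above.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` regenerates everything from the seed: 100 random
trees (≤ 200 vertices) for the flow-centrality oracle; 100 mixed neurons
(200 synapses each) for the segregation limits; the 200-interneuron
calibration column and the 72-interneuron recovery column at 1000
shuffles; the default column for subclass recovery (~10 held-out cells),
M-type recovery/stability (50 consensus runs, two master seeds), and
clump monotonicity; the 40-interneuron motif column; and a double full
pipeline run for byte-determinism. The whole script completes in a few
minutes on one CPU.
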