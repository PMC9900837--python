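"""Synthetic cortical column with planted ground truth.

The generator emulates the statistical structure every downstream stage
assumes: layered soma distributions, per-M-type dendritic trees with
type-specific synapse densities and log-normal sizes, and inhibitory axons
placing multisynaptic, spatially clumped outputs with configurable
compartment preferences and per-M-type selectivity multipliers.

Inhibitory output placement is a two-step process.  (1) A target is chosen
by sampling an actual dendritic/somatic input slot from the column's
baseline, restricted to the drawn compartment and to depth bins reachable
by the axon, with probability proportional to the target M-type's
selectivity multiplier.  Because slots are drawn uniformly within each
(depth bin, compartment) stratum, a multiplier of 1 everywhere makes the
generated connectivity exactly exchangeable with the selectivity module's
shuffle null.  (2) A synapses-per-connection count is drawn and the
synapses are placed on the target near the chosen slot, with presynaptic
vertices laid along the axon so within-connection path spacing follows the
clump scale.

Every cell draws from an independent random substream keyed by
``(seed, kind, index)``, so adding a cell does not perturb others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp_mod
from .geometry import ColumnGeometry
from .skeleton import (
    COMPARTMENT_NAMES,
    SWC_AXON,
    SWC_DENDRITE,
    SWC_SOMA,
    Skeleton,
)
from .tables import EXTERNAL

SUBCLASSES = ("PeriTC", "DistTC", "SparTC", "InhTC")

# Stream tags for per-cell substreams.
_EXC, _INH, _PLACE = 1, 2, 3


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class MTypeSpec:
    """Morphology and input-synapse parameters of one excitatory M-type."""

    name: str
    layer_label: str            # coarse expert label used for cluster naming
    n_cells: int
    depth_range: tuple[float, float]
    basal_branch_count: int = 4
    basal_levels: int = 1       # bifurcation generations per primary branch
    basal_segment_length: float = 45.0   # um, mean unbranched segment
    apical: bool = False
    apical_trunk_length: float = 0.0
    tuft_branches: int = 3
    tuft_breadth: float = 60.0
    tortuosity: float = 0.15    # angular jitter per growth step
    input_density: float = 0.25          # synaptic inputs per um of dendrite
    soma_input_count: int = 50
    size_median: float = 450.0           # arbitrary units, log-normal median
    size_sigma: float = 0.4
    dendrite_radius: float = 0.35        # um, mean vertex radius
    nucleus_volume: float = 1800.0       # um^3


@dataclass
class InterneuronGroupSpec:
    """Parameters for a group of inhibitory cells sharing a targeting style."""

    subclass: str
    n_cells: int
    depth_range: tuple[float, float]
    output_budget: int = 300
    # Preference over {soma, proximal, distal_basal, apical, inhibitory}.
    compartment_prefs: dict = field(default_factory=dict)
    mtype_multipliers: dict = field(default_factory=dict)    # default 1
    inh_subclass_weights: dict = field(default_factory=dict)  # default 1
    syn_per_connection_mean: float = 1.0
    clump_scale: float = 5.0     # um, within-connection axonal spacing
    axial_span: float = 400.0    # um, depth extent of the axon
    input_density: float = 0.6
    size_median: float = 400.0
    size_sigma: float = 0.4
    preferred_size_boost: float = 1.0   # size multiplier onto preferred inh subclass
    nucleus_volume: float = 1100.0
    inhtc_subtype: str | None = None    # planted InhTC_Dist / InhTC_Peri
    name: str = ""


@dataclass
class ColumnSpec:
    seed: int
    pia_depth: float = 0.0
    wm_depth: float = 800.0
    layer_boundaries: tuple[float, ...] = (100.0, 280.0, 420.0, 600.0)
    depth_bin_width: float = 20.0
    column_width: float = 100.0
    mtypes: list[MTypeSpec] = field(default_factory=list)
    interneurons: list[InterneuronGroupSpec] = field(default_factory=list)
    expert_label_fraction: float = 0.7   # inhibitory cells with expert labels
    vertex_step: float = 4.0             # dendritic vertex spacing, um
    axon_step: float = 2.0               # axonal vertex spacing, um
    stem_length: float = 12.0            # root-to-first-vertex distance, um

    def geometry(self) -> ColumnGeometry:
        return ColumnGeometry(
            self.pia_depth, self.wm_depth, self.layer_boundaries,
            rotation_angle=0.0, depth_bin_width=self.depth_bin_width,
        )

    def validate(self):
        for g in self.interneurons:
            s = sum(g.compartment_prefs.values())
            if abs(s - 1.0) > 1e-9:
                raise SpecError(f"compartment prefs of {g.subclass} sum to {s}")
            if any(m <= 0 for m in g.mtype_multipliers.values()):
                raise SpecError("multipliers must be > 0")
        for m in self.mtypes:
            if m.input_density <= 0:
                raise SpecError(f"input density must be > 0 for {m.name}")
            r = comp_mod.soma_collapse_radius(m.nucleus_volume)
            if r >= self.stem_length:
                raise SpecError(
                    f"infeasible spec for M-type {m.name}: soma-collapse radius "
                    f"{r:.1f} um reaches the first dendritic vertex"
                )


@dataclass
class GroundTruth:
    """Planted labels backing recovery tests (synthetic columns only)."""

    mtype: dict = field(default_factory=dict)          # exc cell -> M-type
    subclass: dict = field(default_factory=dict)       # inh cell -> subclass
    inhtc_subtype: dict = field(default_factory=dict)  # inh cell -> subtype
    motif_archetype: dict = field(default_factory=dict)
    apical_roots: dict = field(default_factory=dict)   # cell -> [vertex]
    axon_vertices: dict = field(default_factory=dict)  # inh cell -> [vertex]
    multipliers: dict = field(default_factory=dict)    # inh cell -> {mtype: m}

    def to_json(self, path):
        data = {
            k: {str(c): v for c, v in getattr(self, k).items()}
            for k in ("mtype", "subclass", "inhtc_subtype", "motif_archetype",
                      "apical_roots", "axon_vertices", "multipliers")
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        data = json.loads(Path(path).read_text())
        gt = cls()
        for k in ("mtype", "subclass", "inhtc_subtype", "motif_archetype",
                  "apical_roots", "axon_vertices", "multipliers"):
            setattr(gt, k, {int(c): v for c, v in data.get(k, {}).items()})
        return gt


# ---------------------------------------------------------------------------
# Default specs (the standard study conditions)
# ---------------------------------------------------------------------------

def default_mtypes() -> list[MTypeSpec]:
    """Eight well-separated M-type archetypes spanning the layers."""
    return [
        MTypeSpec("L2a", "L2", 26, (110, 190), basal_branch_count=5,
                  basal_segment_length=35, input_density=1.0,
                  soma_input_count=65, size_median=520, size_sigma=0.45,
                  dendrite_radius=0.42, nucleus_volume=2000),
        MTypeSpec("L2b", "L2", 22, (110, 190), basal_branch_count=3,
                  basal_segment_length=30, input_density=0.55,
                  soma_input_count=30, size_median=340, size_sigma=0.30,
                  dendrite_radius=0.22, nucleus_volume=1400),
        MTypeSpec("L3a", "L3", 24, (190, 280), basal_branch_count=4,
                  basal_segment_length=45, apical=True, apical_trunk_length=150,
                  input_density=0.80, soma_input_count=55, size_median=500,
                  size_sigma=0.45, dendrite_radius=0.38, nucleus_volume=1900),
        MTypeSpec("L4a", "L4", 28, (280, 420), basal_branch_count=5,
                  basal_segment_length=40, apical=True, apical_trunk_length=100,
                  input_density=0.90, soma_input_count=70, size_median=460,
                  size_sigma=0.40, dendrite_radius=0.36, nucleus_volume=1800),
        MTypeSpec("L4b", "L4", 20, (280, 420), basal_branch_count=3,
                  basal_segment_length=35, apical=True, apical_trunk_length=70,
                  input_density=0.50, soma_input_count=35, size_median=350,
                  size_sigma=0.30, dendrite_radius=0.22, nucleus_volume=1300),
        MTypeSpec("L5a", "L5", 24, (420, 600), basal_branch_count=5,
                  basal_segment_length=45, apical=True, apical_trunk_length=330,
                  tuft_breadth=90, input_density=0.80, soma_input_count=85,
                  size_median=650, size_sigma=0.50, dendrite_radius=0.60,
                  nucleus_volume=2500),
        MTypeSpec("L5b", "L5", 16, (420, 600), basal_branch_count=2,
                  basal_segment_length=70, input_density=0.35,
                  soma_input_count=14, size_median=280, size_sigma=0.25,
                  dendrite_radius=0.18, nucleus_volume=1200),
        MTypeSpec("L6a", "L6", 28, (600, 760), basal_branch_count=4,
                  basal_segment_length=40, apical=True, apical_trunk_length=160,
                  input_density=0.65, soma_input_count=45, size_median=430,
                  size_sigma=0.40, dendrite_radius=0.30, nucleus_volume=1700),
    ]


def default_interneurons() -> list[InterneuronGroupSpec]:
    """Four connectivity subclasses with near-disjoint targeting profiles."""
    groups = []
    # Perisomatic-targeting basket-like cells, stratified by depth so motif
    # structure emerges from axon placement.
    for i, (lo, hi) in enumerate([(120, 260), (280, 420), (440, 620)]):
        groups.append(InterneuronGroupSpec(
            "PeriTC", 4, (lo, hi), output_budget=320,
            compartment_prefs={"soma": 0.52, "proximal": 0.32,
                               "distal_basal": 0.06, "apical": 0.02,
                               "inhibitory": 0.08},
            syn_per_connection_mean=3.0, clump_scale=5.0, axial_span=240,
            name=f"PeriTC_{i}"))
    for i, (lo, hi) in enumerate([(120, 260), (280, 420), (440, 620)]):
        groups.append(InterneuronGroupSpec(
            "DistTC", 4, (lo, hi), output_budget=300,
            compartment_prefs={"soma": 0.02, "proximal": 0.08,
                               "distal_basal": 0.52, "apical": 0.28,
                               "inhibitory": 0.10},
            syn_per_connection_mean=2.5, clump_scale=6.0, axial_span=300,
            name=f"DistTC_{i}"))
    groups.append(InterneuronGroupSpec(
        "SparTC", 8, (120, 500), output_budget=150,
        compartment_prefs={"soma": 0.05, "proximal": 0.20,
                           "distal_basal": 0.45, "apical": 0.20,
                           "inhibitory": 0.10},
        syn_per_connection_mean=1.0, axial_span=420, name="SparTC"))
    groups.append(InterneuronGroupSpec(
        "InhTC", 5, (140, 420), output_budget=160,
        compartment_prefs={"soma": 0.02, "proximal": 0.03,
                           "distal_basal": 0.08, "apical": 0.02,
                           "inhibitory": 0.85},
        inh_subclass_weights={"DistTC": 10.0, "PeriTC": 0.5, "SparTC": 0.5,
                              "InhTC": 0.5},
        syn_per_connection_mean=3.2, clump_scale=5.0, axial_span=380,
        preferred_size_boost=1.45, inhtc_subtype="InhTC_Dist", name="InhTC_d"))
    groups.append(InterneuronGroupSpec(
        "InhTC", 3, (140, 420), output_budget=160,
        compartment_prefs={"soma": 0.02, "proximal": 0.03,
                           "distal_basal": 0.08, "apical": 0.02,
                           "inhibitory": 0.85},
        inh_subclass_weights={"PeriTC": 10.0, "DistTC": 0.5, "SparTC": 0.5,
                              "InhTC": 0.5},
        syn_per_connection_mean=3.0, clump_scale=5.0, axial_span=380,
        preferred_size_boost=1.6, inhtc_subtype="InhTC_Peri", name="InhTC_p"))
    return groups


def default_column_spec(seed: int = 0) -> ColumnSpec:
    """The standard ~250-cell, ~40k-synapse synthetic column."""
    return ColumnSpec(seed=seed, mtypes=default_mtypes(),
                      interneurons=default_interneurons())


def calibration_column_spec(seed: int = 0, n_interneurons: int = 200,
                            output_budget: int = 150) -> ColumnSpec:
    """Selectivity-free column: multipliers 1, single-synapse connections.

    Used to check that the Selectivity Index p-values are calibrated; see
    the methods note for why connections carry one synapse here.
    """
    mtypes = []
    for m in default_mtypes():
        m.n_cells = max(8, m.n_cells // 2)
        mtypes.append(m)
    inter = [InterneuronGroupSpec(
        "SparTC", n_interneurons, (130, 650), output_budget=output_budget,
        compartment_prefs={"soma": 0.10, "proximal": 0.25,
                           "distal_basal": 0.45, "apical": 0.20,
                           "inhibitory": 0.0},
        syn_per_connection_mean=1.0, axial_span=320, name="null")]
    return ColumnSpec(seed=seed, mtypes=mtypes, interneurons=inter)


def recovery_column_spec(seed: int = 0, multipliers=(0.5, 2.0, 4.0),
                         n_per_multiplier: int = 24,
                         output_budget: int = 1200) -> ColumnSpec:
    """Column with multipliers planted on rare, spatially intermingled
    M-types, for Selectivity-Index recovery tests.

    Each multiplier cohort targets its own rare M-type, because the two
    error sources of SI recovery pull in opposite directions with the
    target's baseline share p: the SI compresses toward 1 as p grows
    (SI = m / (1 - p + m p)), which matters for m > 1, while counting
    noise on the observed synapse number grows as p shrinks, which matters
    for m < 1.  Suppression (m = 0.5) is therefore planted on the most
    abundant rare type (~5% share) and the strongest enhancement (m = 4)
    on the rarest (~2%); the output budget is sized so shuffle medians stay
    well clear of integer granularity.
    """
    abundant = [
        MTypeSpec(nm, "L4", 34, (280, 420), basal_branch_count=4,
                  basal_segment_length=50, input_density=d,
                  soma_input_count=60, size_median=450, nucleus_volume=1700)
        for nm, d in zip(["L4x", "L4y", "L4z"], (1.20, 1.00, 0.80))
    ]
    # Rare targets, most abundant first (planted shares ~5%, ~3.5%, ~2%).
    rare = [
        MTypeSpec("L4r1", "L4", 20, (280, 420), basal_branch_count=3,
                  basal_segment_length=45, input_density=0.38,
                  soma_input_count=25, size_median=380, nucleus_volume=1400),
        MTypeSpec("L4r2", "L4", 16, (280, 420), basal_branch_count=3,
                  basal_segment_length=45, input_density=0.33,
                  soma_input_count=22, size_median=380, nucleus_volume=1400),
        MTypeSpec("L4r3", "L4", 14, (280, 420), basal_branch_count=3,
                  basal_segment_length=45, input_density=0.20,
                  soma_input_count=20, size_median=380, nucleus_volume=1400),
    ]
    inter = []
    for m, rare_spec in zip(sorted(multipliers), rare):
        inter.append(InterneuronGroupSpec(
            "DistTC", n_per_multiplier, (300, 400),
            output_budget=output_budget,
            compartment_prefs={"soma": 0.10, "proximal": 0.35,
                               "distal_basal": 0.55, "apical": 0.0,
                               "inhibitory": 0.0},
            mtype_multipliers={rare_spec.name: float(m)},
            syn_per_connection_mean=1.0, axial_span=300,
            name=f"mult_{m}"))
    return ColumnSpec(seed=seed, mtypes=abundant + rare, interneurons=inter)


def motif_column_spec(seed: int = 0, n_per_archetype: int = 10,
                      output_budget: int = 250) -> ColumnSpec:
    """Four planted targeting archetypes for motif-group recovery."""
    mtypes = default_mtypes()
    archetypes = [
        ("layer2", (140, 230), {"L2a": 6.0, "L2b": 6.0}),
        ("layer4", (300, 400), {"L4a": 6.0, "L4b": 6.0}),
        ("layer5", (450, 570), {"L5a": 6.0, "L5b": 6.0}),
        ("layer6", (620, 740), {"L6a": 6.0}),
    ]
    inter = []
    for name, (lo, hi), mult in archetypes:
        inter.append(InterneuronGroupSpec(
            "PeriTC", n_per_archetype, (lo, hi), output_budget=output_budget,
            compartment_prefs={"soma": 0.30, "proximal": 0.30,
                               "distal_basal": 0.30, "apical": 0.10,
                               "inhibitory": 0.0},
            mtype_multipliers=mult, syn_per_connection_mean=2.0,
            clump_scale=5.0, axial_span=220, name=name))
    return ColumnSpec(seed=seed, mtypes=mtypes, interneurons=inter)


# ---------------------------------------------------------------------------
# Skeleton growth
# ---------------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


class _TreeBuilder:
    def __init__(self, root_pos):
        self.pos = [np.asarray(root_pos, dtype=float)]
        self.parent = [-1]
        self.label = [SWC_SOMA]
        self.radius = [5.0]

    def add(self, position, parent, label, radius):
        self.pos.append(np.asarray(position, dtype=float))
        self.parent.append(parent)
        self.label.append(label)
        self.radius.append(radius)
        return len(self.pos) - 1

    def build(self) -> Skeleton:
        return Skeleton(np.array(self.pos), np.array(self.parent),
                        np.array(self.radius), np.array(self.label))


def _grow_segment(tb, parent, direction, length, step, jitter, rng, radius,
                  label=SWC_DENDRITE, y_clip=(2.0, 1e9)):
    """Grow one unbranched run of vertices; returns the distal vertex."""
    n_steps = max(1, int(round(length / step)))
    pos = tb.pos[parent].copy()
    d = _unit(np.asarray(direction, dtype=float))
    v = parent
    for _ in range(n_steps):
        d = _unit(d + jitter * rng.normal(size=3))
        pos = pos + d * step
        pos[1] = min(max(pos[1], y_clip[0]), y_clip[1])
        v = tb.add(pos, v, label, max(0.05, radius * (1 + 0.1 * rng.normal())))
    return v


def _grow_basal_tree(tb, parent, direction, spec: MTypeSpec, step, rng, wm):
    """Recursive bifurcating branch process with Gaussian segment lengths."""
    stack = [(parent, direction, spec.basal_levels)]
    while stack:
        par, d, level = stack.pop()
        length = max(step, rng.normal(spec.basal_segment_length,
                                      0.15 * spec.basal_segment_length))
        tip = _grow_segment(tb, par, d, length, step, spec.tortuosity, rng,
                            spec.dendrite_radius, y_clip=(2.0, wm - 2.0))
        if level > 0:
            for sign in (-1.0, 1.0):
                perp = _unit(np.cross(d, rng.normal(size=3)))
                child_dir = _unit(d + sign * 0.7 * perp)
                stack.append((tip, child_dir, level - 1))


def grow_excitatory_skeleton(spec: MTypeSpec, soma_pos, rng, column: ColumnSpec):
    """One excitatory cell: multipolar basal tree plus optional apical."""
    tb = _TreeBuilder(soma_pos)
    step = column.vertex_step
    wm = column.wm_depth
    apical_root = None
    for b in range(spec.basal_branch_count):
        phi = 2 * math.pi * (b + rng.random() * 0.5) / spec.basal_branch_count
        # Downward/outward initial direction.
        d = _unit(np.array([math.cos(phi), 0.45 + 0.3 * rng.random(),
                            math.sin(phi)]))
        stem = tb.add(tb.pos[0] + d * column.stem_length, 0, SWC_DENDRITE,
                      spec.dendrite_radius)
        _grow_basal_tree(tb, stem, d, spec, step, rng, wm)
    if spec.apical and spec.apical_trunk_length > 0:
        up = np.array([0.0, -1.0, 0.0])
        apical_root = tb.add(tb.pos[0] + up * column.stem_length, 0,
                             SWC_DENDRITE, spec.dendrite_radius * 1.4)
        trunk_tip = _grow_segment(
            tb, apical_root, up, spec.apical_trunk_length, step,
            0.05, rng, spec.dendrite_radius * 1.4)
        for t in range(spec.tuft_branches):
            phi = 2 * math.pi * t / spec.tuft_branches
            d = _unit(np.array([math.cos(phi) * 0.8, -0.5, math.sin(phi) * 0.8]))
            _grow_segment(tb, trunk_tip, d, spec.tuft_breadth, step,
                          spec.tortuosity, rng, spec.dendrite_radius * 0.8)
    return tb.build(), apical_root


def grow_inhibitory_skeleton(group: InterneuronGroupSpec, soma_pos, rng,
                             column: ColumnSpec):
    """One interneuron: small multipolar dendrite plus a depth-spanning axon.

    The axon is a sparse polyline (one ascending and one descending chain
    from a base vertex near the soma) so presynaptic path distances for the
    clumped-synapse statistic are well-defined.
    """
    tb = _TreeBuilder(soma_pos)
    step = column.vertex_step
    for b in range(4):
        phi = 2 * math.pi * (b + 0.3 * rng.random()) / 4
        d = _unit(np.array([math.cos(phi), rng.normal(0, 0.5), math.sin(phi)]))
        stem = tb.add(tb.pos[0] + d * column.stem_length, 0, SWC_DENDRITE, 0.4)
        _grow_segment(tb, stem, d, max(step, rng.normal(70, 10)), step, 0.2,
                      rng, 0.4, y_clip=(2.0, column.wm_depth - 2.0))
    # Axon: base vertex offset laterally, then chains up and down in depth.
    soma_depth = soma_pos[1]
    half = group.axial_span / 2.0
    d_lo = max(4.0, soma_depth - half)
    d_hi = min(column.wm_depth - 4.0, soma_depth + half)
    base = tb.add(tb.pos[0] + np.array([4.0, 0.0, 0.0]), 0, SWC_AXON, 0.2)
    axon_vertices = [base]
    chains = []
    for target_depth in (d_lo, d_hi):
        depths = np.arange(soma_depth, target_depth,
                           column.axon_step * np.sign(target_depth - soma_depth))
        chain = [base]
        par = base
        x, z = soma_pos[0] + 4.0, soma_pos[2]
        for dep in depths[1:]:
            par = tb.add(np.array([x, dep, z]), par, SWC_AXON, 0.2)
            chain.append(par)
            axon_vertices.append(par)
        chains.append(np.array(chain, dtype=np.int64))
    return tb.build(), np.array(axon_vertices, dtype=np.int64), chains


# ---------------------------------------------------------------------------
# Column generation
# ---------------------------------------------------------------------------

def _rng_for(seed, kind, index):
    return np.random.default_rng(np.random.SeedSequence((int(seed), kind, int(index))))


def _lognormal_sizes(rng, n, median, sigma):
    return np.exp(rng.normal(math.log(median), sigma, size=n))


@dataclass
class _CellBuild:
    cell_id: int
    skeleton: Skeleton
    coarse_class: str
    mtype: str | None = None
    subclass: str | None = None
    apical_root: int | None = None
    axon_vertices: np.ndarray | None = None
    axon_chains: list | None = None
    group: InterneuronGroupSpec | None = None
    index_in_group: int = 0
    nucleus_volume: float = 1500.0
    compartment_name: np.ndarray | None = None  # per-vertex label strings


def _rule_based_compartments(build: _CellBuild) -> np.ndarray:
    """Per-vertex compartment names via the pipeline's assignment rule."""
    skel = build.skeleton
    roots = [build.apical_root] if build.apical_root is not None else []
    codes = comp_mod.assign_compartments(skel, roots)
    names = np.array([COMPARTMENT_NAMES[c] for c in codes], dtype=object)
    return names


def generate_column(spec: ColumnSpec):
    """Generate the column: cells, skeletons, synapses, geometry, truth.

    Returns ``(cells, skeletons, synapses, geometry, ground_truth)`` with
    table schemas matching :mod:`columncensus.tables`.  Identical seeds give
    byte-identical outputs.
    """
    spec.validate()
    geometry = spec.geometry()
    builds: list[_CellBuild] = []
    truth = GroundTruth()
    next_id = 1

    # --- excitatory cells -------------------------------------------------
    for mi, mt in enumerate(spec.mtypes):
        for ci in range(mt.n_cells):
            rng = _rng_for(spec.seed, _EXC, next_id)
            soma = np.array([
                rng.uniform(0, spec.column_width),
                rng.uniform(*mt.depth_range),
                rng.uniform(0, spec.column_width),
            ])
            skel, apical_root = grow_excitatory_skeleton(mt, soma, rng, spec)
            b = _CellBuild(next_id, skel, "excitatory", mtype=mt.name,
                           apical_root=apical_root,
                           nucleus_volume=mt.nucleus_volume * (1 + 0.08 * rng.normal()))
            builds.append(b)
            truth.mtype[next_id] = mt.name
            truth.apical_roots[next_id] = (
                [int(apical_root)] if apical_root is not None else [])
            next_id += 1

    # --- inhibitory cells -------------------------------------------------
    for gi, grp in enumerate(spec.interneurons):
        for ci in range(grp.n_cells):
            rng = _rng_for(spec.seed, _INH, next_id)
            soma = np.array([
                rng.uniform(0, spec.column_width),
                rng.uniform(*grp.depth_range),
                rng.uniform(0, spec.column_width),
            ])
            skel, axon_verts, chains = grow_inhibitory_skeleton(grp, soma, rng, spec)
            b = _CellBuild(next_id, skel, "inhibitory", subclass=grp.subclass,
                           axon_vertices=axon_verts, axon_chains=chains,
                           group=grp, index_in_group=ci,
                           nucleus_volume=grp.nucleus_volume * (1 + 0.08 * rng.normal()))
            builds.append(b)
            truth.subclass[next_id] = grp.subclass
            if grp.inhtc_subtype:
                truth.inhtc_subtype[next_id] = grp.inhtc_subtype
            truth.motif_archetype[next_id] = grp.name or grp.subclass
            truth.axon_vertices[next_id] = [int(v) for v in axon_verts]
            truth.apical_roots[next_id] = []
            truth.multipliers[next_id] = dict(grp.mtype_multipliers)
            next_id += 1

    # --- baseline input synapses (external drive) ---------------------------
    syn_rows = {k: [] for k in ("pre_cell", "post_cell", "x", "y", "z", "size",
                                "pre_vertex", "post_vertex")}

    def emit(pre_cell, post_cell, pos, size, pre_vertex, post_vertex):
        syn_rows["pre_cell"].append(pre_cell)
        syn_rows["post_cell"].append(post_cell)
        syn_rows["x"].append(pos[0]); syn_rows["y"].append(pos[1])
        syn_rows["z"].append(pos[2])
        syn_rows["size"].append(size)
        syn_rows["pre_vertex"].append(pre_vertex)
        syn_rows["post_vertex"].append(post_vertex)

    for b in builds:
        rng = _rng_for(spec.seed, _PLACE, b.cell_id)
        skel = b.skeleton
        b.compartment_name = _rule_based_compartments(b)
        if b.coarse_class == "excitatory":
            mt = next(m for m in spec.mtypes if m.name == b.mtype)
            density, soma_n = mt.input_density, mt.soma_input_count
            med, sig = mt.size_median, mt.size_sigma
        else:
            grp = b.group
            density, soma_n = grp.input_density, 25
            med, sig = grp.size_median, grp.size_sigma
        dend = skel.dendrite_mask()
        el = skel.edge_lengths
        counts = rng.poisson(density * el)
        counts[~dend] = 0
        counts[skel.root] = soma_n
        verts = np.repeat(np.arange(skel.n_vertices), counts)
        if len(verts) == 0:
            raise SpecError(f"no input synapses generated for cell {b.cell_id}")
        sizes = _lognormal_sizes(rng, len(verts), med, sig)
        for v, s in zip(verts, sizes):
            emit(EXTERNAL, b.cell_id, skel.positions[v], float(s), EXTERNAL, int(v))

    # --- baseline slot index for output placement ---------------------------
    base = pd.DataFrame(syn_rows)
    depths = geometry.depth(base[["x", "y", "z"]].to_numpy())
    bins = geometry.depth_bin(depths)
    by_id = {b.cell_id: b for b in builds}
    comp_of_slot = np.empty(len(base), dtype=object)
    key_of_slot = np.empty(len(base), dtype=object)  # mtype or inh subclass
    is_inh_host = np.zeros(len(base), dtype=bool)
    post = base["post_cell"].to_numpy()
    pv = base["post_vertex"].to_numpy()
    for cid, idx in base.groupby("post_cell").groups.items():
        host = by_id[int(cid)]
        idx = np.asarray(idx)
        if host.coarse_class == "inhibitory":
            comp_of_slot[idx] = "inhibitory"
            key_of_slot[idx] = host.subclass
            is_inh_host[idx] = True
        else:
            comp_of_slot[idx] = host.compartment_name[pv[idx].astype(np.int64)]
            key_of_slot[idx] = host.mtype
    slot_depth = depths

    comp_index = {}
    for comp in ("soma", "proximal", "distal_basal", "apical", "inhibitory"):
        idx = np.flatnonzero(comp_of_slot == comp)
        order = idx[np.argsort(bins[idx], kind="stable")]
        comp_index[comp] = (order, bins[order])

    # Per-(cell, compartment) vertex pools for multisynapse placement.
    vertex_pool = {}
    for b in builds:
        if b.coarse_class == "excitatory":
            for comp in ("soma", "proximal", "distal_basal", "apical"):
                vv = np.flatnonzero(b.compartment_name == comp)
                if len(vv):
                    vertex_pool[(b.cell_id, comp)] = vv
        else:
            vv = np.flatnonzero(b.skeleton.dendrite_mask())
            vertex_pool[(b.cell_id, "inhibitory")] = vv

    # --- inhibitory output placement ----------------------------------------
    comps5 = ("soma", "proximal", "distal_basal", "apical", "inhibitory")
    for b in builds:
        if b.coarse_class != "inhibitory":
            continue
        grp = b.group
        rng = _rng_for(spec.seed, _PLACE, 10_000_000 + b.cell_id)
        skel = b.skeleton
        soma_depth = float(geometry.depth(skel.positions[skel.root][None, :])[0])
        half = grp.axial_span / 2.0
        bw = geometry.depth_bin_width
        lo_bin = int(math.ceil(max(0.0, soma_depth - half) / bw))
        hi_bin = int(math.floor(min(geometry.wm_depth, soma_depth + half) / bw))
        hi_bin = max(hi_bin, lo_bin + 1)
        prefs = np.array([grp.compartment_prefs.get(c, 0.0) for c in comps5])
        counts5 = rng.multinomial(grp.output_budget, prefs)
        # Axon bookkeeping for presynaptic placement.
        chain_of = {}
        pos_in_chain = {}
        for ci, chain in enumerate(b.axon_chains):
            for k, v in enumerate(chain):
                chain_of[int(v)] = ci
                pos_in_chain[int(v)] = k
        axon_depths = [geometry.depth(skel.positions[chain])
                       for chain in b.axon_chains]

        def axon_sites(anchor_depth, k):
            """Vertices along the axon for one connection's synapses."""
            ci = int(np.argmin([np.abs(ad - anchor_depth).min()
                                for ad in axon_depths]))
            chain = b.axon_chains[ci]
            j0 = int(np.abs(axon_depths[ci] - anchor_depth).argmin())
            offsets = np.concatenate([[0.0], np.cumsum(
                rng.exponential(grp.clump_scale, size=k - 1))]) if k > 1 else np.array([0.0])
            steps = np.round(offsets / spec.axon_step).astype(int)
            sign = 1 if j0 < len(chain) - 1 else -1
            js = np.clip(j0 + sign * steps, 0, len(chain) - 1)
            return chain[js]

        for comp, cnt in zip(comps5, counts5):
            if cnt == 0:
                continue
            order, order_bins = comp_index[comp]
            lo = np.searchsorted(order_bins, lo_bin, side="left")
            hi = np.searchsorted(order_bins, hi_bin, side="left")
            cand = order[lo:hi]
            if len(cand) == 0:
                cand = order  # widen to the whole column
            if len(cand) == 0:
                raise SpecError(
                    f"cell {b.cell_id}: no candidate targets for compartment {comp}")
            if comp == "inhibitory":
                w = np.array([grp.inh_subclass_weights.get(k, 1.0)
                              for k in key_of_slot[cand]])
            else:
                w = np.array([grp.mtype_multipliers.get(k, 1.0)
                              for k in key_of_slot[cand]])
            w = w * (post[cand] != b.cell_id)  # no autapse targets
            if w.sum() == 0:
                raise SpecError(
                    f"cell {b.cell_id}: zero-weight candidate pool for {comp}")
            p = w / w.sum()
            # Connection sizes.
            if grp.syn_per_connection_mean <= 1.0:
                ks = np.ones(cnt, dtype=int)
            else:
                draw = 1 + rng.poisson(grp.syn_per_connection_mean - 1.0, size=cnt)
                csum = np.cumsum(draw)
                n_conn = int(np.searchsorted(csum, cnt) + 1)
                ks = draw[:n_conn]
                ks[-1] -= int(csum[n_conn - 1] - cnt)
                ks = ks[ks > 0]
            anchors = rng.choice(cand, size=len(ks), p=p)
            for anchor, k in zip(anchors, ks):
                target = int(post[anchor])
                tb_build = by_id[target]
                anchor_vertex = int(pv[anchor])
                pool_key = (target, comp if not is_inh_host[anchor] else "inhibitory")
                pool = vertex_pool.get(pool_key, np.array([anchor_vertex]))
                if k == 1:
                    sites = np.array([anchor_vertex])
                else:
                    tpos = tb_build.skeleton.positions
                    dists = np.linalg.norm(tpos[pool] - tpos[anchor_vertex], axis=1)
                    sites = pool[np.argsort(dists)[:k]]
                    if len(sites) < k:
                        sites = np.concatenate(
                            [sites, np.full(k - len(sites), anchor_vertex)])
                boost = 1.0
                if (comp == "inhibitory" and grp.inh_subclass_weights
                        and grp.preferred_size_boost != 1.0):
                    best = max(grp.inh_subclass_weights,
                               key=grp.inh_subclass_weights.get)
                    if key_of_slot[anchor] == best:
                        boost = grp.preferred_size_boost
                sizes = _lognormal_sizes(rng, len(sites),
                                         grp.size_median * boost, grp.size_sigma)
                pre_sites = axon_sites(float(slot_depth[anchor]), len(sites))
                for site, size, pre_v in zip(sites, sizes, pre_sites):
                    emit(b.cell_id, target, tb_build.skeleton.positions[int(site)],
                         float(size), int(pre_v), int(site))

    # --- assemble tables ----------------------------------------------------
    synapses = pd.DataFrame(syn_rows)
    synapses.insert(0, "synapse_id", np.arange(len(synapses)))
    synapses["depth"] = geometry.depth(synapses[["x", "y", "z"]].to_numpy())

    rows = []
    for b in builds:
        root_pos = b.skeleton.positions[b.skeleton.root]
        expert_sub = None
        if b.coarse_class == "inhibitory":
            # The first ~70% of each group carries expert subclass
            # annotations (at least two per group, so a linear
            # discriminant can always be trained).
            n_labeled = max(2, round(spec.expert_label_fraction
                                     * b.group.n_cells))
            if b.index_in_group < n_labeled:
                expert_sub = b.subclass
        expert_mtype = None
        if b.coarse_class == "excitatory":
            mt = next(m for m in spec.mtypes if m.name == b.mtype)
            expert_mtype = mt.layer_label
        rows.append({
            "cell_id": b.cell_id,
            "soma_x": root_pos[0], "soma_y": root_pos[1], "soma_z": root_pos[2],
            "nucleus_volume": b.nucleus_volume,
            "coarse_class": b.coarse_class,
            "expert_subclass": expert_sub,
            "expert_mtype": expert_mtype,
        })
    cells = pd.DataFrame(rows)
    skeletons = {b.cell_id: b.skeleton for b in builds}
    return cells, skeletons, synapses, geometry, truth


# ---------------------------------------------------------------------------
# Mixed-neuron fixture
# ---------------------------------------------------------------------------

@dataclass
class MixedNeuron:
    skeleton: Skeleton
    input_vertices: np.ndarray
    output_vertices: np.ndarray
    axon_vertices: np.ndarray   # planted axon subtree (vertex ids)


def generate_mixed_neuron(n_inputs=100, n_outputs=100, epsilon=0.0, seed=0,
                          n_vertices_per_side=50) -> MixedNeuron:
    """Neuron with designated input- and output-bearing subtrees.

    A fraction ``1 - epsilon`` of outputs lands on the axon subtree (and of
    inputs on the dendrite subtree); ``epsilon = 0`` gives perfect
    segregation, ``epsilon = 0.5`` uniform mixing.
    """
    rng = np.random.default_rng(seed)
    tb = _TreeBuilder(np.zeros(3))
    sides = {}
    for side, d in (("dendrite", np.array([1.0, 0.2, 0.0])),
                    ("axon", np.array([-1.0, -0.2, 0.0]))):
        verts = []
        par = 0
        pos = np.zeros(3)
        dd = _unit(d)
        for _ in range(n_vertices_per_side):
            dd = _unit(dd + 0.1 * rng.normal(size=3))
            pos = pos + dd * 4.0
            par = tb.add(pos.copy(), par, SWC_DENDRITE, 0.3)
            verts.append(par)
        sides[side] = np.array(verts, dtype=np.int64)
    skel = tb.build()
    def place(n, main_side):
        other = "axon" if main_side == "dendrite" else "dendrite"
        on_main = rng.random(n) >= epsilon
        out = np.empty(n, dtype=np.int64)
        out[on_main] = rng.choice(sides[main_side], size=int(on_main.sum()))
        out[~on_main] = rng.choice(sides[other], size=int((~on_main).sum()))
        return out
    inputs = place(n_inputs, "dendrite")
    outputs = place(n_outputs, "axon")
    return MixedNeuron(skel, inputs, outputs, sides["axon"])
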