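"""Cell and synapse tables, bundle I/O, and cross-link validation.

The on-disk "bundle" is a directory holding::

    skeletons/<cell_id>.swc   one standard SWC per cell
    cells.csv                 per-cell records
    synapses.csv              the single source of connectivity
    geometry.toml             column geometry
    ground_truth.json         (synthetic columns only)

Synapse rows link pre/post cells and skeleton vertices with position and
size.  External (non-column) presynaptic sources carry the sentinel
``pre_cell = -1`` / ``pre_vertex = -1``; every non-negative cell id
referenced by a synapse must exist in the cell table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ColumnGeometry
from .skeleton import Skeleton

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "cell_id", "soma_x", "soma_y", "soma_z", "nucleus_volume", "coarse_class",
]
SYNAPSE_COLUMNS = [
    "synapse_id", "pre_cell", "post_cell", "x", "y", "z", "size",
    "pre_vertex", "post_vertex",
]
COARSE_CLASSES = ("excitatory", "inhibitory", "nonneuronal")

EXTERNAL = -1  # sentinel for out-of-column presynaptic sources


class BundleError(ValueError):
    """Inconsistent or incomplete bundle."""


def validate_cells(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise BundleError(f"cell table missing columns: {missing}")
    if cells["cell_id"].duplicated().any():
        raise BundleError("duplicate cell_id in cell table")
    bad = ~cells["coarse_class"].isin(COARSE_CLASSES)
    if bad.any():
        raise BundleError(
            f"unknown coarse_class values: {sorted(cells.loc[bad, 'coarse_class'].unique())}"
        )


def validate_synapses(
    synapses: pd.DataFrame,
    cells: pd.DataFrame,
    skeletons: dict[int, Skeleton] | None = None,
) -> None:
    missing = [c for c in SYNAPSE_COLUMNS if c not in synapses.columns]
    if missing:
        raise BundleError(f"synapse table missing columns: {missing}")
    if (synapses["size"] <= 0).any():
        raise BundleError("synapse sizes must be > 0")
    known = set(cells["cell_id"].astype(int))
    for col in ("pre_cell", "post_cell"):
        ids = synapses[col].astype(int)
        bad = ~ids.isin(known) & (ids != EXTERNAL)
        if bad.any():
            raise BundleError(
                f"{col} references unknown cells: {sorted(ids[bad].unique())[:5]}"
            )
    n_autapse = int((synapses["pre_cell"] == synapses["post_cell"]).sum())
    if n_autapse:
        logger.info("synapse table contains %d autapses (kept, excluded from stats)", n_autapse)
    if skeletons is not None:
        for col, cell_col in (("pre_vertex", "pre_cell"), ("post_vertex", "post_cell")):
            sub = synapses[synapses[cell_col] != EXTERNAL]
            for cid, grp in sub.groupby(cell_col):
                cid = int(cid)
                if cid not in skeletons:
                    raise BundleError(f"missing skeleton for cell {cid}")
                n = skeletons[cid].n_vertices
                v = grp[col].to_numpy()
                if ((v < 0) | (v >= n)).any():
                    raise BundleError(
                        f"dangling {col} reference for cell {cid}"
                    )


def exclude_autapses(synapses: pd.DataFrame) -> pd.DataFrame:
    """Drop autapses (used by every connectivity statistic)."""
    return synapses[synapses["pre_cell"] != synapses["post_cell"]]


def read_bundle(bundle_dir):
    """Load and cross-validate a bundle directory.

    Returns ``(cells, skeletons, synapses, geometry)`` where ``skeletons``
    maps cell_id to :class:`Skeleton`.  Depth columns (``depth`` for
    synapses) are computed from the geometry.
    """
    bundle_dir = Path(bundle_dir)
    geometry = ColumnGeometry.from_toml(bundle_dir / "geometry.toml")
    cells = pd.read_csv(bundle_dir / "cells.csv")
    validate_cells(cells)
    skeletons = {}
    for cid in cells["cell_id"].astype(int):
        path = bundle_dir / "skeletons" / f"{cid}.swc"
        if not path.exists():
            raise BundleError(f"missing skeleton for cell {cid}")
        skeletons[cid] = Skeleton.from_swc(path)
    synapses = pd.read_csv(bundle_dir / "synapses.csv")
    validate_synapses(synapses, cells, skeletons)
    synapses = synapses.copy()
    synapses["depth"] = geometry.depth(synapses[["x", "y", "z"]].to_numpy())
    return cells, skeletons, synapses, geometry


def write_bundle(bundle_dir, cells, skeletons, synapses, geometry,
                 ground_truth=None) -> None:
    bundle_dir = Path(bundle_dir)
    (bundle_dir / "skeletons").mkdir(parents=True, exist_ok=True)
    geometry.to_toml(bundle_dir / "geometry.toml")
    cells.to_csv(bundle_dir / "cells.csv", index=False)
    synapses[[c for c in synapses.columns if c != "depth"]].to_csv(
        bundle_dir / "synapses.csv", index=False
    )
    for cid, skel in skeletons.items():
        skel.to_swc(bundle_dir / "skeletons" / f"{cid}.swc")
    if ground_truth is not None:
        ground_truth.to_json(bundle_dir / "ground_truth.json")
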