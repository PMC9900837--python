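"""Shared fixtures and tree-building helpers."""

import numpy as np
import pandas as pd
import pytest

from columncensus.geometry import ColumnGeometry
from columncensus.skeleton import Skeleton


@pytest.fixture(scope="session")
def geometry():
    return ColumnGeometry(pia_depth=0.0, wm_depth=800.0,
                          layer_boundaries=(100.0, 280.0, 420.0, 600.0))


def chain_skeleton(n, step=10.0, direction=(0.0, 1.0, 0.0)):
    """Unbranched chain of n vertices spaced ``step`` um from the root."""
    d = np.asarray(direction, dtype=float)
    pos = np.arange(n)[:, None] * step * d
    parent = np.arange(-1, n - 1)
    return Skeleton(pos, parent)


def random_tree(rng, n, scale=10.0):
    """Random tree: each vertex attaches to a uniformly drawn predecessor."""
    parent = np.full(n, -1, dtype=np.int64)
    pos = np.zeros((n, 3))
    for i in range(1, n):
        parent[i] = rng.integers(0, i)
        pos[i] = pos[parent[i]] + rng.normal(scale=scale, size=3)
    return Skeleton(pos, parent)


def binary_tree_with_unary_root(depth, seg_len=20.0):
    """Full binary tree with 2**depth leaves hung below a single-child root."""
    pos = [np.zeros(3), np.array([0.0, seg_len, 0.0])]
    parent = [-1, 0]
    frontier = [1]
    for level in range(depth):
        nxt = []
        for v in frontier:
            for sign in (-1, 1):
                pos.append(pos[v] + np.array([sign * seg_len, seg_len, 0.0]))
                parent.append(v)
                nxt.append(len(pos) - 1)
        frontier = nxt
    return Skeleton(np.array(pos), np.array(parent)), 2 ** depth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One processed default synthetic column, shared across test modules.

    Runs the compartment pipeline with planted apical roots and labels every
    synapse; the heavier stages are exercised separately.
    """
    from columncensus.pipeline import Pipeline, PipelineConfig

    cfg = PipelineConfig(generate="default", seed=1,
                         out_dir=str(tmp_path_factory.mktemp("default_run")),
                         apical_source="ground_truth", write_cards=False)
    p = Pipeline(cfg)
    p._ensure_labeled()
    return p
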