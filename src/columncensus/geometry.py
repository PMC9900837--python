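"""Column geometry: depth coordinate, layers, and depth binning.

The column is oriented with the y axis pointing from pia toward white matter.
A rigid rotation about the z axis (``rotation_angle`` degrees, mixing x and
y) may be applied first to flatten a tilted pial surface; depth is then the
rotated y coordinate minus ``pia_depth``, so depth 0 is the pia and depth
increases toward white matter.  All binning is half-open ``[lo, hi)``.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ColumnGeometry:
    pia_depth: float
    wm_depth: float
    layer_boundaries: tuple[float, ...]
    rotation_angle: float = 0.0  # degrees about z, flattening the pia
    depth_bin_width: float = 20.0

    def __post_init__(self):
        lb = tuple(float(b) for b in self.layer_boundaries)
        object.__setattr__(self, "layer_boundaries", lb)
        if any(b2 <= b1 for b1, b2 in zip(lb, lb[1:])):
            raise ValueError("layer_boundaries must be strictly increasing")
        if lb and (lb[0] <= self.pia_depth or lb[-1] >= self.wm_depth):
            raise ValueError("layer_boundaries must lie within (pia, wm)")
        if self.wm_depth <= self.pia_depth:
            raise ValueError("wm_depth must exceed pia_depth")

    # -- depth -------------------------------------------------------------

    def depth(self, points) -> np.ndarray:
        """Depth below pia for an (n, 3) array (or single point)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        theta = math.radians(self.rotation_angle)
        y_rot = p[:, 1] * math.cos(theta) + p[:, 0] * math.sin(theta)
        d = y_rot - self.pia_depth
        return d if np.asarray(points).ndim > 1 else float(d[0])

    def radial(self, points, origin) -> np.ndarray:
        """Distance within the pia plane from ``origin`` (x/z after rotation)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        o = np.asarray(origin, dtype=float)
        theta = math.radians(self.rotation_angle)
        x = p[:, 0] * math.cos(theta) - p[:, 1] * math.sin(theta)
        xo = o[0] * math.cos(theta) - o[1] * math.sin(theta)
        r = np.hypot(x - xo, p[:, 2] - o[2])
        return r if np.asarray(points).ndim > 1 else float(r[0])

    # -- binning -----------------------------------------------------------

    @property
    def n_depth_bins(self) -> int:
        span = self.wm_depth - self.pia_depth
        return int(math.ceil(span / self.depth_bin_width))

    @property
    def depth_bin_edges(self) -> np.ndarray:
        return np.arange(self.n_depth_bins + 1) * self.depth_bin_width

    def depth_bin(self, depths) -> np.ndarray:
        """Half-open depth-bin index; out-of-column depths are clipped."""
        d = np.asarray(depths, dtype=float)
        idx = np.floor(d / self.depth_bin_width).astype(np.int64)
        return np.clip(idx, 0, self.n_depth_bins - 1)

    def layer_of(self, depths) -> np.ndarray:
        """Layer index (0-based from pia) per depth; half-open boundaries."""
        d = np.asarray(depths, dtype=float)
        return np.searchsorted(np.asarray(self.layer_boundaries), d, side="right")

    # -- TOML I/O ----------------------------------------------------------

    @classmethod
    def from_toml(cls, path) -> "ColumnGeometry":
        data = tomllib.loads(Path(path).read_text())
        return cls(
            pia_depth=float(data["pia_depth"]),
            wm_depth=float(data["wm_depth"]),
            layer_boundaries=tuple(data.get("layer_boundaries", ())),
            rotation_angle=float(data.get("rotation_angle", 0.0)),
            depth_bin_width=float(data.get("depth_bin_width", 20.0)),
        )

    def to_toml(self, path) -> None:
        lines = [
            f"pia_depth = {self.pia_depth!r}",
            f"wm_depth = {self.wm_depth!r}",
            "layer_boundaries = [%s]"
            % ", ".join(repr(float(b)) for b in self.layer_boundaries),
            f"rotation_angle = {self.rotation_angle!r}",
            f"depth_bin_width = {self.depth_bin_width!r}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")
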