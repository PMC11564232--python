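"""Synthetic branching vascular tree phantoms and Doppler-like rasters.

In-vivo utero-placental ultrasound volumes are not publicly available, so the
imaging pipeline is validated on phantoms with known ground truth: binary
branching tube trees built in continuous millimetre space (ground truth is
therefore independent of any voxel lattice) and rasterized onto an isotropic
grid afterwards.  This separation lets tests distinguish algorithmic error
from discretization error.

A tree with ``generations = d`` of full binary branching has 2^d leaf tips
plus the trunk origin (the skeleton sees the trunk root as an end point too)
and 2^d - 1 bifurcation nodes.  Crossing nodes cannot occur in a strict
binary tree, so they are synthesized on request as straight "crossing bars"
that pierce an existing segment at its midpoint, producing a skeleton voxel
with four 26-adjacent neighbours.

The noise model is additive Gaussian on the Doppler amplitude, clipped at
zero — a deliberately simple stand-in for speckle, off by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import PlacentalMask, VoxelGrid

__all__ = ["PhantomConfig", "TreePhantom", "generate_tree", "rasterize_tree", "truth_metrics"]


@dataclass
class PhantomConfig:
    """Desk-scale branching-tube phantom parameters (lengths in mm)."""

    generations: int = 2
    trunk_length_mm: float = 16.0
    trunk_radius_mm: float = 1.2
    length_decay: float = 0.75
    radius_decay: float = 0.8
    branch_angle_deg: float = 35.0
    n_crossings: int = 0
    noise_sd: float = 0.0
    vessel_amplitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.generations <= 8:
            raise ValueError("generations must be in 0..8")
        for name in ("trunk_length_mm", "trunk_radius_mm", "vessel_amplitude"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("length_decay", "radius_decay"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_crossings < 0 or self.noise_sd < 0:
            raise ValueError("n_crossings and noise_sd must be >= 0")


@dataclass
class TreePhantom:
    """Continuous-space tube tree with derived ground-truth counts.

    ``segments`` holds (start_mm, end_mm, radius_mm) per tube; ``parent`` the
    parent segment index (-1 for the trunk); ``kind`` distinguishes tree
    segments from planted crossing bars.  ``truth`` records tip, bifurcation
    and crossing node counts, total centerline length and mean radius.
    """

    segments: list[tuple[np.ndarray, np.ndarray, float]]
    parent: list[int]
    kind: list[str]
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "segments": [
                {"start_mm": list(map(float, s)), "end_mm": list(map(float, e)),
                 "radius_mm": float(r)}
                for s, e, r in self.segments
            ],
            "parent": self.parent,
            "kind": self.kind,
            "truth": self.truth,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def generate_tree(config: PhantomConfig) -> TreePhantom:
    """Grow a binary branching tube tree; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    parent: list[int] = []
    kind: list[str] = []

    trunk_dir = np.array([0.0, 0.0, 1.0])
    start = np.zeros(3)
    end = start + trunk_dir * config.trunk_length_mm
    segments.append((start, end, config.trunk_radius_mm))
    parent.append(-1)
    kind.append("tree")
    frontier = [(0, trunk_dir)]

    theta = np.deg2rad(config.branch_angle_deg)
    for gen in range(1, config.generations + 1):
        length = config.trunk_length_mm * config.length_decay**gen
        radius = config.trunk_radius_mm * config.radius_decay**gen
        new_frontier = []
        for seg_idx, direction in frontier:
            u, v = _orthonormal_frame(direction)
            phi = rng.uniform(0, 2 * np.pi)
            for sign in (0.0, np.pi):
                azim = phi + sign
                child_dir = (
                    np.cos(theta) * direction
                    + np.sin(theta) * (np.cos(azim) * u + np.sin(azim) * v)
                )
                child_dir /= np.linalg.norm(child_dir)
                s = segments[seg_idx][1]
                e = s + child_dir * length
                segments.append((s, e, radius))
                parent.append(seg_idx)
                kind.append("tree")
                new_frontier.append((len(segments) - 1, child_dir))
        frontier = new_frontier

    n_leaves = len(frontier) if config.generations > 0 else 1
    n_bifurcations = (2**config.generations - 1) if config.generations > 0 else 0

    # Crossing bars: straight tubes piercing a tree segment at its midpoint,
    # perpendicular to it, so the rasterized skeleton contains a degree-4 voxel.
    n_tips = n_leaves + 1
    tree_indices = [i for i, k in enumerate(kind) if k == "tree"]
    for _ in range(config.n_crossings):
        target = int(rng.choice(tree_indices))
        s, e, r = segments[target]
        seg_dir = (e - s) / np.linalg.norm(e - s)
        mid = (s + e) / 2.0
        u, v = _orthonormal_frame(seg_dir)
        azim = rng.uniform(0, 2 * np.pi)
        bar_dir = np.cos(azim) * u + np.sin(azim) * v
        half = max(4.0 * r, 0.4 * float(np.linalg.norm(e - s)))
        bar_r = r * config.radius_decay
        segments.append((mid - bar_dir * half, mid + bar_dir * half, bar_r))
        parent.append(target)
        kind.append("crossbar")
        n_tips += 2

    lengths = [float(np.linalg.norm(e - s)) for s, e, _ in segments]
    radii = [float(r) for _, _, r in segments]
    truth = {
        "n_tips": n_tips,
        "n_bifurcation_nodes": n_bifurcations,
        "n_crossing_nodes": config.n_crossings,
        "centerline_length_mm": float(sum(lengths)),
        "mean_radius_mm": float(np.mean(radii)),
    }
    return TreePhantom(segments=segments, parent=parent, kind=kind, truth=truth)


def _segment_distance_field(shape, origin, spacing, seg_start, seg_end, radius, out):
    """OR capsule occupancy for one segment into ``out`` over a local window.

    Tubes are capsules (cylinders with hemispherical caps), the standard CSG
    tube primitive: caps keep junctions gap-free and terminal vessels rounded.
    A voxel is set when at least half of a 2x2x2 sub-sample of its volume lies
    inside the capsule; supersampling removes the systematic overcount a
    centre-in-tube test produces at coarse spacing.
    """
    lo = np.minimum(seg_start, seg_end) - radius - spacing
    hi = np.maximum(seg_start, seg_end) + radius + spacing
    i0 = np.maximum(((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(((hi - origin) / spacing).astype(int) + 2, shape)
    if (i0 >= i1).any():
        return
    ax = [origin[d] + spacing * (np.arange(i0[d], i1[d]) + 0.5) for d in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = seg_end - seg_start
    L2 = float(d @ d)

    def inside_at(offset):
        p = pts + offset
        if L2 == 0:
            return np.linalg.norm(p - seg_start, axis=-1) <= radius
        t = np.clip(((p - seg_start) @ d) / L2, 0.0, 1.0)
        proj = seg_start + t[..., None] * d
        return np.linalg.norm(p - proj, axis=-1) <= radius

    q = spacing / 4.0
    votes = np.zeros(pts.shape[:-1], dtype=np.int8)
    for sx in (-q, q):
        for sy in (-q, q):
            for sz in (-q, q):
                votes += inside_at(np.array([sx, sy, sz]))
    out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= votes >= 4


def rasterize_tree(
    tree: TreePhantom,
    spacing_mm: float,
    config: PhantomConfig,
    mask_margin_voxels: int = 3,
) -> tuple[VoxelGrid, PlacentalMask]:
    """Rasterize a tube tree onto an isotropic voxel grid.

    Voxels whose centre lies within a tube radius of any centerline receive
    ``vessel_amplitude``; seeded Gaussian noise (``noise_sd``) is added
    everywhere and clipped at zero.  The mask is the tree's bounding box
    dilated by ``mask_margin_voxels``.  A tube whose radius is below the voxel
    spacing cannot be resolved; a warning is emitted.
    """
    if not tree.segments:
        shape = (16, 16, 16)
        rng = np.random.default_rng((config.seed + 1) % 2**31)
        values = np.clip(rng.normal(0.0, config.noise_sd, shape), 0, None) if config.noise_sd > 0 else np.zeros(shape)
        return (
            VoxelGrid(values=values, spacing_mm=spacing_mm),
            PlacentalMask(include=np.ones(shape, dtype=np.uint8)),
        )

    radii = np.array([r for _, _, r in tree.segments])
    if (radii < spacing_mm).any():
        warnings.warn(
            f"{int((radii < spacing_mm).sum())} tube(s) thinner than the voxel "
            f"spacing {spacing_mm} mm are not resolved",
            stacklevel=2,
        )
    pts = np.array([p for s, e, _ in tree.segments for p in (s, e)])
    margin = float(radii.max()) + (mask_margin_voxels + 1) * spacing_mm
    origin = pts.min(axis=0) - margin
    extent = pts.max(axis=0) + margin - origin
    shape = tuple(int(np.ceil(v / spacing_mm)) + 1 for v in extent)

    fg = np.zeros(shape, dtype=bool)
    for s, e, r in tree.segments:
        _segment_distance_field(np.array(shape), origin, spacing_mm, s, e, r, fg)

    rng = np.random.default_rng((config.seed + 1) % 2**31)
    values = np.where(fg, config.vessel_amplitude, 0.0)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, shape)
    values = np.clip(values, 0.0, None)

    mask = np.zeros(shape, dtype=np.uint8)
    idx = np.argwhere(fg)
    lo = np.maximum(idx.min(axis=0) - mask_margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + mask_margin_voxels + 1, shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1

    grid = VoxelGrid(values=values, spacing_mm=spacing_mm, origin_mm=tuple(map(float, origin)))
    return grid, PlacentalMask(include=mask)


def truth_metrics(tree: TreePhantom, spacing_mm: float) -> dict:
    """Expected marker values implied by the continuous-space ground truth.

    Expected uPVV sums capsule volumes, pi*r^2*L + 4/3*pi*r^3 per segment
    (junction overlap is not subtracted, so it slightly overestimates);
    counts map tips -> end points and bifurcation nodes -> bifurcation
    points.
    """
    vol_mm3 = sum(
        np.pi * r**2 * float(np.linalg.norm(e - s)) + 4.0 / 3.0 * np.pi * r**3
        for s, e, r in tree.segments
    )
    return {
        "end_points": tree.truth["n_tips"],
        "bifurcation_points": tree.truth["n_bifurcation_nodes"],
        "crossing_points": tree.truth["n_crossing_nodes"],
        "total_length_mm": tree.truth["centerline_length_mm"],
        "avg_thickness_mm": tree.truth["mean_radius_mm"],
        "upvv_cm3": vol_mm3 / 1000.0,
        "spacing_mm": spacing_mm,
    }
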