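"""Per-spicule 3D morphometry.

The measured quantities mirror what the µCT analysis of larval spicules
reports per skeletal element:

* volume — voxel count × voxel volume;
* surface area — isosurface mesh (default) or exposed voxel faces;
* total length — the spicule is thinned to a one-voxel medial skeleton, the
  skeleton is organized into a graph of endpoint/junction nodes and branch
  paths, short terminal spurs (thinning artifacts) are pruned, and branch
  lengths are summed;
* mean thickness — the Euclidean distance transform (EDT) of the binary
  spicule is sampled along the skeleton; each sample is the local radius
  (distance from the medial axis to the nearest surface), and the mean is
  reported as a diameter by default;
* tips and junctions — endpoint and junction node counts of the pruned
  graph, quantifying ectopic branching (loss of tip dominance).

All operations are anisotropy-aware: spacing is (sz, sy, sx) µm and every
output is in physical units. Thinning itself runs on a smoothed isotropic
resampling of the mask whenever the spacing anisotropy exceeds 1.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.morphology import skeletonize as _sk_skeletonize

from . import segmentation
from .volume_io import RECORD_COLUMNS, VoxelVolume

__all__ = [
    "SkeletonNode",
    "SkeletonBranch",
    "SkeletonGraph",
    "euclidean_distance_transform",
    "skeletonize_3d",
    "build_skeleton_graph",
    "prune_spurs",
    "total_length",
    "mean_thickness",
    "count_tips_junctions",
    "compute_volume",
    "compute_surface_area",
    "measure_spicule",
    "measure_labels",
]

_OFFSETS26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


# -- distance transform -------------------------------------------------------


def euclidean_distance_transform(binary: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Distance (µm) from each foreground voxel centre to the nearest
    background voxel centre, anisotropy-aware.

    The volume is treated as padded by one background voxel on all sides, so
    objects touching the border get finite distances. Background maps to 0.
    """
    mask = np.asarray(binary) != 0
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    d = ndimage.distance_transform_edt(padded, sampling=spacing)
    return d[tuple(slice(1, -1) for _ in range(3))]


# -- skeletonization ----------------------------------------------------------


def skeletonize_3d(binary: np.ndarray) -> np.ndarray:
    """Homotopy-preserving 3D thinning to a one-voxel-wide medial skeleton.

    Wraps scikit-image's 3D thinning; the skeleton is a subset of the
    foreground and preserves the number of 26-connected components.
    """
    mask = np.asarray(binary) != 0
    if not mask.any():
        return np.zeros_like(mask)
    if mask.sum() == 1:
        return mask.copy()
    return _sk_skeletonize(mask).astype(bool)


# -- skeleton graph -----------------------------------------------------------


@dataclass
class SkeletonNode:
    id: int
    kind: Literal["endpoint", "junction", "anchor"]
    coordinate: tuple[int, int, int]  # representative voxel (z, y, x)
    voxels: tuple[tuple[int, int, int], ...]  # the node's voxel cluster


@dataclass
class SkeletonBranch:
    id: int
    node_a: int
    node_b: int
    path: tuple[tuple[int, int, int], ...]  # ordered voxels incl. node voxels

    def length_um(self, spacing, mode: str = "path") -> float:
        pts = np.asarray(self.path, dtype=float) * np.asarray(spacing)
        if len(pts) < 2:
            return 0.0
        if mode == "chord":
            return float(np.linalg.norm(pts[-1] - pts[0]))
        if mode == "path":
            return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        raise ValueError(f"unknown length mode {mode!r}")


@dataclass
class SkeletonGraph:
    """Skeleton voxels organized into nodes (endpoints/junctions) and branches.

    Degree-1 voxels under 26-adjacency become endpoint nodes; 26-adjacent
    voxels of degree >= 3 are merged into a single junction node whose
    coordinate is the cluster member closest to the cluster centroid
    (ties: lowest (z, y, x)). An isolated cycle is anchored at an arbitrary
    voxel ("anchor" node) carrying one closed branch.
    """

    nodes: dict[int, SkeletonNode]
    branches: dict[int, SkeletonBranch]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    @property
    def voxels(self) -> set[tuple[int, int, int]]:
        out: set[tuple[int, int, int]] = set()
        for br in self.branches.values():
            out.update(br.path)
        for nd in self.nodes.values():
            out.update(nd.voxels)
        return out

    def node_position_um(self, node_id: int) -> np.ndarray:
        c = np.asarray(self.nodes[node_id].coordinate, dtype=float)
        return np.asarray(self.origin) + c * np.asarray(self.spacing)

    def incident_branches(self, node_id: int) -> list[int]:
        return [
            b.id
            for b in self.branches.values()
            if b.node_a == node_id or b.node_b == node_id
        ]

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for v in self.voxels:
            mask[v] = True
        return mask


def _has_solid_block(mask: np.ndarray) -> bool:
    if any(s < 2 for s in mask.shape):
        return False
    m = mask.astype(np.uint8)
    s = (
        m[:-1, :-1, :-1] + m[1:, :-1, :-1] + m[:-1, 1:, :-1] + m[:-1, :-1, 1:]
        + m[1:, 1:, :-1] + m[1:, :-1, 1:] + m[:-1, 1:, 1:] + m[1:, 1:, 1:]
    )
    return bool((s == 8).any())


def build_skeleton_graph(
    skeleton: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> SkeletonGraph:
    """Organize a thinned mask into endpoint/junction nodes and branch paths."""
    mask = np.asarray(skeleton) != 0
    if _has_solid_block(mask):
        raise ValueError("not a thinned mask: contains a solid 2x2x2 block")
    shape = mask.shape
    coords = [tuple(c) for c in np.argwhere(mask)]
    graph = SkeletonGraph(nodes={}, branches={}, spacing=tuple(spacing), shape=shape, origin=tuple(origin))
    if not coords:
        return graph
    vox_set = set(coords)

    def neighbors(v):
        z, y, x = v
        return [
            (z + dz, y + dy, x + dx)
            for dz, dy, dx in _OFFSETS26
            if (z + dz, y + dy, x + dx) in vox_set
        ]

    nbrs = {v: neighbors(v) for v in coords}
    degree = {v: len(n) for v, n in nbrs.items()}

    # node voxels: endpoints (deg <= 1) and junction voxels (deg >= 3)
    node_of: dict[tuple[int, int, int], int] = {}
    next_node = 0
    junction_voxels = [v for v in coords if degree[v] >= 3]
    # cluster 26-adjacent junction voxels
    jset = set(junction_voxels)
    seen: set[tuple[int, int, int]] = set()
    for v in junction_voxels:
        if v in seen:
            continue
        cluster = [v]
        seen.add(v)
        stack = [v]
        while stack:
            u = stack.pop()
            for w in nbrs[u]:
                if w in jset and w not in seen:
                    seen.add(w)
                    cluster.append(w)
                    stack.append(w)
        cluster.sort()
        centroid = np.mean(cluster, axis=0)
        rep = min(cluster, key=lambda c: (float(np.sum((np.asarray(c) - centroid) ** 2)), c))
        graph.nodes[next_node] = SkeletonNode(next_node, "junction", rep, tuple(cluster))
        for c in cluster:
            node_of[c] = next_node
        next_node += 1
    for v in coords:
        if degree[v] <= 1 and v not in node_of:
            graph.nodes[next_node] = SkeletonNode(next_node, "endpoint", v, (v,))
            node_of[v] = next_node
            next_node += 1

    # trace branches from every node voxel
    next_branch = 0
    seen_paths: set[tuple[tuple[int, int, int], ...]] = set()

    def add_branch(a_node, b_node, path):
        nonlocal next_branch
        key = tuple(path) if tuple(path) <= tuple(reversed(path)) else tuple(reversed(path))
        if key in seen_paths:
            return
        seen_paths.add(key)
        graph.branches[next_branch] = SkeletonBranch(next_branch, a_node, b_node, tuple(path))
        next_branch += 1

    visited_path_voxels: set[tuple[int, int, int]] = set()
    for v in sorted(node_of):
        for u in nbrs[v]:
            if u in node_of:
                if node_of[u] != node_of[v]:
                    add_branch(node_of[v], node_of[u], [v, u])
                continue
            # walk through degree-2 voxels
            path = [v, u]
            prev, cur = v, u
            while cur not in node_of:
                visited_path_voxels.add(cur)
                nxt = [w for w in nbrs[cur] if w != prev]
                if not nxt:  # dead end without an endpoint node (shouldn't happen)
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
            if cur in node_of:
                add_branch(node_of[v], node_of[cur], path)

    # pure cycles: degree-2 components never reached from a node
    remaining = [v for v in coords if v not in node_of and v not in visited_path_voxels]
    remaining_set = set(remaining)
    while remaining_set:
        anchor = min(remaining_set)
        graph.nodes[next_node] = SkeletonNode(next_node, "anchor", anchor, (anchor,))
        node_of[anchor] = next_node
        path = [anchor]
        prev, cur = anchor, min(nbrs[anchor])
        while cur != anchor:
            path.append(cur)
            nxt = [w for w in nbrs[cur] if w != prev]
            prev, cur = cur, nxt[0]
        path.append(anchor)
        for p in path:
            remaining_set.discard(p)
        add_branch(next_node, next_node, path)
        next_node += 1

    return graph


def prune_spurs(
    graph: SkeletonGraph,
    min_length_um: float | None = None,
    edt: np.ndarray | None = None,
    radius_factor: float = 3.0,
    max_iter: int = 100,
) -> SkeletonGraph:
    """Iteratively remove short endpoint-terminated branches (thinning spurs).

    A spur is a branch with at least one endpoint node whose path length
    falls below the cutoff. The cutoff is ``min_length_um`` when given;
    otherwise it adapts to ``radius_factor`` × the EDT value at the branch's
    junction end (classical thinning produces spurs of the order of the local
    radius). Node kinds are recomputed after each removal round; the last
    remaining branch of a connected component is never removed. Idempotent.
    """
    if min_length_um is None and edt is None:
        raise ValueError("provide min_length_um or an EDT map for adaptive pruning")
    g = graph
    for _ in range(max_iter):
        if not g.branches:
            break
        # connected components over nodes
        parent = {n: n for n in g.nodes}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for br in g.branches.values():
            ra, rb = find(br.node_a), find(br.node_b)
            if ra != rb:
                parent[ra] = rb
        comp_branches: dict[int, list[SkeletonBranch]] = {}
        for br in g.branches.values():
            comp_branches.setdefault(find(br.node_a), []).append(br)

        to_remove: list[SkeletonBranch] = []
        for comp, brs in comp_branches.items():
            candidates = []
            for br in brs:
                kinds = (g.nodes[br.node_a].kind, g.nodes[br.node_b].kind)
                if "endpoint" not in kinds:
                    continue
                if kinds == ("endpoint", "endpoint"):
                    continue  # a free rod is morphology, not a spur
                length = br.length_um(g.spacing)
                if min_length_um is not None:
                    cutoff = min_length_um
                else:
                    jn = br.node_a if kinds[0] != "endpoint" else br.node_b
                    cz, cy, cx = g.nodes[jn].coordinate
                    cutoff = radius_factor * float(edt[cz, cy, cx])  # type: ignore[index]
                if length < cutoff:
                    candidates.append((length, br))
            if candidates and len(candidates) == len(brs):
                candidates.sort(key=lambda t: t[0])
                candidates = candidates[:-1]  # spare the longest branch
            to_remove.extend(br for _, br in candidates)

        if not to_remove:
            break
        keep = g.voxels
        for br in to_remove:
            ka, kb = g.nodes[br.node_a].kind, g.nodes[br.node_b].kind
            junction_node = br.node_b if ka == "endpoint" else br.node_a
            jvox = set(g.nodes[junction_node].voxels)
            keep -= set(br.path) - jvox
        mask = np.zeros(g.shape, dtype=bool)
        for v in keep:
            mask[v] = True
        # re-thin: junction-cluster voxels absorbed by a removed spur can be
        # left as simple bumps that would otherwise keep the junction alive
        mask = skeletonize_3d(mask)
        g = build_skeleton_graph(mask, g.spacing, g.origin)
    g.meta["pruned"] = True
    return g


def total_length(graph: SkeletonGraph, mode: str = "path") -> float:
    """Sum of branch lengths in µm.

    ``mode="path"`` (default) sums Euclidean steps between consecutive path
    voxels; ``mode="chord"`` uses the straight-line distance between each
    branch's end voxels (under-measures curved branches). The mode is
    recorded in the graph's metadata.
    """
    graph.meta["length_mode"] = mode
    return float(sum(br.length_um(graph.spacing, mode) for br in graph.branches.values()))


def mean_thickness(
    binary: np.ndarray,
    skeleton: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    mode: str = "diameter",
) -> float:
    """Average spicule thickness from EDT samples along the skeleton.

    Each skeleton voxel's EDT value is its distance to the nearest surface —
    the local radius. ``mode="diameter"`` (default, reported as
    mean_thickness_um) doubles it; ``mode="radius"`` returns the raw mean.
    """
    mask = np.asarray(binary) != 0
    skel = np.asarray(skeleton) != 0
    if not skel.any():
        raise ValueError("empty skeleton")
    if np.any(skel & ~mask):
        raise ValueError("skeleton must be a subset of the foreground")
    edt = euclidean_distance_transform(mask, spacing)
    r = float(edt[skel].mean())
    if mode == "radius":
        return r
    if mode == "diameter":
        return 2.0 * r
    raise ValueError(f"unknown thickness mode {mode!r}")


def count_tips_junctions(graph: SkeletonGraph) -> tuple[int, int]:
    """(endpoint-node count, junction-node count) of a pruned graph."""
    tips = sum(1 for n in graph.nodes.values() if n.kind == "endpoint")
    junctions = sum(1 for n in graph.nodes.values() if n.kind == "junction")
    return tips, junctions


# -- volume & surface ---------------------------------------------------------


def _label_mask(labels: VoxelVolume, label_id: int) -> np.ndarray:
    mask = np.asarray(labels.values) == label_id
    if not mask.any():
        raise ValueError(f"unknown label id {label_id}")
    return mask


def compute_volume(labels: VoxelVolume, label_id: int) -> float:
    """Volume in µm³: voxel count × voxel volume."""
    return float(_label_mask(labels, label_id).sum()) * labels.voxel_volume_um3


def compute_surface_area(labels: VoxelVolume, label_id: int, method: str = "mesh") -> float:
    """Surface area in µm².

    ``mesh`` triangulates the 0.5-level isosurface of the binary mask
    (marching cubes) — the default, since face counting overestimates smooth
    surfaces by up to ~1.5×. The mask is lightly Gaussian-smoothed
    (σ = 0.8 voxels) before meshing so the triangulation follows the object
    rather than the voxel staircase; on a digitized ball this brings the
    area within ~1% of the analytic value where the raw binary mesh is ~9%
    high. ``voxel_face`` counts exposed voxel faces times their physical
    face areas.
    """
    mask = _label_mask(labels, label_id)
    sz, sy, sx = labels.spacing
    if method == "mesh":
        padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float32), 2), sigma=0.8)
        verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=(sz, sy, sx))
        return float(skmeasure.mesh_surface_area(verts, faces))
    if method == "voxel_face":
        m = np.pad(mask, 1)
        area = 0.0
        face_areas = (sy * sx, sz * sx, sz * sy)  # faces normal to z, y, x
        for ax, fa in zip(range(3), face_areas):
            diff = np.diff(m.astype(np.int8), axis=ax)
            area += float(np.abs(diff).sum()) * fa
        return area
    raise ValueError(f"unknown surface method {method!r}")


# -- the composite measurement ------------------------------------------------

_ANISOTROPY_LIMIT = 1.2


def _isotropize(mask: np.ndarray, spacing) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample to an isotropic grid (finest spacing) when anisotropy > 1.2.

    The float mask is pre-smoothed with a Gaussian of ~0.8 isotropic-voxel
    physical width, linearly interpolated and re-thresholded at 0.5; the
    smoothing suppresses the staircase surface a plain nearest-neighbour
    upsampling would hand to the thinning step.
    """
    spacing = tuple(spacing)
    if max(spacing) / min(spacing) <= _ANISOTROPY_LIMIT:
        return mask, spacing
    s_iso = min(spacing)
    sigma = [0.8 * s_iso / s for s in spacing]  # constant physical width
    sm = ndimage.gaussian_filter(mask.astype(np.float32), sigma)
    zoom = [s / s_iso for s in spacing]
    res = ndimage.zoom(sm, zoom, order=1, grid_mode=True, mode="grid-constant") > 0.5
    return res, (s_iso, s_iso, s_iso)


def measure_spicule(
    binary_mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    length_mode: str = "path",
    thickness_mode: str = "diameter",
    surface_method: str = "mesh",
    prune: float | str | None = "auto",
) -> tuple[dict, dict]:
    """Measure one binary spicule mask; returns (record fields, details).

    The record dict carries volume, surface area, total length, mean
    thickness and tip/junction counts; details carry the pruned
    SkeletonGraph, skeleton mask and EDT map for downstream inspection.
    ``prune`` is "auto" (3× local radius), a length in µm, or None.
    """
    mask = np.asarray(binary_mask) != 0
    if not mask.any():
        raise ValueError("empty spicule mask")
    spacing = tuple(float(s) for s in spacing)
    vol_container = VoxelVolume(mask.astype(np.uint8), spacing, kind="labels", origin=tuple(origin))
    volume = float(mask.sum()) * vol_container.voxel_volume_um3
    area = compute_surface_area(vol_container, 1, method=surface_method)

    work_mask, work_spacing = _isotropize(mask, spacing)
    edt = euclidean_distance_transform(work_mask, work_spacing)
    skel = skeletonize_3d(work_mask)
    graph = build_skeleton_graph(skel, work_spacing, origin)
    if prune == "auto":
        graph = prune_spurs(graph, edt=edt)
    elif prune is not None:
        graph = prune_spurs(graph, min_length_um=float(prune))
    skel_pruned = graph.to_mask()
    length = total_length(graph, mode=length_mode)
    thickness = mean_thickness(work_mask, skel_pruned, work_spacing, mode=thickness_mode)
    n_tips, n_junctions = count_tips_junctions(graph)
    record = {
        "volume_um3": volume,
        "surface_area_um2": area,
        "total_length_um": length,
        "mean_thickness_um": thickness,
        "n_tips": n_tips,
        "n_junctions": n_junctions,
    }
    details = {
        "graph": graph,
        "skeleton": skel_pruned,
        "edt": edt,
        "length_mode": length_mode,
        "thickness_mode": thickness_mode,
        "work_spacing": work_spacing,
    }
    return record, details


def measure_labels(
    volume: VoxelVolume,
    condition: str = "",
    timepoint_hpf: float = math.nan,
    id_prefix: str = "spicule",
    **options,
) -> pd.DataFrame:
    """Measure every spicule in a volume; one record per label.

    Grayscale input is segmented first (Otsu + components); binary input is
    labeled; a label field is used as-is. Measurement options are forwarded
    to :func:`measure_spicule`.
    """
    seg_opts = {
        k: options.pop(k)
        for k in ("method", "threshold", "connectivity", "min_voxels", "seed_mask")
        if k in options
    }
    if volume.kind == "labels":
        labels = volume
    else:
        labels = segmentation.segment_spicules(volume, **seg_opts)
    rows = []
    for lid in range(1, int(labels.values.max()) + 1):
        mask = labels.values == lid
        # crop to a padded bounding box for speed; origin shifted to match
        obj = ndimage.find_objects(mask.astype(np.int8))[0]
        sl = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(obj, mask.shape)
        )
        sub = mask[sl]
        sub_origin = tuple(
            o + s.start * sp for o, s, sp in zip(labels.origin, sl, labels.spacing)
        )
        rec, _ = measure_spicule(sub, labels.spacing, origin=sub_origin, **options)
        rows.append(
            {
                "spicule_id": f"{id_prefix}_{lid:03d}",
                "condition": condition,
                "timepoint_hpf": timepoint_hpf,
                **rec,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
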