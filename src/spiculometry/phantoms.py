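"""Synthetic voxel phantoms, cohorts and fluorescence fixtures with exact truth.

Sea urchin larval spicules are, to first order, unions of calcite rods a few
µm thick: a triradiate (three rods meeting at one junction) that elongates
into body rods, with ectopic branches (tip splitting, back branching)
appearing under perturbed regulation. This module renders idealized spicules
as unions of capsules — cylinders with hemispherical caps — on a voxel grid,
so every fixture carries analytic ground truth for centerline length, radius,
volume and branch topology.

Capsules rather than flat-capped cylinders are used deliberately: the medial
axis of a capsule is exactly its centerline segment, so skeleton-based length
estimates have a clean target. Foreground is decided by the voxel-centre
point-in-capsule test; partial-volume effects are emulated only by the
grayscale renderer's blur.

All generators take one integer seed; per-phantom sub-streams are derived
deterministically from (seed, index), so outputs are bit-identical across
runs with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import RECORD_COLUMNS, VoxelVolume

__all__ = [
    "RodPrimitive",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "capsule_volume",
    "capsule_surface_area",
    "voxelize",
    "make_rod_phantom",
    "make_triradiate_phantom",
    "make_branched_phantom",
    "render_grayscale",
    "make_cohort",
    "make_fluor_fixture",
    "STUDY_COHORT",
    "ROCK_RATIO_BY_GROUP",
    "PHALLOIDIN_TIP_BACK_RATIO",
]

Point = tuple[float, float, float]  # (z, y, x) in µm


@dataclass(frozen=True)
class RodPrimitive:
    """A capsule: the segment p0-p1 dilated by ``radius`` (all in µm, z/y/x)."""

    p0: Point
    p1: Point
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("p0 and p1 must differ")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))


@dataclass(frozen=True)
class PhantomSpec:
    """A set of capsules plus rasterization parameters."""

    primitives: tuple[RodPrimitive, ...]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "primitives", tuple(self.primitives))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")
        if self.pad < 1:
            raise ValueError("pad must be >= 1 voxel")


@dataclass
class GroundTruth:
    """Analytic truth for a phantom, in physical units.

    ``analytic_volume_um3`` is the sum of capsule volumes; for multi-capsule
    phantoms this is an upper bound that ignores the small overlap at
    junctions (the voxelized volume is strictly below it).
    """

    total_centerline_length_um: float
    radius_um: float
    analytic_volume_um3: float
    expected_tips: int
    expected_junctions: int
    tip_points_um: tuple[Point, ...] = ()
    junction_points_um: tuple[Point, ...] = ()

    @property
    def junction_to_nearest_tip_um(self) -> float:
        """Distance from the (first) junction to its closest tip; inf if none."""
        if not self.junction_points_um or not self.tip_points_um:
            return math.inf
        j = np.asarray(self.junction_points_um[0])
        return float(min(np.linalg.norm(j - np.asarray(t)) for t in self.tip_points_um))


def capsule_volume(length: float, radius: float) -> float:
    """Volume of a capsule: cylinder πr²L plus the two hemispherical caps."""
    return math.pi * radius**2 * length + 4.0 / 3.0 * math.pi * radius**3


def capsule_surface_area(length: float, radius: float) -> float:
    """Lateral cylinder area 2πrL plus the full sphere of the two caps."""
    return 2.0 * math.pi * radius * length + 4.0 * math.pi * radius**2


def voxelize(spec: PhantomSpec) -> VoxelVolume:
    """Rasterize the union of capsules onto a grid enclosing them plus padding.

    A voxel is foreground iff its centre lies within ``radius`` of any
    primitive's segment. Raises when any radius is below half the coarsest
    spacing ("under-resolved phantom"): such rods can rasterize with gaps.
    """
    spacing = np.asarray(spec.spacing)
    for prim in spec.primitives:
        if prim.radius < spacing.max() / 2:
            raise ValueError(
                f"under-resolved phantom: radius {prim.radius} µm < half the "
                f"coarsest spacing ({spacing.max()} µm); foreground may disconnect"
            )
    pts = np.array([p for prim in spec.primitives for p in (prim.p0, prim.p1)], dtype=float)
    rmax = max(prim.radius for prim in spec.primitives)
    lo = pts.min(axis=0) - rmax - spec.pad * spacing
    hi = pts.max(axis=0) + rmax + spec.pad * spacing
    # snap the origin onto the global voxel lattice so translated specs land
    # on identical sub-voxel phase
    origin = np.floor(lo / spacing) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + 1
    grids = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    Z, Y, X = np.meshgrid(*grids, indexing="ij", sparse=True)
    mask = np.zeros(tuple(shape), dtype=bool)
    for prim in spec.primitives:
        a = np.asarray(prim.p0)
        b = np.asarray(prim.p1)
        ab = b - a
        denom = float(ab @ ab)
        # projection parameter of each voxel centre onto the segment, clamped
        t = ((Z - a[0]) * ab[0] + (Y - a[1]) * ab[1] + (X - a[2]) * ab[2]) / denom
        t = np.clip(t, 0.0, 1.0)
        d2 = (
            (Z - a[0] - t * ab[0]) ** 2
            + (Y - a[1] - t * ab[1]) ** 2
            + (X - a[2] - t * ab[2]) ** 2
        )
        mask |= d2 <= prim.radius**2
    return VoxelVolume(
        values=mask.astype(np.uint8),
        spacing=spec.spacing,  # type: ignore[arg-type]
        kind="binary",
        origin=tuple(origin),
        meta={"phantom_seed": spec.seed, "n_primitives": len(spec.primitives)},
    )


def make_rod_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Render a single straight rod; truth: 2 tips, 0 junctions, exact volume."""
    if len(spec.primitives) != 1:
        raise ValueError("make_rod_phantom expects exactly one primitive")
    prim = spec.primitives[0]
    vol = voxelize(spec)
    truth = GroundTruth(
        total_centerline_length_um=prim.length,
        radius_um=prim.radius,
        analytic_volume_um3=capsule_volume(prim.length, prim.radius),
        expected_tips=2,
        expected_junctions=0,
        tip_points_um=(tuple(prim.p0), tuple(prim.p1)),
    )
    return vol, truth


def make_triradiate_phantom(
    center: Point,
    directions: Sequence[Point],
    lengths: Sequence[float],
    radius: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pad: int = 3,
) -> tuple[VoxelVolume, GroundTruth]:
    """Three capsules sharing one endpoint: the initial spicule geometry."""
    if len(directions) != 3 or len(lengths) != 3:
        raise ValueError("need exactly three directions and lengths")
    dirs = [np.asarray(d, dtype=float) for d in directions]
    dirs = [d / np.linalg.norm(d) for d in dirs]
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(abs(dirs[i] @ dirs[j]) - 1.0) < 1e-9:
                raise ValueError("arm directions must be pairwise non-parallel")
    c = np.asarray(center, dtype=float)
    prims = [
        RodPrimitive(tuple(c), tuple(c + L * d), radius) for d, L in zip(dirs, lengths)
    ]
    vol = voxelize(PhantomSpec(primitives=tuple(prims), spacing=spacing, pad=pad))
    truth = GroundTruth(
        total_centerline_length_um=float(sum(lengths)),
        radius_um=radius,
        analytic_volume_um3=sum(capsule_volume(L, radius) for L in lengths),
        expected_tips=3,
        expected_junctions=1,
        tip_points_um=tuple(tuple(p.p1) for p in prims),
        junction_points_um=(tuple(c),),
    )
    return vol, truth


def make_branched_phantom(
    base: RodPrimitive,
    branch_fraction: float,
    branch_direction: Point,
    branch_length: float,
    radius: float | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pad: int = 3,
) -> tuple[VoxelVolume, GroundTruth]:
    """A rod with an ectopic branch attached at fraction f along its axis.

    f < 1 emulates "dripping" branches along the rod's back: one side branch
    of ``branch_length`` leaves the axis at p0 + f·(p1−p0). f = 1 emulates
    tip splitting: the growing tip bifurcates, so TWO prongs of
    ``branch_length`` (the given direction and its mirror across the rod
    axis) emanate from p1 — a single branch at the very end would form a
    corner with only two tips and no junction. Either way the truth is
    3 tips and 1 junction, with the junction location recorded so
    tip-splitting (junction at a rod end) can be distinguished from
    back-branching.
    """
    if not 0 < branch_fraction <= 1:
        raise ValueError("branch_fraction must be in (0, 1]")
    radius = base.radius if radius is None else radius
    if branch_length < 2 * radius:
        raise ValueError(
            f"unresolvable branch: length {branch_length} µm < 2×radius ({2 * radius} µm)"
        )
    a = np.asarray(base.p0, dtype=float)
    b = np.asarray(base.p1, dtype=float)
    attach = a + branch_fraction * (b - a)
    d = np.asarray(branch_direction, dtype=float)
    d = d / np.linalg.norm(d)
    u = (b - a) / base.length
    if abs(abs(d @ u) - 1.0) < 1e-9:
        raise ValueError("branch_direction must not be parallel to the base rod")
    if branch_fraction == 1.0:
        # tip split: reflect d across the axis for the second prong
        d2 = 2.0 * (d @ u) * u - d
        prongs = (
            RodPrimitive(tuple(attach), tuple(attach + branch_length * d), radius),
            RodPrimitive(tuple(attach), tuple(attach + branch_length * d2), radius),
        )
        prims = (base,) + prongs
        tips = (tuple(a), prongs[0].p1, prongs[1].p1)
        extra_len = 2 * branch_length
    else:
        branch = RodPrimitive(tuple(attach), tuple(attach + branch_length * d), radius)
        prims = (base, branch)
        tips = (tuple(a), tuple(b), branch.p1)
        extra_len = branch_length
    vol = voxelize(PhantomSpec(primitives=prims, spacing=spacing, pad=pad))
    truth = GroundTruth(
        total_centerline_length_um=base.length + extra_len,
        radius_um=radius,
        analytic_volume_um3=capsule_volume(base.length, base.radius)
        + sum(capsule_volume(p.length, p.radius) for p in prims[1:]),
        expected_tips=3,
        expected_junctions=1,
        tip_points_um=tips,
        junction_points_um=(tuple(attach),),
    )
    return vol, truth


def render_grayscale(
    binary: VoxelVolume,
    fg_mean: float = 40000.0,
    bg_mean: float = 10000.0,
    blur_sigma: float = 0.7,
    noise_sd: float = 2000.0,
    seed: int = 0,
) -> VoxelVolume:
    """Turn a binary phantom into a noisy 16-bit grayscale volume.

    The label map is Gaussian-blurred (partial-volume emulation), mapped to
    the foreground/background mean intensities, and Gaussian noise is added;
    output clipped to [0, 65535]. Deterministic for a fixed seed.
    """
    if not (fg_mean > bg_mean >= 0):
        raise ValueError("need fg_mean > bg_mean >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lab = np.asarray(binary.values, dtype=np.float64)
    if blur_sigma > 0:
        lab = ndimage.gaussian_filter(lab, sigma=blur_sigma)
    img = bg_mean + (fg_mean - bg_mean) * lab
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 0x9E3779B9 % (2**31)])
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    out = binary.with_values(img, kind="grayscale")
    out.meta.update(
        fg_mean=fg_mean, bg_mean=bg_mean, blur_sigma=blur_sigma, noise_sd=noise_sd, seed=seed
    )
    return out


# -- cohorts ------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Two conditions × two timepoints of simulated spicule populations.

    Defaults reproduce the SR-µCT study design: control vs ROCK-inhibited
    spicules dissected at 48 and 72 hpf, mean volumes chosen so the control
    cohort grows at 325.5 µm³/hr, the inhibited cohort at 119.8 µm³/hr, and
    the control/inhibited volume ratio at 72 hpf is 2.5 (the reported group
    sizes were ~44 spicules/group; 40 is used for simulations here). Ectopic
    branching is a property of the inhibited condition only.
    """

    n_per_group: int = 40
    conditions: tuple[str, str] = ("control", "rock_inhibited")
    timepoints_hpf: tuple[float, float] = (48.0, 72.0)
    mean_volume_um3: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: {
            ("control", 48.0): 7188.0,
            ("control", 72.0): 15000.0,
            ("rock_inhibited", 48.0): 3124.8,
            ("rock_inhibited", 72.0): 6000.0,
        }
    )
    volume_cv: float = 0.2
    branch_probability: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "rock_inhibited": 0.5}
    )
    radius_um: float = 4.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.volume_cv < 0:
            raise ValueError("volume_cv must be >= 0")
        for c in self.conditions:
            p = self.branch_probability.get(c, 0.0)
            if not 0 <= p <= 1:
                raise ValueError(f"branch probability for {c!r} out of [0, 1]")
        for c in self.conditions:
            for t in self.timepoints_hpf:
                if (c, t) not in self.mean_volume_um3:
                    raise ValueError(f"mean_volume_um3 missing group {(c, t)}")


#: The cohort parameters emulating the study's four SR-µCT groups.
STUDY_COHORT = CohortSpec()


def _rod_length_for_volume(volume: float, radius: float) -> float:
    """Invert the capsule volume formula for length at fixed radius."""
    return (volume - 4.0 / 3.0 * math.pi * radius**3) / (math.pi * radius**2)


def make_cohort(
    spec: CohortSpec, render: bool = True
) -> tuple[list[tuple[PhantomSpec, GroundTruth, VoxelVolume | None]], pd.DataFrame]:
    """Simulate per-spicule cohorts for every condition × timepoint group.

    Volumes are drawn Normal(mean, cv·mean) per group and realized by scaling
    rod length at fixed radius (so thickness truth is constant within the
    cohort). With the condition's branch probability, a side branch is added
    — a tip split (f = 1) or a back branch (f = 0.5), alternating — and the
    rod is shortened so the summed capsule volume still equals the draw.

    With ``render=False`` only specs and the truth table are produced (no
    voxelization), which is what population-level statistics need.

    Returns the phantom list and a truth table with the standard
    morphometric record columns.
    """
    phantoms: list[tuple[PhantomSpec, GroundTruth, VoxelVolume | None]] = []
    rows = []
    r = spec.radius_um
    min_volume = capsule_volume(4 * r, r)  # shortest rod kept resolvable
    idx = 0
    for condition in spec.conditions:
        p_branch = spec.branch_probability.get(condition, 0.0)
        for tp in spec.timepoints_hpf:
            mean = spec.mean_volume_um3[(condition, tp)]
            for k in range(spec.n_per_group):
                rng = np.random.default_rng([spec.seed % (2**31), idx])
                vol_draw = max(rng.normal(mean, spec.volume_cv * mean), min_volume)
                branched = rng.random() < p_branch
                if branched:
                    tip_split = k % 2 == 0
                    branch_len = max(4 * r, 0.15 * _rod_length_for_volume(vol_draw, r))
                    n_arms = 2 if tip_split else 1
                    rod_vol = max(vol_draw - n_arms * capsule_volume(branch_len, r), min_volume)
                    L = _rod_length_for_volume(rod_vol, r)
                    base = RodPrimitive((0.0, 0.0, 0.0), (0.0, 0.0, L), r)
                    f = 1.0 if tip_split else 0.5
                    attach = np.array([0.0, 0.0, f * L])
                    d = np.array([0.0, 1.0, 1.0]) / math.sqrt(2)
                    if tip_split:
                        d2 = np.array([0.0, -1.0, 1.0]) / math.sqrt(2)
                        arms = (
                            RodPrimitive(tuple(attach), tuple(attach + branch_len * d), r),
                            RodPrimitive(tuple(attach), tuple(attach + branch_len * d2), r),
                        )
                        tip_pts = (base.p0, arms[0].p1, arms[1].p1)
                    else:
                        arms = (
                            RodPrimitive(tuple(attach), tuple(attach + branch_len * d), r),
                        )
                        tip_pts = (base.p0, base.p1, arms[0].p1)
                    prims = (base,) + arms
                    truth = GroundTruth(
                        total_centerline_length_um=L + n_arms * branch_len,
                        radius_um=r,
                        analytic_volume_um3=capsule_volume(L, r)
                        + n_arms * capsule_volume(branch_len, r),
                        expected_tips=3,
                        expected_junctions=1,
                        tip_points_um=tip_pts,
                        junction_points_um=(tuple(attach),),
                    )
                else:
                    L = _rod_length_for_volume(vol_draw, r)
                    base = RodPrimitive((0.0, 0.0, 0.0), (0.0, 0.0, L), r)
                    prims = (base,)
                    truth = GroundTruth(
                        total_centerline_length_um=L,
                        radius_um=r,
                        analytic_volume_um3=capsule_volume(L, r),
                        expected_tips=2,
                        expected_junctions=0,
                        tip_points_um=(base.p0, base.p1),
                    )
                pspec = PhantomSpec(
                    primitives=prims, spacing=spec.spacing, pad=3, seed=int(rng.integers(2**31))
                )
                volume = voxelize(pspec) if render else None
                phantoms.append((pspec, truth, volume))
                rows.append(
                    {
                        "spicule_id": f"{condition}_{tp:g}hpf_{k:03d}",
                        "condition": condition,
                        "timepoint_hpf": tp,
                        "volume_um3": truth.analytic_volume_um3,
                        "surface_area_um2": sum(
                            capsule_surface_area(p.length, p.radius) for p in prims
                        ),
                        "total_length_um": truth.total_centerline_length_um,
                        "mean_thickness_um": 2 * r,
                        "n_tips": truth.expected_tips,
                        "n_junctions": truth.expected_junctions,
                    }
                )
                idx += 1
    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return phantoms, table


# -- fluorescence fixtures ----------------------------------------------------

#: Mean stained-signal region ratios (skeletogenic / ectoderm) measured in the
#: study per timepoint and condition; these are the densities the fixture
#: generator reproduces (ectoderm baseline density 0.1).
ROCK_RATIO_BY_GROUP: dict[tuple[int, str], float] = {
    (22, "control"): 1.3,
    (22, "vegfr_inhibited"): 1.0,
    (27, "control"): 1.8,
    (27, "vegfr_inhibited"): 1.6,
    (33, "control"): 4.6,
    (33, "vegfr_inhibited"): 1.5,
}

#: Mean F-actin (phalloidin) tip/back signal ratio at 33 hpf.
PHALLOIDIN_TIP_BACK_RATIO = 3.0

_STAINED_LEVEL = 200
_BG_LEVEL = 10


def make_fluor_fixture(
    shape: tuple[int, int],
    region_masks: Mapping[str, np.ndarray],
    stained_density_per_region: Mapping[str, float],
    blob_spec: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    max_retries: int = 2000,
) -> tuple[np.ndarray, dict[str, np.ndarray], pd.DataFrame]:
    """Build a 2D image with known stained-pixel counts per named region.

    Within each region the requested fraction of pixels (rounded to the
    nearest count) is set to the stained level; any threshold between the
    background and stained levels recovers them exactly. A region may instead
    carry ``blob_spec[region] = (count, radius)`` circular blobs placed
    without overlap (its density entry must then be absent or 0 — blob pixels
    are the stained pixels, so both blob and stained truths stay exact).

    Returns the image, the masks (as passed), and a truth table with columns
    region, area_px, stained_px, n_blobs.
    """
    rng = np.random.default_rng([seed % (2**31), 0xF1D0])
    img = np.full(shape, _BG_LEVEL, dtype=np.uint16)
    occupancy = np.zeros(shape, dtype=bool)
    for name_a, m_a in region_masks.items():
        if m_a.shape != shape:
            raise ValueError(f"mask {name_a!r} shape mismatch")
        for name_b, m_b in region_masks.items():
            if name_a < name_b and np.any(m_a & m_b):
                raise ValueError(f"regions {name_a!r} and {name_b!r} overlap")
    rows = []
    blob_spec = dict(blob_spec or {})
    for name, mask in region_masks.items():
        area = int(mask.sum())
        if area == 0:
            raise ValueError(f"region {name!r} is empty")
        n_blobs = 0
        stained = 0
        if name in blob_spec:
            if stained_density_per_region.get(name, 0.0) != 0.0:
                raise ValueError(
                    f"region {name!r} has both blobs and nonzero scatter density; "
                    "blob regions derive stained counts from blob pixels only"
                )
            count, radius = blob_spec[name]
            ys, xs = np.nonzero(mask)
            placed = 0
            tries = 0
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            while placed < count:
                tries += 1
                if tries > max_retries:
                    raise RuntimeError(
                        f"could not place {count} blobs of radius {radius} in region {name!r}"
                    )
                j = int(rng.integers(len(ys)))
                cy, cx = int(ys[j]), int(xs[j])
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
                # keep the blob inside the region and 8-disconnected from others
                halo = ndimage.binary_dilation(disk, structure=np.ones((3, 3), bool))
                if not np.all(mask[disk]) or np.any(occupancy & halo):
                    continue
                img[disk] = _STAINED_LEVEL
                occupancy |= disk
                stained += int(disk.sum())
                placed += 1
            n_blobs = count
        else:
            density = float(stained_density_per_region.get(name, 0.0))
            if not 0 <= density <= 1:
                raise ValueError(f"density for {name!r} out of [0, 1]")
            stained = int(round(density * area))
            flat = np.flatnonzero(mask.ravel())
            chosen = rng.choice(flat, size=stained, replace=False)
            img.ravel()[chosen] = _STAINED_LEVEL
        rows.append(
            {"region": name, "area_px": area, "stained_px": stained, "n_blobs": n_blobs}
        )
    truth = pd.DataFrame(rows)
    return img, dict(region_masks), truth
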