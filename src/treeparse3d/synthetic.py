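"""Synthetic rubber-plantation point-cloud generator.

Emulates the structural regimes of a managed plantation survey: trees planted
in rows at regular intervals, adjacent crowns interpenetrating, a strong
vertical density gradient (dense foliage returns in the upper canopy, sparse
returns around trunks), mixed growth stages (young trees at roughly half the
mature scale), per-point semantic labels (crown = 1, background = 0), unique
instance IDs for crowns, and a paired top-view polygon annotation per crown.

The tree model is an ellipsoidal crown over a cylindrical trunk — the
simplest shape family that exposes crown overlap and the canopy-to-trunk
density contrast. Points are drawn uniformly inside each solid at the
configured volumetric density, a ground layer is sampled at areal density,
and one deterministic apex return is added per tree (the first return a
nadir scanner records from the treetop), which pins the max-z height of each
instance at finite density. All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CrownAnnotationSet, PointCloud, ValidationError

__all__ = ["PlantationSpec", "generate_plantation", "generate_topview_json"]


@dataclass
class PlantationSpec:
    """Layout and sampling regime for one synthetic plantation block.

    Defaults mirror a managed rubber stand: 3 m in-row spacing, 7 m between
    rows, mature heights 14-20 m, crown radii 1.0-1.8 m, a 10:1 canopy-to-
    trunk volumetric density ratio, and a 70/30 mature/young mix.
    """

    rows: int = 4
    trees_per_row: int = 5
    row_spacing: float = 7.0          # m between rows
    tree_spacing: float = 3.0         # m within a row
    crown_radius_range: tuple[float, float] = (1.0, 1.8)
    height_range: tuple[float, float] = (14.0, 20.0)
    overlap_factor: float = 0.1       # fraction of crown radius interpenetrating
    canopy_density: float = 25.0      # points / m^3 inside crowns
    trunk_density: float = 2.5        # points / m^3 inside trunks
    ground_density: float = 40.0      # points / m^2 of ground/understory returns
    growth_stage_mix: tuple[float, float] = (0.3, 0.7)   # (young, mature)
    stage_layout: str = "random"      # or "alternating": deterministic
                                      # young/mature checkerboard
    young_scale: float = 0.5
    noise_sd: float = 0.03            # m, isotropic jitter on every return
    seed: int = 0

    def validate(self) -> None:
        if self.rows * self.trees_per_row < 1:
            raise ValidationError("spec yields 0 trees")
        if self.canopy_density <= 0 or self.trunk_density <= 0:
            raise ValidationError("densities must be > 0")
        if self.canopy_density <= self.trunk_density:
            raise ValidationError("canopy_density must exceed trunk_density")
        if self.overlap_factor < 0:
            raise ValidationError("overlap_factor must be >= 0")
        if abs(sum(self.growth_stage_mix) - 1.0) > 1e-9:
            raise ValidationError("growth_stage_mix proportions must sum to 1")


@dataclass
class _Tree:
    instance_id: int
    x: float
    y: float
    height: float
    crown_radius: float
    crown_semi_z: float       # vertical semi-axis of the crown ellipsoid
    trunk_radius: float
    stage: str


def _sample_ellipsoid(rng, n, center, semi):
    """Uniform points inside an axis-aligned ellipsoid."""
    pts = np.empty((0, 3))
    while len(pts) < n:
        cand = rng.uniform(-1.0, 1.0, size=(max(2 * (n - len(pts)), 16), 3))
        cand = cand[(cand ** 2).sum(axis=1) <= 1.0]
        pts = np.vstack([pts, cand])
    return pts[:n] * semi + center


def _sample_cylinder(rng, n, center_xy, radius, z0, z1):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    z = rng.uniform(z0, z1, size=n)
    return np.stack([center_xy[0] + r * np.cos(th),
                     center_xy[1] + r * np.sin(th), z], axis=1)


def _layout_trees(spec: PlantationSpec, rng: np.random.Generator) -> list[_Tree]:
    spacing = min(spec.row_spacing, spec.tree_spacing)
    # cap the radius so two adjacent crowns interpenetrate by at most
    # overlap_factor * r: 2r - s = f*r  =>  r = s / (2 - f)
    r_cap = spacing / (2.0 - min(spec.overlap_factor, 1.0))
    p_young = spec.growth_stage_mix[0]
    trees = []
    inst_id = 1
    for i in range(spec.rows):
        for j in range(spec.trees_per_row):
            if spec.stage_layout == "alternating":
                stage = "young" if (i + j) % 2 else "mature"
            else:
                stage = "young" if rng.uniform() < p_young else "mature"
            scale = spec.young_scale if stage == "young" else 1.0
            h = rng.uniform(*spec.height_range) * scale
            r = min(rng.uniform(*spec.crown_radius_range), r_cap) * scale
            jitter = rng.normal(0.0, 0.05, size=2)
            trees.append(_Tree(
                instance_id=inst_id,
                x=i * spec.row_spacing + jitter[0],
                y=j * spec.tree_spacing + jitter[1],
                height=h,
                crown_radius=r,
                crown_semi_z=0.3 * h,
                trunk_radius=max(0.06, 0.1 * r),
                stage=stage,
            ))
            inst_id += 1
    return trees


def generate_plantation(
    spec: PlantationSpec,
) -> tuple[PointCloud, CrownAnnotationSet, pd.DataFrame]:
    """Generate one labeled plantation block.

    Returns the labeled point cloud, the paired top-view crown-polygon
    annotation set (cloud XY coordinates, identity alignment) and a
    ground-truth table with one row per tree: position, height, analytic
    crown diameter/volume, trunk geometry and growth stage.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trees = _layout_trees(spec, rng)

    chunks, sem_chunks, inst_chunks = [], [], []
    records = []
    for t in trees:
        a, c = t.crown_radius, t.crown_semi_z
        crown_center = np.array([t.x, t.y, t.height - c])
        crown_vol = 4.0 / 3.0 * np.pi * a * a * c
        n_crown = rng.poisson(spec.canopy_density * crown_vol)
        crown_pts = _sample_ellipsoid(rng, n_crown, crown_center, (a, a, c))
        # deterministic apex return from the treetop
        crown_pts = np.vstack([crown_pts, [t.x, t.y, t.height]])

        trunk_top = t.height - c            # trunk reaches into the crown base
        trunk_vol = np.pi * t.trunk_radius ** 2 * trunk_top
        n_trunk = rng.poisson(spec.trunk_density * trunk_vol)
        trunk_pts = _sample_cylinder(rng, n_trunk, (t.x, t.y),
                                     t.trunk_radius, 0.0, trunk_top)

        chunks += [crown_pts, trunk_pts]
        sem_chunks += [np.ones(len(crown_pts), dtype=np.int64),
                       np.zeros(len(trunk_pts), dtype=np.int64)]
        inst_chunks += [np.full(len(crown_pts), t.instance_id, dtype=np.int64),
                        np.zeros(len(trunk_pts), dtype=np.int64)]
        records.append({
            "instance_id": t.instance_id, "x": t.x, "y": t.y,
            "height": t.height, "crown_diameter": 2.0 * a,
            "crown_volume": crown_vol, "crown_semi_z": c,
            "trunk_radius": t.trunk_radius, "trunk_top": trunk_top,
            "stage": t.stage,
        })

    # ground layer over the block footprint (background class mass)
    margin = 2.0
    xs = [t.x for t in trees]
    ys = [t.y for t in trees]
    x0, x1 = min(xs) - margin, max(xs) + margin
    y0, y1 = min(ys) - margin, max(ys) + margin
    n_ground = rng.poisson(spec.ground_density * (x1 - x0) * (y1 - y0))
    if n_ground > 0:
        gx = rng.uniform(x0, x1, size=n_ground)
        gy = rng.uniform(y0, y1, size=n_ground)
        gz = np.abs(rng.normal(0.0, 0.05, size=n_ground))
        chunks.append(np.stack([gx, gy, gz], axis=1))
        sem_chunks.append(np.zeros(n_ground, dtype=np.int64))
        inst_chunks.append(np.zeros(n_ground, dtype=np.int64))

    coords = np.vstack(chunks)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    pc = PointCloud(coords, np.concatenate(sem_chunks),
                    np.concatenate(inst_chunks))
    gt = pd.DataFrame.from_records(records).set_index("instance_id",
                                                      drop=False)
    ann = generate_topview_json(pc, gt)
    return pc, ann, gt


def generate_topview_json(pc: PointCloud, gt: pd.DataFrame) -> CrownAnnotationSet:
    """Build the top-view annotation: convex hull of each instance's XY."""
    from scipy.spatial import ConvexHull, QhullError

    if pc.instance is None:
        raise ValidationError("instance labels required for top-view annotation")
    polygons = []
    labels = {}
    for inst_id in np.unique(pc.instance[pc.instance > 0]):
        xy = pc.coords[pc.instance == inst_id, :2]
        xy = np.unique(xy, axis=0)
        if len(xy) < 3:
            import logging
            logging.getLogger(__name__).warning(
                "instance %d has < 3 distinct XY points; skipped", inst_id)
            continue
        try:
            hull = ConvexHull(xy)
        except QhullError:
            continue
        polygons.append((int(inst_id), xy[hull.vertices]))
        labels[int(inst_id)] = "crown"
    bounds = None
    if polygons:
        allxy = pc.coords[:, :2]
        bounds = (allxy[:, 0].min(), allxy[:, 1].min(),
                  allxy[:, 0].max(), allxy[:, 1].max())
    return CrownAnnotationSet(polygons=polygons, class_labels=labels,
                              region_bounds=bounds)
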