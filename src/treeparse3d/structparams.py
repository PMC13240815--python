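"""Tree-level structural parameter extraction.

For each segmented instance three standard forest-inventory parameters are
computed:

* height — max z minus the ground elevation under the instance;
* crown diameter — diameter of the circle with the same area as the convex
  hull of the crown points' XY projection, 2*sqrt(area/pi);
* crown volume — occupied-voxel volume of the crown points at a configured
  voxel size.

Ground elevation defaults to the z = 0 plane (the synthetic-generator
convention); a per-point ground column may be supplied for real data.
``agreement`` reports per-parameter R^2 (coefficient of determination
against the identity fit pred = truth) and RMSE, optionally broken down by
block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io_formats import PointCloud, ValidationError

log = logging.getLogger(__name__)

__all__ = ["TreeMetrics", "AgreementReport", "extract_metrics", "agreement"]


@dataclass
class TreeMetrics:
    instance_id: int
    height: float
    crown_diameter: float
    crown_volume: float


@dataclass
class AgreementReport:
    per_parameter: pd.DataFrame          # index: parameter; cols: r2, rmse, n
    per_block: pd.DataFrame | None = None


def _crown_diameter(xy: np.ndarray) -> float:
    xy = np.unique(xy, axis=0)
    if len(xy) < 3:
        if len(xy) == 2:
            return float(np.linalg.norm(xy[0] - xy[1]))
        return 0.0
    try:
        hull = ConvexHull(xy)
    except QhullError:        # collinear points
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
        return float(d.max())
    return float(2.0 * np.sqrt(hull.volume / np.pi))   # 2D hull.volume = area


def _crown_volume(pts: np.ndarray, voxel_size: float) -> float:
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        log.warning("instance has < 4 non-coplanar points; volume set to 0")
        return 0.0
    idx = np.floor(pts / voxel_size).astype(np.int64)
    return float(len(np.unique(idx, axis=0)) * voxel_size ** 3)


def extract_metrics(pc: PointCloud, ground_z: float | np.ndarray = 0.0,
                    voxel_size: float = 0.2) -> list[TreeMetrics]:
    """Per-instance height, crown diameter and crown volume.

    Height uses all points of the instance; diameter and volume use its
    crown points (semantic = 1) when semantic labels are present.
    """
    if pc.instance is None:
        raise ValidationError("instance labels required")
    ground = np.broadcast_to(np.asarray(ground_z, dtype=float), (len(pc),))
    out = []
    for inst_id in np.unique(pc.instance[pc.instance > 0]):
        mask = pc.instance == inst_id
        pts = pc.coords[mask]
        height = float((pts[:, 2] - ground[mask]).max())
        if pc.semantic is not None:
            crown = pts[pc.semantic[mask] == 1]
            crown = crown if len(crown) else pts
        else:
            crown = pts
        out.append(TreeMetrics(
            instance_id=int(inst_id),
            height=height,
            crown_diameter=_crown_diameter(crown[:, :2]),
            crown_volume=_crown_volume(crown, voxel_size),
        ))
    return out


_PARAMS = ("height", "crown_diameter", "crown_volume")


def _r2_rmse(p: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    resid = p - t
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return r2, rmse


def agreement(pred: list[TreeMetrics], truth: list[TreeMetrics],
              blocks: dict[int, object] | None = None) -> AgreementReport:
    """R^2 / RMSE per parameter over instances matched by ID.

    With fewer than 2 matched trees (or zero truth variance) R^2 is
    undefined and reported as NaN.
    """
    pmap = {m.instance_id: m for m in pred}
    tmap = {m.instance_id: m for m in truth}
    ids = sorted(set(pmap) & set(tmap))
    rows = {}
    for param in _PARAMS:
        p = np.array([getattr(pmap[i], param) for i in ids])
        t = np.array([getattr(tmap[i], param) for i in ids])
        if len(ids) < 2:
            rows[param] = {"r2": np.nan,
                           "rmse": float(np.abs(p - t).mean()) if len(ids) else np.nan,
                           "n": len(ids)}
            continue
        r2, rmse = _r2_rmse(p, t)
        rows[param] = {"r2": r2, "rmse": rmse, "n": len(ids)}
    per_param = pd.DataFrame(rows).T
    per_block = None
    if blocks:
        recs = []
        for blk in sorted(set(blocks.values()), key=str):
            sub = [i for i in ids if blocks.get(i) == blk]
            for param in _PARAMS:
                p = np.array([getattr(pmap[i], param) for i in sub])
                t = np.array([getattr(tmap[i], param) for i in sub])
                if len(sub) >= 2:
                    r2, rmse = _r2_rmse(p, t)
                else:
                    r2, rmse = np.nan, np.nan
                recs.append({"block": blk, "parameter": param,
                             "r2": r2, "rmse": rmse, "n": len(sub)})
        per_block = pd.DataFrame.from_records(recs)
    return AgreementReport(per_parameter=per_param, per_block=per_block)
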