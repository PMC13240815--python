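"""Adaptive Lemming Optimization Clustering (ALOC).

A closed-loop metaheuristic that tunes clustering hyperparameters for
instance-level crown separation. One of two clustering backends is chosen
by input size:

* ``knn`` (segments below ``size_threshold`` points) — a k-nearest-neighbor
  graph with edges longer than a merge distance removed; connected
  components become instances. theta = (k, merge_distance).
* ``meanshift`` (larger segments) — scikit-learn MeanShift on the XY
  projection of the upper-canopy core (points within the top fraction of a
  coarse canopy-height grid, so each tree contributes its own crown top
  regardless of growth stage); every point is then assigned to the nearest
  mode and clusters below a minimum size are merged into the nearest
  retained mode. theta = (bandwidth, min_cluster_size).

The search alternates two phases driven by the dynamic control factor

    E = 2 * ln(1/random()) * theta_angle,
    theta_angle = 2 * arctan(1 - iteration/max_iter),

global Levy-flight exploration while E > 1, and exploitation when E <= 1:
the DS / GFT parameter updates (picked with probability 0.5 each)

    DS:  theta_new = theta_best + F * R * B * r1 * (theta_best - theta_current)
    GFT: theta_new = theta_current + F * r2 * (theta_best - theta_current)

optionally followed by a spiral local-search step

    radius = ||theta_best - theta_current||_2,
    spiral = radius * (sin(2 pi r3) + cos(2 pi r3)),
    theta_new = theta_best + F * theta_current * spiral * random().

Every update is clamped to the per-component bounds. A candidate is scored
by the feedback rule

    score_eval = alpha * mean(F1) + (1 - alpha) * max(F1),  alpha = 0.7,

over the validation samples, and the incumbent (theta_best, best_score) is
updated only when score_eval exceeds the historical best; the walking state
theta_current always moves to the candidate so the search keeps exploring.
The Levy-flight step length is step = u / |v|^(1/beta) with u ~ N(0, sigma^2),
v ~ N(0, 1), beta = 1.5 and the sigma scale from the standard Mantegna
formula. During supervised refinement the scorer compares candidate
clusterings against labeled validation blocks; at pure inference time a
silhouette-based proxy objective is provided (clearly a stand-in, not part
of the published feedback rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.special import gamma as gamma_fn
from sklearn.cluster import MeanShift
from sklearn.neighbors import kneighbors_graph

from .io_formats import PointCloud, ValidationError
from .metrics import match_instances

log = logging.getLogger(__name__)

__all__ = [
    "LevySampler", "SearchState", "ClusterParams", "select_backend",
    "levy_sigma", "control_factor", "exploit_update", "spiral_update",
    "feedback_score", "optimize", "cluster_with", "make_supervised_scorer",
    "make_proxy_scorer", "DEFAULT_BOUNDS",
]

DEFAULT_BOUNDS = {
    "knn": np.array([[2.0, 30.0], [0.2, 4.0]]),        # k, merge distance (m)
    "meanshift": np.array([[0.5, 5.0], [1.0, 100.0]]), # bandwidth (m), min size
}


@dataclass
class ClusterParams:
    theta: np.ndarray
    bounds: np.ndarray            # per-component [lo, hi]

    def clamp(self) -> "ClusterParams":
        self.theta = np.clip(self.theta, self.bounds[:, 0], self.bounds[:, 1])
        return self


@dataclass
class LevySampler:
    beta: float = 1.5
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self):
        if not 0.0 < self.beta <= 2.0:
            raise ValidationError("beta must lie in (0, 2]")
        self.sigma = levy_sigma(self.beta)

    def step(self, dim: int) -> np.ndarray:
        u = self.rng.normal(0.0, self.sigma, size=dim)
        v = self.rng.normal(0.0, 1.0, size=dim)
        while (v == 0.0).any():          # probability-zero guard
            v[v == 0.0] = self.rng.normal(0.0, 1.0, size=int((v == 0.0).sum()))
        return u / np.abs(v) ** (1.0 / self.beta)


@dataclass
class SearchState:
    iteration: int = 0
    max_iter: int = 50
    f_scale: float = 0.5
    best_params: np.ndarray | None = None
    best_score: float = -np.inf
    history: list[float] = field(default_factory=list)


def levy_sigma(beta: float = 1.5) -> float:
    """Mantegna scale: sigma(1.5) ~= 0.696575."""
    num = gamma_fn(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = gamma_fn((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def angular_control(iteration: int, max_iter: int) -> float:
    """theta_angle = 2 * arctan(1 - iteration/max_iter)."""
    return 2.0 * np.arctan(1.0 - iteration / max_iter)


def control_factor(iteration: int, max_iter: int,
                   rng: np.random.Generator) -> float:
    """E = 2 * ln(1/random()) * theta_angle; 0 exactly at the final iteration."""
    if not 0 <= iteration <= max_iter or max_iter < 1:
        raise ValidationError("need 0 <= iteration <= max_iter, max_iter >= 1")
    r = rng.uniform()
    while r == 0.0:
        r = rng.uniform()
    return 2.0 * np.log(1.0 / r) * angular_control(iteration, max_iter)


def exploit_update(state: SearchState, params: ClusterParams, variant: str,
                   rng: np.random.Generator) -> ClusterParams:
    """DS / GFT exploitation step toward theta_best, clamped to bounds."""
    if state.best_params is None:
        return params
    theta_best = state.best_params
    theta_cur = params.theta
    if variant == "ds":
        r_pert = rng.normal()
        b_pert = rng.normal()
        r1 = rng.uniform()
        theta_new = theta_best + state.f_scale * r_pert * b_pert * r1 * \
            (theta_best - theta_cur)
    elif variant == "gft":
        r2 = rng.uniform()
        theta_new = theta_cur + state.f_scale * r2 * (theta_best - theta_cur)
    else:
        raise ValidationError(f"unknown exploit variant {variant!r}")
    return ClusterParams(theta_new, params.bounds).clamp()


def spiral_update(state: SearchState, params: ClusterParams,
                  rng: np.random.Generator) -> ClusterParams:
    """Spiral local refinement around theta_best, clamped to bounds."""
    if state.best_params is None:
        return params
    radius = float(np.linalg.norm(state.best_params - params.theta))
    r3 = rng.uniform()
    spiral = radius * (np.sin(2 * np.pi * r3) + np.cos(2 * np.pi * r3))
    theta_new = state.best_params + \
        state.f_scale * params.theta * spiral * rng.uniform()
    return ClusterParams(theta_new, params.bounds).clamp()


def feedback_score(f1_per_sample: np.ndarray, alpha: float = 0.7) -> float:
    """score_eval = alpha * mean(F1) + (1 - alpha) * max(F1)."""
    f1 = np.asarray(f1_per_sample, dtype=float)
    if f1.size == 0:
        raise ValidationError("feedback_score needs a non-empty F1 vector")
    if (f1 < 0).any() or (f1 > 1).any():
        raise ValidationError("F1 values must lie in [0, 1]")
    return float(alpha * f1.mean() + (1.0 - alpha) * f1.max())


def select_backend(pc_segment: PointCloud | int,
                   size_threshold: int = 5000) -> str:
    """knn for segments with fewer than size_threshold points, else meanshift."""
    n = pc_segment if isinstance(pc_segment, int) else len(pc_segment)
    if n < 1:
        raise ValidationError("segment is empty")
    return "knn" if n < size_threshold else "meanshift"


# ---------------------------------------------------------------------------
# clustering backends
# ---------------------------------------------------------------------------

def _cluster_knn(xyz: np.ndarray, theta: np.ndarray) -> np.ndarray:
    xy = xyz[:, :2]
    k = int(round(theta[0]))
    k = max(1, min(k, len(xy) - 1)) if len(xy) > 1 else 0
    if k == 0:
        return np.ones(len(xy), dtype=np.int64)
    g = kneighbors_graph(xy, n_neighbors=k, mode="distance")
    g.data[g.data > theta[1]] = 0.0
    g.eliminate_zeros()
    _, labels = connected_components(g, directed=False)
    return labels.astype(np.int64) + 1


_MAX_MEANSHIFT_POINTS = 2500
_CHM_CELL = 1.0           # m, canopy-height grid for core extraction
_CORE_FRACTION = 0.7      # keep points with z >= fraction * local canopy top


def _canopy_core(xyz: np.ndarray) -> np.ndarray:
    """Mask of upper-canopy points: z within the top fraction of the local
    canopy-height cell, so mode seeking sees one well-separated blob per
    crown top at any growth stage."""
    cell = np.floor(xyz[:, :2] / _CHM_CELL).astype(np.int64)
    _, inv = np.unique(cell, axis=0, return_inverse=True)
    chm = np.full(inv.max() + 1, -np.inf)
    np.maximum.at(chm, inv, xyz[:, 2])
    return xyz[:, 2] >= _CORE_FRACTION * chm[inv]


def _cluster_meanshift(xyz: np.ndarray, theta: np.ndarray,
                       seed: int = 0) -> np.ndarray:
    bandwidth = float(theta[0])
    min_size = max(1, int(round(theta[1])))
    xy = xyz[:, :2]
    core = _canopy_core(xyz)
    fit_xy = xy[core] if core.sum() >= 3 else xy
    if len(fit_xy) > _MAX_MEANSHIFT_POINTS:
        sub = np.random.default_rng(seed).choice(
            len(fit_xy), _MAX_MEANSHIFT_POINTS, replace=False)
        fit_xy = fit_xy[sub]
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=True)
    try:
        ms.fit(fit_xy)
    except ValueError:      # bin_seeding can leave no seeds at odd bandwidths
        ms = MeanShift(bandwidth=bandwidth, bin_seeding=False)
        ms.fit(fit_xy)
    centers = ms.cluster_centers_
    d = np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2)
    labels = d.argmin(axis=1)
    # merge clusters below the minimum size into the nearest retained mode
    sizes = np.bincount(labels, minlength=len(centers))
    keep = np.flatnonzero(sizes >= min_size)
    if len(keep) == 0:
        keep = np.array([sizes.argmax()])
    d_keep = d[:, keep]
    labels = keep[d_keep.argmin(axis=1)]
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(np.int64) + 1


def cluster_with(backend: str, xyz: np.ndarray, theta: np.ndarray,
                 seed: int = 0) -> np.ndarray:
    """Run the named backend on foreground coordinates; labels in {1..M}."""
    if backend == "knn":
        return _cluster_knn(xyz, theta)
    if backend == "meanshift":
        return _cluster_meanshift(xyz, theta, seed=seed)
    raise ValidationError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------

def make_supervised_scorer(gt_instances: np.ndarray, tau: float = 0.5):
    """Per-sample instance F-score against labeled validation ground truth."""
    gt = np.asarray(gt_instances)

    def scorer(pred_instances: np.ndarray) -> np.ndarray:
        res = match_instances(pred_instances, gt, tau=tau)
        return np.array([res.fscore])

    return scorer


def _chm_peak_count(coords: np.ndarray, cell: float = 1.0,
                    min_height: float = 2.0) -> int:
    """Count local maxima of the coarse canopy-height model — a label-free
    estimate of how many tree tops a block holds."""
    from scipy.ndimage import maximum_filter

    ij = np.floor((coords[:, :2] - coords[:, :2].min(axis=0)) / cell)
    ij = ij.astype(np.int64)
    chm = np.zeros(ij.max(axis=0) + 1)
    np.maximum.at(chm, tuple(ij.T), coords[:, 2])
    neigh = maximum_filter(chm, size=3)
    peaks = (chm == neigh) & (chm >= min_height)
    # merge adjacent peak cells (plateaus) into single summits
    from scipy.ndimage import label as cc_label
    _, n = cc_label(peaks)
    return max(int(n), 1)


def make_proxy_scorer(coords: np.ndarray, seed: int = 0,
                      max_points: int = 1500):
    """Unsupervised stand-in objective for pure inference time.

    Combines the XY silhouette of the candidate clustering (mapped onto
    [0, 1]) with agreement between the cluster count and the number of
    canopy-height-model peaks. ``coords`` must cover the full cloud (same
    length as the instance map the scorer receives). This objective is a
    clearly-labeled substitute for the supervised validation feedback; it is
    not part of the published feedback rule.
    """
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(seed)
    xy = coords[:, :2]
    k_est = _chm_peak_count(coords)

    def scorer(pred_instances: np.ndarray) -> np.ndarray:
        labels = pred_instances[pred_instances > 0]
        pts = xy[pred_instances > 0]
        k = len(np.unique(labels))
        if k < 2 or len(labels) < 3:
            sil = 0.0 if k_est > 1 else 1.0
        else:
            if len(labels) > max_points:
                sub = rng.choice(len(labels), max_points, replace=False)
                pts_s, labels_s = pts[sub], labels[sub]
            else:
                pts_s, labels_s = pts, labels
            if len(np.unique(labels_s)) < 2:
                sil = 0.0
            else:
                sil = (silhouette_score(pts_s, labels_s) + 1.0) / 2.0
        count_term = 1.0 / (1.0 + abs(k - k_est))
        return np.array([0.5 * sil + 0.5 * count_term])

    return scorer


# ---------------------------------------------------------------------------
# the closed-loop optimizer
# ---------------------------------------------------------------------------

@dataclass
class InstanceSegmentation:
    instance: np.ndarray            # per-point IDs over the full cloud
    best_params: np.ndarray
    best_score: float
    backend: str
    state: SearchState


def optimize(pc: PointCloud, val_fn=None, max_iter: int = 50,
             seed: int = 0, size_threshold: int = 5000,
             bounds: np.ndarray | None = None, alpha: float = 0.7,
             stop_score: float = 0.999,
             foreground: np.ndarray | None = None) -> InstanceSegmentation:
    """Closed-loop clustering-parameter search; returns the incumbent map.

    ``foreground`` defaults to the cloud's semantic crown labels (or all
    points when unlabeled); ``val_fn`` maps a full-length instance map to a
    vector of per-sample F-scores and defaults to the silhouette proxy.
    """
    if foreground is None:
        foreground = (pc.semantic == 1) if pc.semantic is not None \
            else np.ones(len(pc), dtype=bool)
    fg_idx = np.flatnonzero(foreground)
    full = np.zeros(len(pc), dtype=np.int64)
    state = SearchState(max_iter=max_iter)
    if len(fg_idx) == 0:
        log.warning("no foreground points; returning empty segmentation")
        return InstanceSegmentation(full, np.array([]), 0.0, "none", state)

    fg_coords = pc.coords[fg_idx]
    backend = select_backend(len(fg_idx), size_threshold)
    bnds = np.asarray(bounds) if bounds is not None else DEFAULT_BOUNDS[backend]
    rng = np.random.default_rng(seed)
    levy = LevySampler(rng=rng)
    if val_fn is None:
        val_fn = make_proxy_scorer(pc.coords, seed=seed)

    def evaluate(theta: np.ndarray) -> tuple[float, np.ndarray]:
        labels = cluster_with(backend, fg_coords, theta, seed=seed)
        pred_full = np.zeros(len(pc), dtype=np.int64)
        pred_full[fg_idx] = labels
        return feedback_score(val_fn(pred_full), alpha=alpha), pred_full

    scale = bnds[:, 1] - bnds[:, 0]
    # multi-start initialization: a short sweep across the box seeds the
    # incumbent before the closed-loop search takes over
    n_init = min(5, max_iter + 1) if max_iter > 0 else 1
    fracs = np.linspace(0.1, 0.9, n_init)
    init_thetas = [bnds[:, 0] + f * scale for f in fracs]
    best_map = None
    for theta0 in init_thetas:
        cand = ClusterParams(theta0.astype(float), bnds).clamp()
        score, cand_map = evaluate(cand.theta)
        if score > state.best_score:
            state.best_score = score
            state.best_params = cand.theta.copy()
            best_map = cand_map
        state.history.append(state.best_score)
    params = ClusterParams(state.best_params.copy(), bnds)

    for it in range(1, max_iter + 1):
        state.iteration = it
        if state.best_score >= stop_score:
            break
        e = control_factor(it, max_iter, rng)
        if e > 1.0:
            cand = ClusterParams(
                params.theta + 0.1 * scale * levy.step(len(params.theta)),
                bnds).clamp()
        else:
            variant = "ds" if rng.uniform() < 0.5 else "gft"
            cand = exploit_update(state, params, variant, rng)
            if rng.uniform() < 0.5:
                cand = spiral_update(state, cand, rng)
        cand_score, cand_map = evaluate(cand.theta)
        # incumbent accepted only on strict improvement
        if cand_score > state.best_score:
            state.best_score = cand_score
            state.best_params = cand.theta.copy()
            best_map = cand_map
        params = cand                     # the walker always moves on
        state.history.append(state.best_score)

    return InstanceSegmentation(best_map, state.best_params,
                                state.best_score, backend, state)
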