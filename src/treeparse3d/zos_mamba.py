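"""Z-order Selective Mamba (ZOS-Mamba).

Voxelizes the point cloud, serializes voxels along the Morton (Z-order)
curve — interleaving the binary bits of the integer voxel coordinates so
spatially adjacent voxels stay close in the 1D sequence — runs a selective
state-space scan over the serialized features, applies RMSNorm, and restores
the original spatial order.

Two scan modes are provided. ``sequential`` evaluates the discretized
recurrence

    x_{t+1} = exp(dt_t * A) x_t + dt_t B_t u_t,     y_t = C_t x_t + D u_t

step by step and is the correctness reference. ``parallel`` evaluates the
cumulative-sum form

    X = cumsum(exp(dt A) * dt B * u),               y = C X + D u

which coincides with the recurrence when A = 0 (and approaches it as
||A|| -> 0) but is not algebraically identical for general A; it is kept as
a selectable efficiency-motivated variant, never the reference.

The input-dependent parameters (dt, B, C) come from a seeded linear
projection of the input, with dt made positive by Softplus. Voxel features
are the mean over member points; after the scan each voxel's feature is
copied back to its member points, so the point count is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Linear, softplus
from .io_formats import PointCloud, ValidationError

__all__ = [
    "VoxelGrid", "ZOrderSequence", "SSMBlock", "voxelize", "zorder_encode",
    "build_zorder_sequence", "serialize", "restore", "selective_scan",
    "rmsnorm", "ZOSMambaEncoder", "ZOSConfig",
]


@dataclass
class VoxelGrid:
    voxel_size: float
    origin: np.ndarray
    voxel_coords: np.ndarray     # V x 3 integer coordinates of occupied voxels
    point_to_voxel: np.ndarray   # N-vector: index into voxel_coords

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)


@dataclass
class ZOrderSequence:
    b: int
    z_index: np.ndarray          # per-voxel Morton code
    perm: np.ndarray             # sorts voxels by ascending z_index
    inv_perm: np.ndarray


def voxelize(pc: PointCloud, voxel_size: float) -> VoxelGrid:
    """Assign every point to one voxel under half-open binning [k*s, (k+1)*s)."""
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    origin = pc.coords.min(axis=0)
    idx = np.floor((pc.coords - origin) / voxel_size).astype(np.int64)
    idx = np.maximum(idx, 0)     # guard the exact-min edge against fp rounding
    uniq, point_to_voxel = np.unique(idx, axis=0, return_inverse=True)
    return VoxelGrid(voxel_size=voxel_size, origin=origin,
                     voxel_coords=uniq, point_to_voxel=point_to_voxel)


def zorder_encode(voxel_coords: np.ndarray, b: int) -> np.ndarray:
    """Morton code: bit i of x goes to output bit 3i, y to 3i+1, z to 3i+2."""
    vc = np.asarray(voxel_coords, dtype=np.uint64)
    if vc.ndim == 1:
        vc = vc[None, :]
    for ax, name in enumerate("xyz"):
        if (vc[:, ax] >= (1 << b)).any():
            raise ValidationError(
                f"{name}-coordinate >= 2^{b}; increase encoding precision b")
    code = np.zeros(len(vc), dtype=np.uint64)
    one = np.uint64(1)
    for i in range(b):
        code |= ((vc[:, 0] >> np.uint64(i)) & one) << np.uint64(3 * i)
        code |= ((vc[:, 1] >> np.uint64(i)) & one) << np.uint64(3 * i + 1)
        code |= ((vc[:, 2] >> np.uint64(i)) & one) << np.uint64(3 * i + 2)
    return code


def build_zorder_sequence(voxel_coords: np.ndarray,
                          b: int | None = None) -> ZOrderSequence:
    """Morton-sort the voxels; b defaults to the minimal bits covering the grid."""
    vc = np.asarray(voxel_coords, dtype=np.int64)
    if b is None:
        b = max(1, int(np.ceil(np.log2(vc.max() + 1))) if vc.max() > 0 else 1)
    z = zorder_encode(vc, b)
    perm = np.argsort(z, kind="stable")      # stable tie-break by original index
    inv_perm = np.empty_like(perm)
    inv_perm[perm] = np.arange(len(perm))
    return ZOrderSequence(b=b, z_index=z, perm=perm, inv_perm=inv_perm)


def serialize(features: np.ndarray, seq: ZOrderSequence) -> np.ndarray:
    """Permute features into ascending Morton order."""
    if len(features) != len(seq.perm):
        raise ValidationError(
            f"feature count {len(features)} != sequence length {len(seq.perm)}")
    return features[seq.perm]


def restore(y_norm: np.ndarray, seq: ZOrderSequence) -> np.ndarray:
    """Invert ``serialize``: restore(serialize(x)) == x."""
    if len(y_norm) != len(seq.perm):
        raise ValidationError(
            f"feature count {len(y_norm)} != sequence length {len(seq.perm)}")
    out = np.empty_like(y_norm)
    out[seq.perm] = y_norm
    return out


class SSMBlock:
    """Selective state-space parameters with seeded projections.

    ``A`` is d x n (negative-diagonal style init for stable decay), ``d_skip``
    is the static feed-through initialized to 1. dt, B, C are produced by a
    linear projection of the input, with dt = Softplus(dt_hat) > 0.
    """

    def __init__(self, d: int, n_state: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d = d
        self.n_state = n_state
        self.A = -np.repeat(np.arange(1, n_state + 1, dtype=np.float64)[None, :],
                            d, axis=0)
        self.d_skip = np.ones(d)
        self.proj = Linear(d, d + 2 * n_state, rng)

    def input_params(self, u: np.ndarray):
        """(dt: T x d, B: T x n, C: T x n) from a linear projection of u."""
        p = self.proj(u)
        dt = softplus(p[:, :self.d])
        b = p[:, self.d:self.d + self.n_state]
        c = p[:, self.d + self.n_state:]
        if not np.isfinite(p).all():
            bad = int(np.argwhere(~np.isfinite(p).all(axis=1))[0, 0])
            raise FloatingPointError(f"NaN/Inf in scan parameters at step {bad}")
        return dt, b, c

    @property
    def n_params(self) -> int:
        return self.A.size + self.d_skip.size + self.proj.n_params


def selective_scan(u: np.ndarray, block: SSMBlock,
                   mode: str = "sequential") -> np.ndarray:
    """Run the selective scan over a T x d sequence; returns T x d output."""
    u = np.asarray(u, dtype=np.float64)
    T, d = u.shape
    dt, b, c = block.input_params(u)
    if mode == "sequential":
        x = np.zeros((d, block.n_state))
        y = np.empty_like(u)
        for t in range(T):
            decay = np.exp(dt[t][:, None] * block.A)            # d x n
            x = decay * x + (dt[t][:, None] * u[t][:, None]) * b[t][None, :]
            y[t] = x @ c[t] + block.d_skip * u[t]
        return y
    if mode == "parallel":
        # cumulative-sum form: X = cumsum(exp(dt A) * dt B * u); y = C X + D u
        decay = np.exp(dt[:, :, None] * block.A[None, :, :])     # T x d x n
        terms = decay * (dt * u)[:, :, None] * b[:, None, :]
        X = np.cumsum(terms, axis=0)
        y = np.einsum("tdn,tn->td", X, c) + block.d_skip * u
        return y
    raise ValidationError(f"unknown scan mode {mode!r}")


def rmsnorm(y: np.ndarray, w: np.ndarray | float = 1.0,
            eps: float = 1e-8) -> np.ndarray:
    """Row-wise RMS normalization: y / sqrt(mean(y^2) + eps) * w."""
    y = np.asarray(y, dtype=np.float64)
    rms = np.sqrt(np.mean(y * y, axis=-1, keepdims=True) + eps)
    return y / rms * w


@dataclass
class ZOSConfig:
    voxel_size: float = 0.2      # m
    d: int = 16                  # feature dim carried through the scan
    n_state: int = 8
    n_layers: int = 1
    scan_mode: str = "sequential"
    eps: float = 1e-8
    seed: int = 0


class ZOSMambaEncoder:
    """Voxel pool -> Morton serialize -> selective scan -> RMSNorm -> restore.

    Input per-point features are linearly lifted to width d; output is one
    d-vector per point (voxel feature copied back to member points), so the
    point count is always preserved.
    """

    def __init__(self, d_in: int, config: ZOSConfig | None = None):
        self.config = config or ZOSConfig()
        rng = np.random.default_rng(self.config.seed)
        self.lift = Linear(d_in, self.config.d, rng)
        self.blocks = [SSMBlock(self.config.d, self.config.n_state,
                                seed=self.config.seed + 1 + i)
                       for i in range(self.config.n_layers)]
        self.w_norm = np.ones(self.config.d)

    def __call__(self, pc: PointCloud, point_features: np.ndarray) -> np.ndarray:
        grid = voxelize(pc, self.config.voxel_size)
        feats = self.lift(point_features)
        # mean-pool member points into each voxel
        vox = np.zeros((grid.n_voxels, feats.shape[1]))
        np.add.at(vox, grid.point_to_voxel, feats)
        counts = np.bincount(grid.point_to_voxel, minlength=grid.n_voxels)
        vox /= counts[:, None]
        seq = build_zorder_sequence(grid.voxel_coords)
        y = serialize(vox, seq)
        for block in self.blocks:
            y = selective_scan(y, block, mode=self.config.scan_mode)
            y = rmsnorm(y, self.w_norm, self.config.eps)
        y = restore(y, seq)
        return y[grid.point_to_voxel]

    @property
    def n_params(self) -> int:
        return (self.lift.n_params + self.w_norm.size
                + sum(b.n_params for b in self.blocks))
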