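"""End-to-end orchestration: encode (MDE) -> structure (ZOS-Mamba) ->
semantic head -> ALOC instance refinement.

The two encoder blocks are deterministic feature extractors with seeded,
fixed weights; the trainable component is the semantic head, a 2-layer MLP
classifying each point as crown vs background, optimized with Adam on
per-point binary cross-entropy (gradients derived by hand — the model is
small enough that no autodiff framework is needed). Instances are produced
by the ALOC clustering stage on the predicted foreground, not by a learned
instance head.

Blocks are the unit of batching: each optimizer step consumes up to
``batch_size`` blocks (the published protocol counts samples per batch).
Training is deterministic given the seed; a checkpoint stores the head
weights, Adam state and epoch counter, so a resumed run reproduces an
uninterrupted one bitwise.

Block-wise whole-scene inference is a documented stub: blocks are processed
independently and instance IDs are offset per block; no cross-block merging
is performed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aloc
from ._nn import sigmoid
from .io_formats import CrownAnnotationSet, PointCloud, ValidationError, \
    normalize_coords
from .mde import MDEConfig, MDEncoder
from .metrics import semantic_miou
from .zos_mamba import ZOSConfig, ZOSMambaEncoder

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "TrainConfig", "AlocConfig", "EvalConfig",
    "SegmentationResult", "Checkpoint", "FeatureExtractor",
    "train", "segment", "report_complexity",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    epochs: int = 150
    batch_size: int = 16          # blocks per optimizer step
    learning_rate: float = 0.02
    weight_decay: float = 1e-3    # L2 on the head; prunes nuisance channels
    hidden: int = 32
    seed: int = 0


@dataclass
class AlocConfig:
    size_threshold: int = 5000
    max_iter: int = 20
    alpha: float = 0.7
    tau: float = 0.5
    min_instance_points: int = 30   # smaller clusters revert to background


@dataclass
class EvalConfig:
    tau: float = 0.5


@dataclass
class IOConfig:
    log_level: str = "INFO"


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    mde: MDEConfig = field(default_factory=MDEConfig)
    zos_mamba: ZOSConfig = field(default_factory=ZOSConfig)
    aloc: AlocConfig = field(default_factory=AlocConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    _SECTIONS = {"io": IOConfig, "mde": MDEConfig, "zos_mamba": ZOSConfig,
                 "aloc": AlocConfig, "train": TrainConfig, "eval": EvalConfig}

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        cfg = cls()
        for section, payload in (doc or {}).items():
            if section not in cls._SECTIONS:
                raise ValidationError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            for key, value in (payload or {}).items():
                if not hasattr(target, key):
                    raise ValidationError(
                        f"unknown key {key!r} in section [{section}]")
                if isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
        cfg.mde.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(
            {k: asdict(getattr(self, k)) for k in self._SECTIONS},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SegmentationResult:
    semantic_prob: np.ndarray
    instance: np.ndarray
    provenance: dict


# ---------------------------------------------------------------------------
# feature extraction (fixed encoders)
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """MDE + ZOS-Mamba features plus raw geometric channels per point."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.mde = MDEncoder(config.mde)
        self.zos = ZOSMambaEncoder(d_in=config.mde.d_out,
                                   config=config.zos_mamba)

    # vertical reference scale (m): the encoder sees height above the block
    # floor on an absolute scale, so a flat ground-only block is not
    # stretched to look like a full canopy by per-block min-max scaling
    Z_REF = 25.0

    def _encoder_coords(self, pc: PointCloud) -> np.ndarray:
        pc_norm, _ = normalize_coords(pc)
        z = pc.coords[:, 2]
        z_abs = np.clip((z - z.min()) / self.Z_REF, 0.0, 1.0)
        return np.column_stack([pc_norm.coords[:, :2], z_abs])

    @staticmethod
    def _local_geometry(pc: PointCloud, k: int = 8,
                        cell: float = 1.0) -> np.ndarray:
        """Block-independent per-point descriptors: neighborhood radius
        (density proxy), local vertical spread, and height above the local
        ground cell — the standard crown/trunk/ground separators."""
        from sklearn.neighbors import NearestNeighbors

        coords = pc.coords
        k_eff = min(k, len(coords) - 1)
        if k_eff < 1:
            return np.zeros((len(coords), 3))
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
        dist, idx = nn.kneighbors(coords)
        radius = dist[:, -1]
        z = coords[:, 2]
        z_spread = z[idx].std(axis=1)
        ij = np.floor((coords[:, :2] - coords[:, :2].min(axis=0)) / cell)
        ij = ij.astype(np.int64)
        _, inv = np.unique(ij, axis=0, return_inverse=True)
        ground = np.full(inv.max() + 1, np.inf)
        np.minimum.at(ground, inv, z)
        return np.column_stack([radius, z_spread, z - ground[inv]])

    def __call__(self, pc: PointCloud,
                 ann: CrownAnnotationSet | None) -> np.ndarray:
        enc_coords = self._encoder_coords(pc)
        mde_feats = self.mde(enc_coords, ann)
        zos_feats = self.zos(pc, mde_feats)
        z = pc.coords[:, 2]
        geo = np.column_stack([enc_coords[:, :2], z - z.min(), z,
                               self._local_geometry(pc)])
        return np.hstack([geo, mde_feats, zos_feats])

    @property
    def d_out(self) -> int:
        return 7 + self.config.mde.d_out + self.config.zos_mamba.d

    @property
    def n_params(self) -> int:
        return self.mde.n_params + self.zos.n_params


# ---------------------------------------------------------------------------
# semantic head: 2-layer MLP, manual backprop, Adam
# ---------------------------------------------------------------------------

class SemanticHead:
    def __init__(self, d_in: int, hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / d_in)
        s2 = np.sqrt(2.0 / hidden)
        self.params = {
            "W1": rng.normal(0, s1, size=(d_in, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, s2, size=(hidden, 1)),
            "b2": np.zeros(1),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.maximum(x @ self.params["W1"] + self.params["b1"], 0.0)
        return sigmoid(h @ self.params["W2"] + self.params["b2"])[:, 0]

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       weight_decay: float = 0.0):
        p = self.params
        z1 = x @ p["W1"] + p["b1"]
        h = np.maximum(z1, 0.0)
        logits = (h @ p["W2"] + p["b2"])[:, 0]
        prob = sigmoid(logits)
        eps = 1e-12
        # class-balanced BCE: crown points heavily outnumber background in
        # canopy blocks, and an unweighted loss would bias the prior there
        pos = max(float(y.sum()), 1.0)
        neg = max(float(len(y) - y.sum()), 1.0)
        wgt = np.where(y > 0.5, len(y) / (2 * pos), len(y) / (2 * neg))
        loss = -np.mean(wgt * (y * np.log(prob + eps)
                               + (1 - y) * np.log(1 - prob + eps)))
        n = len(y)
        dlogits = (wgt * (prob - y))[:, None] / n    # BCE-with-sigmoid gradient
        grads = {
            "W2": h.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dh = dlogits @ p["W2"].T
        dz1 = dh * (z1 > 0)
        grads["W1"] = x.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        if weight_decay:
            for k in ("W1", "W2"):
                loss += 0.5 * weight_decay * float((p[k] ** 2).sum())
                grads[k] = grads[k] + weight_decay * p[k]
        return float(loss), grads

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


class Adam:
    def __init__(self, params: dict, lr: float = 0.02,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class Checkpoint:
    head_params: dict
    adam_m: dict
    adam_v: dict
    adam_t: int
    epoch: int
    config_hash: str
    feat_mean: np.ndarray | None = None    # training-set feature statistics,
    feat_std: np.ndarray | None = None     # frozen at fit time
    log: list[dict] = field(default_factory=list)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return x
        return (x - self.feat_mean) / self.feat_std


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    arrays = {}
    for group, d in (("p", ckpt.head_params), ("m", ckpt.adam_m),
                     ("v", ckpt.adam_v)):
        for k, v in d.items():
            arrays[f"{group}_{k}"] = v
    if ckpt.feat_mean is not None:
        arrays["s_feat_mean"] = ckpt.feat_mean
        arrays["s_feat_std"] = ckpt.feat_std
    meta = json.dumps({"adam_t": ckpt.adam_t, "epoch": ckpt.epoch,
                       "config_hash": ckpt.config_hash, "log": ckpt.log})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        groups: dict[str, dict] = {"p": {}, "m": {}, "v": {}, "s": {}}
        for key in data.files:
            if key == "__meta__":
                continue
            g, name = key.split("_", 1)
            groups[g][name] = data[key]
    return Checkpoint(head_params=groups["p"], adam_m=groups["m"],
                      adam_v=groups["v"], adam_t=meta["adam_t"],
                      epoch=meta["epoch"], config_hash=meta["config_hash"],
                      feat_mean=groups["s"].get("feat_mean"),
                      feat_std=groups["s"].get("feat_std"),
                      log=meta["log"])


# ---------------------------------------------------------------------------
# train / segment / complexity
# ---------------------------------------------------------------------------

Block = tuple[PointCloud, CrownAnnotationSet | None]


def train(config: PipelineConfig, train_blocks: list[Block],
          val_blocks: list[Block] | None = None,
          resume_from: Checkpoint | None = None) -> Checkpoint:
    """Train the semantic head; deterministic given config.train.seed."""
    if not train_blocks:
        raise ValidationError("empty training set")
    tc = config.train
    if tc.optimizer.lower() != "adam":
        raise ValidationError(f"unsupported optimizer {tc.optimizer!r}")
    extractor = FeatureExtractor(config)
    raw = [(extractor(pc, ann), (pc.semantic > 0).astype(float))
           for pc, ann in train_blocks]
    # feature statistics are fit on the training set and frozen, so new
    # blocks are judged on the training scale rather than their own
    stacked = np.vstack([x for x, _ in raw])
    feat_mean = stacked.mean(axis=0)
    feat_std = np.maximum(stacked.std(axis=0), 1e-8)
    feats = [((x - feat_mean) / feat_std, y) for x, y in raw]
    val_feats = [((extractor(pc, ann) - feat_mean) / feat_std, pc.semantic)
                 for pc, ann in (val_blocks or [])]

    head = SemanticHead(extractor.d_out, tc.hidden, seed=tc.seed)
    opt = Adam(head.params, lr=tc.learning_rate)
    start_epoch = 0
    train_log: list[dict] = []
    if resume_from is not None:
        head.params = {k: v.copy() for k, v in resume_from.head_params.items()}
        opt.m = {k: v.copy() for k, v in resume_from.adam_m.items()}
        opt.v = {k: v.copy() for k, v in resume_from.adam_v.items()}
        opt.t = resume_from.adam_t
        start_epoch = resume_from.epoch
        train_log = list(resume_from.log)

    n_blocks = len(feats)
    for epoch in range(start_epoch, tc.epochs):
        # per-epoch deterministic shuffle keeps resume bitwise-equivalent
        order = np.random.default_rng(tc.seed + 1000 + epoch).permutation(n_blocks)
        losses = []
        for start in range(0, n_blocks, tc.batch_size):
            chunk = order[start:start + tc.batch_size]
            x = np.vstack([feats[i][0] for i in chunk])
            y = np.concatenate([feats[i][1] for i in chunk])
            loss, grads = head.loss_and_grads(x, y, tc.weight_decay)
            opt.step(head.params, grads)
            losses.append(loss)
        entry = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        if val_feats:
            mious = [semantic_miou((head.forward(x) > 0.5).astype(int), y)
                     for x, y in val_feats]
            entry["val_miou"] = float(np.mean(mious))
        train_log.append(entry)
        log.info("epoch %d: %s", epoch + 1, entry)

    return Checkpoint(head_params=head.params, adam_m=opt.m, adam_v=opt.v,
                      adam_t=opt.t, epoch=tc.epochs,
                      config_hash=config.hash(), feat_mean=feat_mean,
                      feat_std=feat_std, log=train_log)


def segment(config: PipelineConfig, checkpoint: Checkpoint, pc: PointCloud,
            ann: CrownAnnotationSet | None = None,
            val_fn=None, seed: int = 0) -> SegmentationResult:
    """Semantic probabilities from the head, instances from ALOC refinement.

    With ``ann`` absent the encoder runs in single-modal 3D-only mode (the
    zero-descriptor path), which is logged.
    """
    if checkpoint.config_hash != config.hash():
        log.warning("checkpoint config hash %s != current config %s",
                    checkpoint.config_hash, config.hash())
    if ann is None:
        log.info("no annotation set supplied: running in 3D-only mode")
    extractor = FeatureExtractor(config)
    x = checkpoint.standardize(extractor(pc, ann))
    head = SemanticHead(extractor.d_out, config.train.hidden,
                        seed=config.train.seed)
    head.params = {k: v.copy() for k, v in checkpoint.head_params.items()}
    prob = head.forward(x)
    foreground = prob > 0.5
    if not foreground.any():
        log.warning("no foreground points predicted; zero instances")
        instance = np.zeros(len(pc), dtype=np.int64)
    else:
        seg = aloc.optimize(
            pc, val_fn=val_fn, max_iter=config.aloc.max_iter, seed=seed,
            size_threshold=config.aloc.size_threshold,
            alpha=config.aloc.alpha, foreground=foreground)
        instance = seg.instance.copy()
        ids, counts = np.unique(instance[instance > 0], return_counts=True)
        for i, c in zip(ids, counts):
            if c < config.aloc.min_instance_points:
                instance[instance == i] = 0
        # compact surviving IDs onto {1..M}
        survivors = np.unique(instance[instance > 0])
        remap = np.zeros(survivors.max() + 1 if len(survivors) else 1,
                         dtype=np.int64)
        remap[survivors] = np.arange(1, len(survivors) + 1)
        instance[instance > 0] = remap[instance[instance > 0]]
    return SegmentationResult(
        semantic_prob=prob, instance=instance,
        provenance={"config_hash": config.hash(), "seed": seed,
                    "mode": "3d_only" if ann is None else "multimodal"})


def report_complexity(config: PipelineConfig,
                      n_points: int = 4096) -> dict:
    """Exact parameter count plus a dense-multiply FLOP estimate per pass."""
    extractor = FeatureExtractor(config)
    head = SemanticHead(extractor.d_out, config.train.hidden,
                        seed=config.train.seed)
    param_count = extractor.n_params + head.n_params

    def mlp_flops(layers: list[tuple[int, int]], n: int) -> int:
        return sum(2 * a * b * n for a, b in layers)

    cfg_m, cfg_z = config.mde, config.zos_mamba
    flops = mlp_flops([(12, cfg_m.d_s),
                       (cfg_m.d_s, 2 * cfg_m.d_s),
                       (2 * cfg_m.d_s, 8 * cfg_m.d_feat)], 1)
    flops += mlp_flops([(8, cfg_m.d_feat)], n_points)          # fuse
    flops += mlp_flops([(cfg_m.d_feat, 2 * cfg_m.d_feat),
                        (2 * cfg_m.d_feat, cfg_m.n_branch),
                        (3 + cfg_m.d_s, 2 * (3 + cfg_m.d_s)),
                        (2 * (3 + cfg_m.d_s), 1),
                        (cfg_m.d_feat + 3 + cfg_m.d_s, 4 * cfg_m.subspace_k),
                        (3, cfg_m.d_out)], n_points)
    flops += mlp_flops([(cfg_m.d_out, cfg_z.d),
                        (cfg_z.d, cfg_z.d + 2 * cfg_z.n_state)], n_points)
    flops += 8 * cfg_z.d * cfg_z.n_state * n_points * cfg_z.n_layers  # scan
    flops += mlp_flops([(extractor.d_out, config.train.hidden),
                        (config.train.hidden, 1)], n_points)
    return {"param_count": int(param_count), "flop_estimate": int(flops),
            "n_points": n_points}
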