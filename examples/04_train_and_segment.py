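"""Toy end-to-end run: train the semantic head, segment a held-out block.

Eight synthetic trees in three blocks train the crown/background
classifier for 20 epochs on CPU; a two-row test block is then segmented
into instances by the adaptive clustering stage and scored against the
generator's ground truth.
"""

import numpy as np

from treeparse3d import PipelineConfig, PlantationSpec, generate_plantation
from treeparse3d.metrics import match_instances, semantic_miou
from treeparse3d.pipeline import segment, train

cfg = PipelineConfig()
cfg.train.epochs = 20
cfg.train.batch_size = 1      # one block per Adam step at toy scale

train_blocks = [
    generate_plantation(PlantationSpec(
        rows=1, trees_per_row=2, growth_stage_mix=(0.0, 1.0), seed=10))[:2],
    generate_plantation(PlantationSpec(
        rows=2, trees_per_row=2, stage_layout="alternating", seed=11))[:2],
    generate_plantation(PlantationSpec(
        rows=1, trees_per_row=2, stage_layout="alternating", seed=12))[:2],
]
val_pc, val_ann, _ = generate_plantation(PlantationSpec(
    rows=1, trees_per_row=2, stage_layout="alternating", seed=50))

ckpt = train(cfg, train_blocks, [(val_pc, val_ann)])
print(f"trained {cfg.train.epochs} epochs; "
      f"final loss {ckpt.log[-1]['loss']:.4f}, "
      f"held-out semantic mIoU {ckpt.log[-1]['val_miou']:.3f}")

test_pc, test_ann, _ = generate_plantation(PlantationSpec(
    rows=2, trees_per_row=2, tree_spacing=6.0, seed=60))
res = segment(cfg, ckpt, test_pc, test_ann, seed=0)

miou = semantic_miou((res.semantic_prob > 0.5).astype(int), test_pc.semantic)
m = match_instances(res.instance, test_pc.instance, tau=0.5)
n_inst = len(np.unique(res.instance[res.instance > 0]))
print(f"test block: semantic mIoU {miou:.3f}, {n_inst} instances, "
      f"instance F-score {m.fscore:.3f}")
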