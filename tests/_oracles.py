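"""Shared brute-force oracles, kept independent of the implementation."""

from itertools import permutations

import numpy as np


def optimal_assignment_oracle(pred, gt, tau):
    """Maximum-TP one-to-one assignment by exhaustive search (<= 6 ids)."""
    pids = [i for i in np.unique(pred) if i > 0]
    gids = [i for i in np.unique(gt) if i > 0]

    def iou(p, g):
        pm, gm = pred == p, gt == g
        inter = (pm & gm).sum()
        return inter / (pm.sum() + gm.sum() - inter) if inter else 0.0

    best_tp = 0
    small, large = (pids, gids) if len(pids) <= len(gids) else (gids, pids)
    for perm in permutations(large, len(small)):
        tp = sum(1 for a, b in zip(small, perm)
                 if (iou(a, b) if small is pids else iou(b, a)) >= tau)
        best_tp = max(best_tp, tp)
    return best_tp
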