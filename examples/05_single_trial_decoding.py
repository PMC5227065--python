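"""Decode target vs distractor from single-trial laminar MUA.

Window-averaged MUA per recording site (200-750 ms) feeds a linear SVM;
ROC areas on held-out 10% splits, repeated 10 times, give the single-trial
classification accuracy.  A label permutation test calibrates significance.
"""

import numpy as np

from lamflow import (
    SimConfig,
    decode_session,
    make_ground_truth,
    permutation_significance,
    simulate_session,
)

cfg = SimConfig(task="memory", n_trials_per_condition=50, seed=21)
gt = make_ground_truth(cfg, "memory_like")
rec, trials = simulate_session(gt, cfg)

window = (rec.times_ms >= 200) & (rec.times_ms < 750)
features = rec.mua[:, :, window].mean(axis=2)  # trials x channels
labels = trials["condition"].to_numpy()

res = decode_session(features, labels, seed=0)
p = permutation_significance(res, features, labels, n_perm=100, seed=0, n_repeats=3)
print(f"memory task, {features.shape[0]} trials, {features.shape[1]} sites")
print(f"mean ROC accuracy over 10 repeats: {res.accuracy:.3f} "
      f"(per repeat: {np.round(res.per_repeat, 2)})")
print(f"permutation test: p = {p:.4f} (floor 1/101 at 100 permutations)")
print("accuracy near 1 reflects the simulator's clean sustained modulation;")
print("real recordings carry far more trial-to-trial variability")
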