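"""Response latency per laminar compartment and LFP band power.

Latency is the time the fitted Gaussian + cumulative-Gaussian curve reaches
33% of its maximum; in the simulated column layer 4C and the deepest
contacts respond first.  Band power compares gamma (30-90 Hz) and alpha
(5-15 Hz) LFP power between conditions.
"""

import numpy as np

from lamflow import SimConfig, band_power, fit_latency, make_ground_truth, simulate_session

cfg = SimConfig(task="attention", n_trials_per_condition=30, seed=11)
gt = make_ground_truth(cfg, "attention_like")
rec, trials = simulate_session(gt, cfg)

avg = rec.mua.mean(axis=0)
sel = (rec.times_ms >= -100) & (rec.times_ms < 300)
fitted = {}
for comp in ("layer4", "deep", "superficial"):
    chans = np.flatnonzero(gt.compartments == comp)
    fit = fit_latency(avg[chans].mean(axis=0)[sel], rec.times_ms[sel])
    fitted[comp] = fit.latency_ms
    print(f"{comp:12s} fitted latency {fit.latency_ms:5.1f} ms "
          f"(transient onset parameter {gt.layer_latencies[chans].mean():.0f} ms)")
assert fitted["layer4"] < fitted["deep"] < fitted["superficial"]
print("the fitted latencies preserve the ground-truth ordering: layer 4C "
      "responds first, then the deep and superficial compartments")

conds = trials["condition"].to_numpy()
lfp_target = rec.lfp[conds == "target"]
gamma = band_power(lfp_target, rec.fs_lfp, (30, 90),
                   times_ms=rec.times_ms, window_ms=(200, 750)).mean()
alpha = band_power(lfp_target, rec.fs_lfp, (5, 15),
                   times_ms=rec.times_ms, window_ms=(200, 750)).mean()
print(f"target-condition LFP power, 200-750 ms: gamma {gamma:.2e}, "
      f"alpha {alpha:.2e} (white simulator noise gives no band preference;")
print("band_power exists to quantify the gamma-up/alpha-down signature in real data)")
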