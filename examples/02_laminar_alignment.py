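"""Locate the layer-4C/5 boundary from the evoked CSD polarity reversal.

Simulates full-field checkerboard sessions with different electrode depths
and shows that the reversal from deep sources to the layer-4C sink, read
around 40 ms after stimulus onset, recovers the true boundary; channels are
then assigned to laminar compartments by depth relative to that boundary.
"""

from lamflow import (
    CSDParams,
    SimConfig,
    build_alignment,
    compute_csd,
    find_reversal,
    make_ground_truth,
    simulate_session,
)

for true_boundary in (6, 10, 14):
    cfg = SimConfig(
        task="checkerboard",
        conditions=("checkerboard",),
        n_trials_per_condition=15,
        seed=true_boundary,
        boundary_channel=true_boundary,
    )
    gt = make_ground_truth(cfg, "null")
    rec, _ = simulate_session(gt, cfg)
    csd = compute_csd(rec.lfp.mean(axis=0), CSDParams(), times_ms=rec.times_ms)
    found = find_reversal(csd, rec.times_ms)  # searches 40 +/- 10 ms
    al = build_alignment(found, rec.n_channels)
    n_per = {c: int((al.compartment == c).sum()) for c in
             ("deep", "layer4", "superficial")}
    print(f"true boundary {true_boundary:2d} -> found {found:2d}; "
          f"compartment channel counts {n_per}")
print("each compartment spans 0.5 mm (five contacts at 0.1 mm spacing)")
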