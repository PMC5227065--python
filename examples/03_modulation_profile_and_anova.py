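"""Laminar profile of attentional modulation across a simulated cohort.

Runs the full pipeline on 12 attention-task penetrations: the target-minus-
distractor MUA difference (in units of the peak response) is computed per
channel, averaged per laminar compartment and tested across penetrations
with a Wilcoxon signed-rank test and a repeated-measures ANOVA over the
three compartments.  The simulated ground truth puts modulation 0.30 in the
superficial and deep compartments and 0.10 in layer 4, the laminar signature
of feedback input that avoids the input layer.
"""

from lamflow import PipelineConfig, run_pipeline

report = run_pipeline(
    PipelineConfig(preset="attention_like", n_penetrations=12, seed=7)
)
w = report["windows"]["modulation"]
print("target-minus-distractor MUA, 200-750 ms window, n = 12 penetrations")
print(f"  mean modulation (fraction of peak): {w['mean_modulation']:.3f}")
print(f"  signed-rank test: p = {w['paired_test']['p']:.4f}")
print("  compartment means:",
      {k: round(v, 3) for k, v in w["compartment_means"].items()})
print(f"  repeated-measures ANOVA: F = {w['anova']['F']:.1f}, "
      f"p = {w['anova']['p']:.2e} (Greenhouse-Geisser eps = "
      f"{w['anova']['epsilon']:.2f})")
print("  post-hoc (Bonferroni x3):",
      {k: f"{v:.4f}" for k, v in w["anova"]["posthoc"].items()})
print(f"  laminar profile consistency across penetrations: "
      f"mean r = {report['profile_consistency']['mean_r']:.2f}, "
      f"p = {report['profile_consistency']['p']:.4f}")
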