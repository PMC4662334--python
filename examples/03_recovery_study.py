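"""A miniature parameter-recovery study.

Runs a handful of replicates of scenario 4 with both estimators and prints
relative biases with Monte-Carlo standard errors plus the surface error
metrics. (Study-scale results need hundreds of replicates; this is a
pattern demo that runs in about a minute.)
"""

import ctsecr as ct

cfg = ct.StudyConfig(
    scenario=ct.get_scenario("exp4"),
    estimators=("singlecatch", "multicatch"),
    R=8,
    base_seed=5,
    rmsb_boot=200,
)
result = ct.run_study(cfg, progress=False)
summary = result.summarize()

print(f"scenario {summary['scenario']}: mean unique "
      f"{summary['mean_unique']:.1f}, saturation "
      f"{summary['mean_saturation_pct']:.0f}%")
for est, entry in summary["estimators"].items():
    print(f"\n{est} ({entry['reps_used']} usable replicates)")
    for param, (rb, se) in entry["relative_bias"].items():
        print(f"  RB({param:6s}) {rb:8.2f}% (SE {se:.2f})")
    full = entry["surface_metrics"]["full"]
    print(f"  RMSPE(full) {full['rmspe'][0]:.3f}  RMSB(full) {full['rmsb'][0]:.3f}")
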