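"""Run the complete coupled range/growth analysis end to end.

Equivalent to `fishclim demo --seed 1 --outdir fishclim_demo`, but from
Python, with a look at the integrated outputs. Takes a few minutes.
"""

from fishclim.pipeline import demo_config, run_pipeline

result = run_pipeline(demo_config(seed=1, outdir="fishclim_demo"))

print(f"retained variables: {result.retained_variables}")
print(f"SDM members: { {a: round(w, 3) for a, w in result.sdm.members} }")
print(f"ensemble AUC (held out): {result.sdm.ensemble_auc_holdout:.3f}\n")

merged = result.range_table[
    ["scenario", "pct_change", "distance_km", "bearing_deg"]
].merge(
    result.growth_means[["scenario", "mean_Linf_mm", "mean_K_per_yr"]],
    on="scenario",
)
print(merged.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

for target, reg in result.coupling.items():
    print(f"\ncoupling {target}: slope = {reg.slope:.4g} per % change, "
          f"r2 = {reg.r2:.3f}, F(1,{reg.df2}) = {reg.F:.1f}, p = {reg.p:.2g}")
print("\nclimate space expands with warming while mean maximum size falls and")
print("growth rate rises - the coupled shift the pipeline is built to detect.")
print("full artifact tree written to fishclim_demo/")
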