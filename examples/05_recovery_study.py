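"""Parameter-recovery check: can the model recover known coefficients?

Generates replicate datasets from the dock-like truth, refits each, and
tabulates bias and 90%-interval coverage of every regression coefficient.
With a correctly calibrated sampler, coverage should sit near 0.90 and
systematic bias near zero.  Five replicates keep this quick (~1 min);
increase `reps` for a sharper estimate.
"""

from gradcoda import SamplerSpec, default_dock_like_spec, recovery_experiment

spec = default_dock_like_spec(seed=0)
table = recovery_experiment(
    spec, reps=5, sampler=SamplerSpec(chains=2, warmup=300, draws=300)
)

coverage = table["covered"].mean()
bias_sd = (
    table.groupby(["power", "coord"])
    .apply(lambda g: g["bias"].mean() / g["post_sd"].mean(), include_groups=False)
    .abs()
    .max()
)
print(table.head(8).round(3).to_string(index=False))
print(f"\n90% interval coverage: {coverage:.2f} (nominal 0.90)")
print(f"largest per-component |bias| in posterior-SD units: {bias_sd:.2f}")
print("At 5 replicates each per-component bias estimate carries ~0.45 SD"
      "\nof Monte-Carlo noise, so values up to ~1 are expected for an"
      "\nunbiased sampler; at 20 replicates (see the acceptance script)"
      "\ncoverage lands near 0.88 and the mean |bias| near 0.2 SD.")
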