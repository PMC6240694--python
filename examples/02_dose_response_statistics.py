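"""Correlate module eigengenes with exposure dose.

Each module is summarized by its eigengene (first principal component of
the standardized member expression); the eigengene is correlated with
the ordinal dose level and tested with the Student-t correlation test.
Modules passing p < 0.01 are the dose-responsive ones.
"""

from coexnet import PipelineConfig, SyntheticConfig, generate, run_condition

data = generate(SyntheticConfig(seed=0))
result = run_condition(
    data.expression, data.metadata, PipelineConfig(condition="estrogen")
)

print("module-dose correlations (all modules):")
print(result.trait_table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
print("significant at p < 0.01 (sorted by correlation, as reported):")
print(result.significant[["module", "r", "p"]].to_string(index=False,
                                                         float_format=lambda v: f"{v:.3g}"))
# Three planted modules carry monotonic dose effects of |alpha| = 0.7; the
# detected correlations land near +/-0.7 and far below the 0.01 threshold.
# The null and low-dose-peak modules are detected as co-expression modules
# but (usually) fail the monotonic dose test.
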